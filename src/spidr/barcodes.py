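"""Barcode identification and read routing.

Each sequenced fragment is a read pair: one mate carries the insert (either
a cDNA fragment ligated to the RPM adaptor, or an antibody-bead oligo tag
followed by a UMI) and the other mate carries the concatenated split-pool
tags.  This module decodes the tag string positionally, trims the RPM
adaptor, and routes every read into exactly one of the RNA / OLIGO /
UNASSIGNED streams.  Unparseable reads are kept (as UNASSIGNED) so that
routing is a partition of the input and losses are auditable.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .scheme import BarcodeScheme, RoundSpec, hamming

RNA = "RNA"
OLIGO = "OLIGO"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read; read2 carries the barcode tags by default."""

    read_id: str
    seq1: str
    seq2: str


@dataclass
class TaggedRead:
    read_id: str
    # one entry per barcode position in READ order (position i is parsed at the
    # offset of scheme.read_rounds()[i]); each entry is the (round name,
    # tag name) actually matched there -- which may belong to a different
    # round than expected if ligation went out of order -- or None for a gap.
    barcode: tuple[Optional[tuple[str, str]], ...]
    read_class: str
    residual_sequence: str
    umi: str = ""
    antibody_tag: str = ""
    sample_label: Optional[str] = None

    @property
    def n_tags(self) -> int:
        return sum(1 for t in self.barcode if t is not None)

    @property
    def barcode_complete(self) -> bool:
        return bool(self.barcode) and all(t is not None for t in self.barcode)

    def barcode_string(self) -> str:
        """Period-joined ``round=tag`` entries in read order ('-' for a gap)."""
        return format_barcode(self.barcode)


def format_barcode(barcode: tuple[Optional[tuple[str, str]], ...]) -> str:
    return ".".join("-" if t is None else f"{t[0]}={t[1]}" for t in barcode)


def parse_barcode(text: str) -> tuple[Optional[tuple[str, str]], ...]:
    """Inverse of :func:`format_barcode`."""
    out: list[Optional[tuple[str, str]]] = []
    for part in text.split("."):
        if part == "-" or part == "":
            out.append(None)
        else:
            rnd, _, tag = part.partition("=")
            out.append((rnd, tag))
    return tuple(out)


def _match_tag(segment: str, round_: RoundSpec, tol: int) -> Optional[str]:
    """Tag name in this round matching the segment within tol mismatches."""
    tags = round_.tags
    for name, seq in tags.items():
        if seq == segment:
            return name
    if tol > 0:
        for name, seq in tags.items():
            if hamming(seq, segment) <= tol:
                return name
    return None


def _match_any_round(
    segment: str, rounds: Iterable[RoundSpec], tol: int
) -> Optional[tuple[str, str]]:
    """(round name, tag name) for the first round whose tag set matches."""
    for r in rounds:
        if len(segment) != r.tag_length:
            continue
        name = _match_tag(segment, r, tol)
        if name is not None:
            return (r.name, name)
    return None


def trim_rpm(sequence: str, scheme: BarcodeScheme) -> str:
    """Remove the RPM adaptor anchored at either read end.

    Occurrences at the 5' and 3' ends (within the scheme's mismatch
    tolerance) are stripped, repeatedly in case of adaptor concatemers;
    interior sequence is never touched.
    """
    rpm = scheme.rpm_sequence
    tol = scheme.mismatch_tolerance
    k = len(rpm)

    def _is_rpm(segment: str) -> bool:
        return len(segment) == k and hamming(segment, rpm) <= tol

    out = sequence
    while len(out) >= k and _is_rpm(out[:k]):
        out = out[k:]
    while len(out) >= k and _is_rpm(out[-k:]):
        out = out[:-k]
    return out


def _find_rpm(sequence: str, scheme: BarcodeScheme) -> bool:
    """True if the RPM adaptor occurs anywhere in the read."""
    rpm = scheme.rpm_sequence
    tol = scheme.mismatch_tolerance
    k = len(rpm)
    if rpm in sequence:
        return True
    if tol == 0:
        return False
    for i in range(len(sequence) - k + 1):
        if hamming(sequence[i : i + k], rpm) <= tol:
            return True
    return False


def identify_barcodes(
    read_pair: ReadPair,
    scheme: BarcodeScheme,
    antibody_tags: Optional[dict[str, str]] = None,
) -> TaggedRead:
    """Decode the split-pool barcode on a read pair and classify the read.

    The barcode mate is parsed positionally: fixed offsets derived from the
    scheme's tag and spacer lengths, in read order (terminal tag first under
    the default ``reverse_ligation`` layout).  Each positional segment is
    matched against every round's tag set of the right length, so a tag
    ligated out of order is still identified and can be rejected downstream.
    A segment matching no tag leaves a gap; the read is never dropped.

    Reads whose insert mate contains the RPM adaptor are RNA; otherwise, if
    ``antibody_tags`` (name -> sequence) is supplied and the insert starts
    with a recognizable antibody tag followed by a UMI, the read is OLIGO;
    anything else is UNASSIGNED.
    """
    read_rounds = scheme.read_rounds()
    tol = scheme.mismatch_tolerance
    entries: list[Optional[tuple[str, str]]] = []
    pos = 0
    seq2 = read_pair.seq2
    for expected in read_rounds:
        seg = seq2[pos : pos + expected.tag_length]
        hit = None
        if len(seg) == expected.tag_length:
            # try the expected round first (exact positional layout), then all
            name = _match_tag(seg, expected, tol)
            if name is not None:
                hit = (expected.name, name)
            else:
                hit = _match_any_round(seg, scheme.rounds, tol)
        entries.append(hit)
        pos += expected.tag_length + len(expected.spacer)
    barcode = tuple(entries)

    sample_label: Optional[str] = None
    if scheme.sample_round_index is not None:
        want = scheme.rounds[scheme.sample_round_index].name
        for entry in barcode:
            if entry is not None and entry[0] == want:
                sample_label = scheme.sample_label_for(entry[1])
                break

    seq1 = read_pair.seq1
    if _find_rpm(seq1, scheme):
        return TaggedRead(
            read_id=read_pair.read_id,
            barcode=barcode,
            read_class=RNA,
            residual_sequence=trim_rpm(seq1, scheme),
            sample_label=sample_label,
        )

    if antibody_tags:
        tag_len = len(next(iter(antibody_tags.values())))
        tag_seg = seq1[:tag_len]
        umi = seq1[tag_len : tag_len + scheme.umi_length]
        ab_name = None
        if len(tag_seg) == tag_len:
            for name, seq in antibody_tags.items():
                if seq == tag_seg or (tol > 0 and hamming(seq, tag_seg) <= tol):
                    ab_name = name
                    break
        if ab_name is not None and len(umi) == scheme.umi_length:
            return TaggedRead(
                read_id=read_pair.read_id,
                barcode=barcode,
                read_class=OLIGO,
                residual_sequence=seq1[tag_len + scheme.umi_length :],
                umi=umi,
                antibody_tag=ab_name,
                sample_label=sample_label,
            )

    return TaggedRead(
        read_id=read_pair.read_id,
        barcode=barcode,
        read_class=UNASSIGNED,
        residual_sequence=seq1,
        sample_label=sample_label,
    )


def identify_all(
    read_pairs: Iterable[ReadPair],
    scheme: BarcodeScheme,
    antibody_tags: Optional[dict[str, str]] = None,
) -> Iterator[TaggedRead]:
    for rp in read_pairs:
        yield identify_barcodes(rp, scheme, antibody_tags)


def ligation_report(
    tagged_reads: Iterable[TaggedRead], scheme: BarcodeScheme
) -> pd.DataFrame:
    """Ligation efficiency: reads by number of identified tags and class.

    Returns a table with columns ``read_class``, ``n_tags``, ``count`` and
    ``fraction`` (fraction within the read class), covering k = 0..n_rounds.
    Empty input yields an empty table.
    """
    counts: Counter[tuple[str, int]] = Counter()
    for tr in tagged_reads:
        counts[(tr.read_class, tr.n_tags)] += 1
    if not counts:
        return pd.DataFrame(columns=["read_class", "n_tags", "count", "fraction"])
    classes = sorted({c for c, _ in counts})
    rows = []
    for cls in classes:
        total = sum(v for (c, _), v in counts.items() if c == cls)
        for k in range(scheme.n_rounds + 1):
            n = counts.get((cls, k), 0)
            rows.append(
                {"read_class": cls, "n_tags": k, "count": n, "fraction": n / total}
            )
    return pd.DataFrame(rows)


def _open_maybe_gz(path: str | Path):
    p = str(path)
    return gzip.open(p, "rt") if p.endswith(".gz") else open(p)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream a paired FASTQ file pair as ReadPair objects (gzip supported)."""
    with _open_maybe_gz(path1) as f1, _open_maybe_gz(path2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().rstrip("\n")
            f1.readline()
            f1.readline()
            h2 = f2.readline()
            s2 = f2.readline().rstrip("\n")
            f2.readline()
            f2.readline()
            name1 = h1[1:].split()[0].rstrip("\n")
            name2 = h2[1:].split()[0].rstrip("\n")
            if name1 != name2:
                raise ValueError(f"paired FASTQ out of sync: {name1!r} vs {name2!r}")
            yield ReadPair(read_id=name1, seq1=s1, seq2=s2)


def write_tagged_reads(tagged_reads: Iterable[TaggedRead], path) -> int:
    """Write tagged reads as TSV; returns the number of rows written."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "read_id\tread_class\tbarcode\tn_tags\tantibody_tag\tumi\tsample_label\tresidual\n"
        )
        for tr in tagged_reads:
            fh.write(
                f"{tr.read_id}\t{tr.read_class}\t{tr.barcode_string()}\t{tr.n_tags}\t"
                f"{tr.antibody_tag}\t{tr.umi}\t{tr.sample_label or ''}\t{tr.residual_sequence}\n"
            )
            n += 1
    return n
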