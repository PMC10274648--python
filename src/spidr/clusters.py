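"""SPIDR cluster construction: group reads by barcode, filter, deduplicate.

A SPIDR cluster is one bead: the set of antibody-oligo reads and RNA reads
sharing a complete split-pool barcode string.  Reads whose barcode has a
gap go to an "unbarcoded" sink and are counted, never silently dropped.
Clusters whose barcode string could not have arisen from sequential
ligation -- a tag observed at a position belonging to a different round, or
the same tag ligated twice -- are filtered out.  PCR duplicates are
collapsed exactly: oligo reads on (antibody tag, UMI) and RNA reads on
(reference, start, end, strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .barcodes import OLIGO, RNA, TaggedRead, format_barcode, parse_barcode
from .scheme import BarcodeScheme

Barcode = tuple[Optional[tuple[str, str]], ...]

#: SAM tag carrying the period-joined barcode string on aligned RNA reads
BARCODE_SAM_TAG = "XB"
#: SAM tag carrying the condition label, when sample multiplexing is used
SAMPLE_SAM_TAG = "XS"

CLUSTER_FILE_VERSION = "spidr-clusters-v1"


@dataclass(frozen=True)
class RnaRecord:
    """One aligned, uniquely mapping RNA read (0-based half-open)."""

    reference: str
    start: int
    end: int
    strand: str  # '+' or '-'
    unique_mapping: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"RnaRecord requires start < end, got {self.start},{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class OligoRecord:
    """One antibody-bead oligo read: the antibody identity plus its UMI."""

    antibody_tag: str
    umi: str

    def __post_init__(self) -> None:
        if not self.antibody_tag or not self.umi:
            raise ValueError("OligoRecord requires non-empty antibody_tag and umi")


@dataclass
class SpidrCluster:
    barcode: Barcode
    sample_label: Optional[str] = None
    oligos: list[OligoRecord] = field(default_factory=list)
    rnas: list[RnaRecord] = field(default_factory=list)

    def barcode_string(self) -> str:
        return format_barcode(self.barcode)

    @property
    def n_records(self) -> int:
        return len(self.oligos) + len(self.rnas)


@dataclass
class ClusterLog:
    """Counters accumulated while building/filtering clusters."""

    unbarcoded_rna: int = 0
    unbarcoded_oligo: int = 0
    nonunique_rna: int = 0
    clusters_built: int = 0
    filtered_out_of_order: int = 0
    filtered_repeat: int = 0


def rna_records_from_sam(
    path: str | Path, min_mapq: int = 30
) -> Iterator[tuple[Barcode, Optional[str], RnaRecord]]:
    """Yield (barcode, sample label, record) from an aligned SAM/BAM file.

    The barcode string travels through alignment in the ``XB`` tag.  Reads
    are marked non-unique when secondary/supplementary, MAPQ below
    ``min_mapq``, or NH > 1; those are dropped by :func:`build_clusters`.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            unique = not (aln.is_secondary or aln.is_supplementary)
            if aln.mapping_quality < min_mapq:
                unique = False
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                unique = False
            barcode: Barcode = ()
            if aln.has_tag(BARCODE_SAM_TAG):
                barcode = parse_barcode(str(aln.get_tag(BARCODE_SAM_TAG)))
            sample = (
                str(aln.get_tag(SAMPLE_SAM_TAG)) if aln.has_tag(SAMPLE_SAM_TAG) else None
            )
            rec = RnaRecord(
                reference=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                unique_mapping=unique,
            )
            yield barcode, sample, rec


def build_clusters(
    tagged_oligo_reads: Iterable[TaggedRead],
    rna_reads: Iterable[tuple[Barcode, Optional[str], RnaRecord]],
    log: Optional[ClusterLog] = None,
) -> tuple[list[SpidrCluster], ClusterLog]:
    """Group oligo and RNA reads into one cluster per complete barcode.

    Record counts are conserved: every input record lands in exactly one
    cluster or is counted in the log (unbarcoded / non-unique sinks).
    """
    log = log if log is not None else ClusterLog()
    by_barcode: dict[Barcode, SpidrCluster] = {}

    def _get(barcode: Barcode, sample: Optional[str]) -> SpidrCluster:
        cl = by_barcode.get(barcode)
        if cl is None:
            cl = SpidrCluster(barcode=barcode, sample_label=sample)
            by_barcode[barcode] = cl
        elif cl.sample_label is None:
            cl.sample_label = sample
        return cl

    for tr in tagged_oligo_reads:
        if tr.read_class != OLIGO:
            continue
        if not tr.barcode_complete:
            log.unbarcoded_oligo += 1
            continue
        _get(tr.barcode, tr.sample_label).oligos.append(
            OligoRecord(antibody_tag=tr.antibody_tag, umi=tr.umi)
        )

    for barcode, sample, rec in rna_reads:
        if not rec.unique_mapping:
            log.nonunique_rna += 1
            continue
        if not barcode or any(t is None for t in barcode):
            log.unbarcoded_rna += 1
            continue
        _get(barcode, sample).rnas.append(rec)

    clusters = list(by_barcode.values())
    log.clusters_built = len(clusters)
    return clusters, log


def barcode_is_valid(barcode: Barcode, scheme: BarcodeScheme) -> bool:
    """True when a complete barcode is in round order with no repeated tag."""
    expected = [r.name for r in scheme.read_rounds()]
    if len(barcode) != len(expected) or any(t is None for t in barcode):
        return False
    for entry, want in zip(barcode, expected):
        if entry[0] != want:
            return False  # out of order: a tag from the wrong round
    if len(set(barcode)) != len(barcode):
        return False  # identical repeat
    return True


def filter_barcode_strings(
    clusters: Iterable[SpidrCluster],
    scheme: BarcodeScheme,
    log: Optional[ClusterLog] = None,
) -> tuple[list[SpidrCluster], ClusterLog]:
    """Drop clusters whose barcode is out-of-order or repeats a tag."""
    log = log if log is not None else ClusterLog()
    expected = [r.name for r in scheme.read_rounds()]
    kept = []
    for cl in clusters:
        bc = cl.barcode
        if len(bc) != len(expected) or any(t is None for t in bc):
            log.filtered_out_of_order += 1
            continue
        if any(entry[0] != want for entry, want in zip(bc, expected)):
            log.filtered_out_of_order += 1
            continue
        if len(set(bc)) != len(bc):
            log.filtered_repeat += 1
            continue
        kept.append(cl)
    return kept, log


def dedup_oligos(cluster: SpidrCluster) -> SpidrCluster:
    """Collapse oligo reads to unique (antibody tag, UMI) pairs.

    UMIs are scoped per antibody tag within the cluster, so distinct
    bead-tag species with coincidentally equal UMIs survive.  Order of
    first appearance is preserved; the operation is idempotent.
    """
    seen: set[OligoRecord] = set()
    out = []
    for o in cluster.oligos:
        if o not in seen:
            seen.add(o)
            out.append(o)
    return replace_records(cluster, oligos=out)


def dedup_rnas(cluster: SpidrCluster) -> SpidrCluster:
    """Collapse RNA reads to unique (reference, start, end, strand)."""
    seen: set[RnaRecord] = set()
    out = []
    for r in cluster.rnas:
        if r not in seen:
            seen.add(r)
            out.append(r)
    return replace_records(cluster, rnas=out)


def replace_records(
    cluster: SpidrCluster,
    oligos: Optional[list[OligoRecord]] = None,
    rnas: Optional[list[RnaRecord]] = None,
) -> SpidrCluster:
    return SpidrCluster(
        barcode=cluster.barcode,
        sample_label=cluster.sample_label,
        oligos=cluster.oligos if oligos is None else oligos,
        rnas=cluster.rnas if rnas is None else rnas,
    )


def dedup_cluster(cluster: SpidrCluster) -> SpidrCluster:
    return dedup_rnas(dedup_oligos(cluster))


# ---------------------------------------------------------------------------
# cluster file format (text, one cluster per line):
#   <barcode string>\t[SMP:<label>\t]OLG:<antibody>:<umi>\t...\tRNA:<ref>:<start>-<end>:<strand>\t...
# ---------------------------------------------------------------------------


def write_clusters(clusters: Iterable[SpidrCluster], path: str | Path) -> int:
    """Write the cluster file; bit-exact round-trip with read_clusters."""
    n = 0
    with open(path, "w") as fh:
        fh.write(f"#{CLUSTER_FILE_VERSION}\n")
        for cl in clusters:
            parts = [cl.barcode_string()]
            if cl.sample_label is not None:
                parts.append(f"SMP:{cl.sample_label}")
            parts.extend(f"OLG:{o.antibody_tag}:{o.umi}" for o in cl.oligos)
            parts.extend(
                f"RNA:{r.reference}:{r.start}-{r.end}:{r.strand}" for r in cl.rnas
            )
            fh.write("\t".join(parts) + "\n")
            n += 1
    return n


def read_clusters(path: str | Path) -> Iterator[SpidrCluster]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            cl = SpidrCluster(barcode=parse_barcode(fields[0]))
            for fld in fields[1:]:
                kind, _, rest = fld.partition(":")
                if kind == "SMP":
                    cl.sample_label = rest
                elif kind == "OLG":
                    ab, _, umi = rest.rpartition(":")
                    cl.oligos.append(OligoRecord(antibody_tag=ab, umi=umi))
                elif kind == "RNA":
                    body, _, strand = rest.rpartition(":")
                    ref, _, span = body.rpartition(":")
                    start_s, _, end_s = span.partition("-")
                    cl.rnas.append(
                        RnaRecord(
                            reference=ref,
                            start=int(start_s),
                            end=int(end_s),
                            strand=strand,
                        )
                    )
                else:
                    raise ValueError(f"unknown cluster record type {kind!r}")
            yield cl
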