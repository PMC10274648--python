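"""Peak filtering and priority-based annotation against a GTF.

Every peak gets exactly one label.  When a window overlaps several
features (e.g. a CDS in one isoform and a 3'UTR in another), the label is
chosen by fixed priority:

    miRNA > CDS > 5'UTR > 3'UTR > proximal intron (within 500 nt of a
    splice site) > distal intron > non-coding exon > non-coding intron

with "intergenic" for peaks overlapping nothing.  Peaks whose primary gene
is a miRNA host are relabelled "miRNA_proximal".  GTF input is 1-based
closed and converted to the 0-based half-open coordinates used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

PROXIMAL_INTRON_NT = 500

MIRNA = "miRNA"
CDS = "CDS"
UTR5 = "5UTR"
UTR3 = "3UTR"
PROX_INTRON = "proximal_intron"
DIST_INTRON = "distal_intron"
NC_EXON = "noncoding_exon"
NC_INTRON = "noncoding_intron"
INTERGENIC = "intergenic"
MIRNA_PROXIMAL = "miRNA_proximal"

PRIORITY = [MIRNA, CDS, UTR5, UTR3, PROX_INTRON, DIST_INTRON, NC_EXON, NC_INTRON]
CATEGORIES = PRIORITY + [MIRNA_PROXIMAL, INTERGENIC]


def gtf_to_internal(start_1based: int, end_closed: int) -> tuple[int, int]:
    """GTF (1-based closed) -> internal (0-based half-open)."""
    return start_1based - 1, end_closed


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`gtf_to_internal` (lossless round trip)."""
    return start + 1, end


@dataclass(frozen=True)
class _Feature:
    category: str  # base category; introns stored as 'intron'
    gene_id: str
    coding: bool


class AnnotationDB:
    """Interval index over a GTF for priority annotation of peaks."""

    def __init__(self) -> None:
        # (reference, strand) -> IntervalTree of _Feature
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.genes: dict[str, dict] = {}
        self.mirna_hosts: set[str] = set()
        self.transcripts: pd.DataFrame = pd.DataFrame(
            columns=["gene_id", "transcript_id", "reference", "start", "end", "strand"]
        )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_gtf(cls, gtf_path: str | Path) -> "AnnotationDB":
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        self = cls()

        def _attr(feat, *keys, default=""):
            for k in keys:
                if k in feat.attributes:
                    return feat.attributes[k][0]
            return default

        for gene in db.features_of_type("gene"):
            start, end = gtf_to_internal(gene.start, gene.end)
            self.genes[gene.id] = {
                "reference": gene.seqid,
                "start": start,
                "end": end,
                "strand": gene.strand,
                "biotype": _attr(gene, "gene_type", "gene_biotype", default="protein_coding"),
            }

        tx_rows = []
        for tx in db.features_of_type("transcript"):
            gene_id = _attr(tx, "gene_id")
            gene = self.genes.get(gene_id, {})
            biotype = gene.get("biotype", "protein_coding")
            strand = tx.strand
            ref = tx.seqid
            exons = sorted(
                (gtf_to_internal(e.start, e.end) for e in db.children(tx, featuretype="exon")),
                key=lambda iv: iv[0],
            )
            cds = sorted(
                (gtf_to_internal(c.start, c.end) for c in db.children(tx, featuretype="CDS")),
                key=lambda iv: iv[0],
            )
            tstart, tend = gtf_to_internal(tx.start, tx.end)
            tx_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tx.id,
                    "reference": ref,
                    "start": tstart,
                    "end": tend,
                    "strand": strand,
                }
            )
            self._index_transcript(ref, strand, gene_id, biotype, exons, cds)

        for gene_id, g in self.genes.items():
            if g["biotype"] == "miRNA":
                # the miRNA body outranks everything it overlaps
                self._add(g["reference"], g["strand"], g["start"], g["end"],
                          _Feature(MIRNA, gene_id, False))
        self._flag_mirna_hosts()
        self.transcripts = pd.DataFrame(
            tx_rows,
            columns=["gene_id", "transcript_id", "reference", "start", "end", "strand"],
        )
        return self

    def _index_transcript(
        self,
        ref: str,
        strand: str,
        gene_id: str,
        biotype: str,
        exons: Sequence[tuple[int, int]],
        cds: Sequence[tuple[int, int]],
    ) -> None:
        if not exons:
            return
        coding = bool(cds)
        if biotype == "miRNA":
            return  # indexed from the gene record
        if coding:
            cds_lo = min(s for s, _ in cds)
            cds_hi = max(e for _, e in cds)
            for s, e in cds:
                self._add(ref, strand, s, e, _Feature(CDS, gene_id, True))
            for es, ee in exons:
                # exonic sequence outside the CDS span is UTR; side depends on strand
                if es < cds_lo:
                    lo, hi = es, min(ee, cds_lo)
                    cat = UTR5 if strand == "+" else UTR3
                    self._add(ref, strand, lo, hi, _Feature(cat, gene_id, True))
                if ee > cds_hi:
                    lo, hi = max(es, cds_hi), ee
                    cat = UTR3 if strand == "+" else UTR5
                    self._add(ref, strand, lo, hi, _Feature(cat, gene_id, True))
        else:
            for es, ee in exons:
                self._add(ref, strand, es, ee, _Feature(NC_EXON, gene_id, False))
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:]):
            if next_start > prev_end:
                self._add(
                    ref, strand, prev_end, next_start, _Feature("intron", gene_id, coding)
                )

    def _add(self, ref: str, strand: str, start: int, end: int, feat: _Feature) -> None:
        if end <= start:
            return
        self._trees.setdefault((ref, strand), IntervalTree()).addi(start, end, feat)

    def _flag_mirna_hosts(self) -> None:
        mirnas = [(gid, g) for gid, g in self.genes.items() if g["biotype"] == "miRNA"]
        for gid, g in self.genes.items():
            if g["biotype"] == "miRNA":
                continue
            for mid, m in mirnas:
                if (
                    m["reference"] == g["reference"]
                    and m["start"] < g["end"]
                    and m["end"] > g["start"]
                ):
                    self.mirna_hosts.add(gid)
                    break

    # -- queries -------------------------------------------------------------

    def _overlapping(self, ref: str, start: int, end: int, strand: Optional[str]):
        strands = [strand] if strand is not None else ["+", "-"]
        for s in strands:
            tree = self._trees.get((ref, s))
            if tree is None:
                continue
            yield from tree.overlap(start, end)

    def annotate_interval(
        self, ref: str, start: int, end: int, strand: Optional[str] = None
    ) -> str:
        """Single priority label for a genomic interval."""
        best_rank = len(PRIORITY)
        best_gene: Optional[str] = None
        for iv in self._overlapping(ref, start, end, strand):
            feat: _Feature = iv.data
            if feat.category == "intron":
                # distance of the peak to the nearer splice site of this intron
                d5 = max(0, start - iv.begin)
                d3 = max(0, iv.end - end)
                if feat.coding:
                    cat = PROX_INTRON if min(d5, d3) <= PROXIMAL_INTRON_NT else DIST_INTRON
                else:
                    cat = NC_INTRON
            else:
                cat = feat.category
            rank = PRIORITY.index(cat)
            if rank < best_rank:
                best_rank = rank
                best_gene = feat.gene_id
        if best_rank == len(PRIORITY):
            return INTERGENIC
        label = PRIORITY[best_rank]
        if label != MIRNA and best_gene in self.mirna_hosts:
            return MIRNA_PROXIMAL
        return label


def annotate_peak(peak, db: AnnotationDB, stranded: bool = True) -> str:
    """Label one peak (an object/row with reference, start, end, strand)."""
    strand = peak.strand if stranded else None
    return db.annotate_interval(peak.reference, int(peak.start), int(peak.end), strand)


def annotate_peaks(
    peaks: pd.DataFrame, db: AnnotationDB, stranded: bool = True
) -> pd.DataFrame:
    """Add an ``annotation`` column to a peak table."""
    out = peaks.copy()
    out["annotation"] = [
        db.annotate_interval(
            row.reference, int(row.start), int(row.end), row.strand if stranded else None
        )
        for row in peaks.itertuples()
    ]
    return out


def filter_peaks(
    peaks: pd.DataFrame,
    blacklist: Iterable[tuple[str, int, int]] = (),
) -> pd.DataFrame:
    """Drop peaks in blacklist regions or from non-uniquely-mapped signal.

    ``blacklist`` holds (reference, start, end) intervals, 0-based
    half-open; a malformed interval (start >= end) raises.  If the peak
    table carries a ``unique_mapping`` column, rows marked False are
    dropped as well.
    """
    bl = list(blacklist)
    for ref, s, e in bl:
        if s >= e:
            raise ValueError(f"malformed blacklist interval {ref}:{s}-{e} (start >= end)")
    keep = pd.Series(True, index=peaks.index)
    if "unique_mapping" in peaks.columns:
        keep &= peaks["unique_mapping"].astype(bool)
    for ref, s, e in bl:
        keep &= ~(
            (peaks["reference"] == ref) & (peaks["start"] < e) & (peaks["end"] > s)
        )
    return peaks.loc[keep].reset_index(drop=True)


def read_blacklist_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def annotation_composition(
    peaks: pd.DataFrame, min_peaks: int = 100
) -> pd.DataFrame:
    """Per-protein fraction of peaks in each annotation category.

    Intergenic peaks are removed first; proteins are kept only when they
    retain strictly more than ``min_peaks`` peaks.  Rows sum to 1.
    """
    if "protein" not in peaks.columns or "annotation" not in peaks.columns:
        raise ValueError("peak table needs 'protein' and 'annotation' columns")
    df = peaks[peaks["annotation"] != INTERGENIC]
    sizes = df.groupby("protein").size()
    keep = sizes[sizes > min_peaks].index
    df = df[df["protein"].isin(keep)]
    if df.empty:
        return pd.DataFrame(columns=[c for c in CATEGORIES if c != INTERGENIC])
    comp = (
        df.groupby(["protein", "annotation"]).size().unstack(fill_value=0).astype(float)
    )
    for cat in CATEGORIES:
        if cat != INTERGENIC and cat not in comp.columns:
            comp[cat] = 0.0
    comp = comp[[c for c in CATEGORIES if c != INTERGENIC]]
    return comp.div(comp.sum(axis=1), axis=0)
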