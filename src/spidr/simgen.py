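"""Synthetic SPIDR experiments with full truth tables.

The generator emulates the data-generating process the pipeline assumes:
antibody beads each carrying one antibody identity and a handful of oligo
tags (zero-truncated Poisson, median 4 at the default mean), a split-pool
barcode string per bead, inter-bead crosstalk (a bead acquiring a stray
tag of another antibody), RNA reads per bead (negative binomial), planted
RBP footprints with configurable fold enrichment over local background and
crosslink truncation pile-ups, uniform background reads, PCR duplicates,
and per-round ligation failures.  Outputs are paired FASTQ for the oligo
and cDNA libraries, pre-aligned RNA records in SAM (alignment itself is
out of scope), a miniature genome FASTA, a GENCODE-style GTF exercising
every annotation category, and TSV truth tables tracing every read to its
bead.

Everything is driven by one integer seed: the same config yields
byte-identical output files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .scheme import BarcodeScheme, RoundCategory, RoundSpec, dump_scheme, hamming

BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSite:
    """A planted RBP footprint with an optional crosslink pile-up.

    ``fold`` is the target coverage fold over local background at the
    footprint; ``truncation_fraction`` of the planted reads start exactly
    at the crosslink coordinate (``position``), emulating RT stops.
    ``condition`` restricts the site to one sample condition (None = all).
    """

    protein: str
    reference: str
    position: int
    footprint: int = 50
    fold: float = 10.0
    truncation_fraction: float = 0.5
    strand: str = "+"
    condition: Optional[str] = None


@dataclass
class SimConfig:
    n_beads: int = 1000
    antibodies: tuple[str, ...] = (
        "RBP1", "RBP2", "RBP3", "RBP4", "RBP5", "RBP6", "IgG", "GFP",
    )
    tags_per_cluster_mean: float = 4.0  # zero-truncated Poisson mean parameter
    crosstalk_rate: float = 0.05
    rna_reads_mean: float = 10.0
    rna_reads_dispersion: float = 2.0  # negative binomial size parameter
    planted_sites: tuple[PlantedSite, ...] = ()
    pcr_duplication_rate: float = 0.1
    ligation_failure_rate: float = 0.05
    genome_length: int = 100_000
    reference_name: str = "chrS"
    n_rounds: int = 6
    tags_per_round: int = 12
    tag_length: int = 8
    antibody_tag_length: int = 12
    umi_length: int = 8
    read_length_mean: float = 60.0
    read_length_sd: float = 10.0
    min_read_length: int = 20
    barcode_read_length: int = 80
    sample_conditions: tuple[str, ...] = ()  # round-1 tag partition, if any
    seed: int = 0

    def validate(self) -> None:
        for name, rate in (
            ("crosstalk_rate", self.crosstalk_rate),
            ("pcr_duplication_rate", self.pcr_duplication_rate),
            ("ligation_failure_rate", self.ligation_failure_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {rate}")
        if self.tags_per_cluster_mean <= 0:
            raise SimulationError("tags_per_cluster_mean must be positive")
        if self.n_beads < 1:
            raise SimulationError("n_beads must be >= 1")
        for site in self.planted_sites:
            if site.fold < 1.0:
                raise SimulationError(f"enrichment fold must be >= 1, got {site.fold}")
            if not 0.0 <= site.truncation_fraction <= 1.0:
                raise SimulationError("truncation_fraction must be in [0, 1]")
            if site.protein not in self.antibodies:
                raise SimulationError(f"planted site protein {site.protein!r} unknown")
            if site.reference != self.reference_name:
                raise SimulationError(
                    f"planted site reference {site.reference!r} is not in the genome"
                )
            if not (0 <= site.position and site.position + site.footprint <= self.genome_length):
                raise SimulationError(
                    f"planted site at {site.position} (footprint {site.footprint}) "
                    "lies outside the genome"
                )
            if site.condition is not None and site.condition not in self.sample_conditions:
                raise SimulationError(f"unknown condition {site.condition!r}")
        if self.sample_conditions and len(self.sample_conditions) < 2:
            raise SimulationError("sample multiplexing needs >= 2 conditions")


@dataclass
class TruthTables:
    """Ground truth for every bead, site, and emitted read."""

    beads: pd.DataFrame  # bead_id, antibody, barcode, condition
    sites: pd.DataFrame  # site_id, protein, reference, position, ...
    oligo_reads: pd.DataFrame  # read_id, bead_id, antibody_tag, umi, duplicate_of
    rna_reads: pd.DataFrame  # read_id, bead_id, reference, start, end, strand, site_id, duplicate_of


@dataclass
class SimResult:
    out_dir: Path
    scheme: BarcodeScheme
    antibody_tags: dict[str, str]
    truth: TruthTables
    genome_fasta: Path
    annotation_gtf: Path
    rna_sam: Path
    oligo_fastq: tuple[Path, Path]
    cdna_fastq: tuple[Path, Path]


# ---------------------------------------------------------------------------
# sequence codes
# ---------------------------------------------------------------------------


def _random_kmers(
    rng: np.random.Generator, n: int, length: int, min_dist: int
) -> list[str]:
    """Greedy random code: n k-mers with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise SimulationError(
                f"could not draw {n} length-{length} tags at distance {min_dist}"
            )
        cand = "".join(
            BASES[rng.integers(0, 4, size=length)].astype(str)
        )
        if all(hamming(cand, prev) >= min_dist for prev in out):
            out.append(cand)
    return out


def make_sim_scheme(cfg: SimConfig, rng: np.random.Generator) -> BarcodeScheme:
    """A valid split-pool scheme for the simulated experiment.

    Tag sequences within each round keep pairwise distance >= 3 so that the
    default 1-mismatch correction is unambiguous.  Categories alternate
    Odd/Even with a Terminal last round; tag names are globally unique.
    If sample conditions are configured, the first-ligated round's tags are
    partitioned evenly across conditions.
    """
    # one global code so tags are unambiguous ACROSS rounds as well: a tag
    # ligated in the wrong round is still identifiable, hence rejectable
    all_seqs = _random_kmers(rng, cfg.n_rounds * cfg.tags_per_round, cfg.tag_length, 3)
    rounds = []
    for i in range(cfg.n_rounds):
        if i == cfg.n_rounds - 1:
            cat = RoundCategory.TERMINAL
        else:
            cat = RoundCategory.ODD if i % 2 == 0 else RoundCategory.EVEN
        seqs = all_seqs[i * cfg.tags_per_round : (i + 1) * cfg.tags_per_round]
        tags = {f"R{i + 1}T{j + 1}": s for j, s in enumerate(seqs)}
        rounds.append(RoundSpec(name=f"round{i + 1}", category=cat, tags=tags))
    sample_round_index = None
    sample_labels: dict[str, str] = {}
    if cfg.sample_conditions:
        sample_round_index = 0
        tag_names = list(rounds[0].tags)
        n_cond = len(cfg.sample_conditions)
        for j, tag in enumerate(tag_names):
            sample_labels[tag] = cfg.sample_conditions[j * n_cond // len(tag_names)]
    return BarcodeScheme(
        rounds=tuple(rounds),
        umi_length=cfg.umi_length,
        sample_round_index=sample_round_index,
        sample_labels=sample_labels,
    )


def zero_truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Draws from Poisson(mean) conditioned on being >= 1."""
    out = rng.poisson(mean, size=size)
    while True:
        zero = out == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = rng.poisson(mean, size=n_zero)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)].astype(str))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# miniature annotation
# ---------------------------------------------------------------------------


def build_annotation(reference: str, genome_length: int) -> list[str]:
    """GENCODE-style GTF lines for a gene layout scaled to the contig.

    The layout exercises every annotation category: two multi-exon coding
    genes (one with two isoforms, one on the minus strand), a coding miRNA
    host with the miRNA in its intron, a histone-like single-exon coding
    gene, and a two-exon lncRNA.  Coordinates below are 0-based half-open
    and converted to GTF's 1-based closed on output.
    """
    L = genome_length
    if L < 20_000:
        raise SimulationError("genome_length must be >= 20000 for the gene layout")

    def f(x: float) -> int:
        return int(L * x)

    lines: list[str] = []

    def emit(feature, start, end, strand, gene_id, gene_name, biotype, tx_id=None):
        attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}"; gene_type "{biotype}";'
        if tx_id:
            attrs += f' transcript_id "{tx_id}";'
        lines.append(
            f"{reference}\tsim\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    # geneA: coding, + strand, two isoforms sharing 3 exons
    gA = (f(0.05), f(0.15))
    exonsA = [(f(0.05), f(0.07)), (f(0.09), f(0.11)), (f(0.13), f(0.15))]
    cdsA = [(f(0.06), f(0.07)), (f(0.09), f(0.11)), (f(0.13), f(0.14))]
    emit("gene", *gA, "+", "GENEA", "GeneA", "protein_coding")
    emit("transcript", *gA, "+", "GENEA", "GeneA", "protein_coding", "GENEA-T1")
    for ex in exonsA:
        emit("exon", *ex, "+", "GENEA", "GeneA", "protein_coding", "GENEA-T1")
    for c in cdsA:
        emit("CDS", *c, "+", "GENEA", "GeneA", "protein_coding", "GENEA-T1")
    # shorter isoform: first two exons only
    emit("transcript", exonsA[0][0], exonsA[1][1], "+", "GENEA", "GeneA",
         "protein_coding", "GENEA-T2")
    for ex in exonsA[:2]:
        emit("exon", *ex, "+", "GENEA", "GeneA", "protein_coding", "GENEA-T2")
    emit("CDS", cdsA[0][0], cdsA[0][1], "+", "GENEA", "GeneA", "protein_coding", "GENEA-T2")

    # geneB: coding, - strand, two exons
    gB = (f(0.20), f(0.28))
    exonsB = [(f(0.20), f(0.22)), (f(0.26), f(0.28))]
    cdsB = [(f(0.205), f(0.22)), (f(0.26), f(0.275))]
    emit("gene", *gB, "-", "GENEB", "GeneB", "protein_coding")
    emit("transcript", *gB, "-", "GENEB", "GeneB", "protein_coding", "GENEB-T1")
    for ex in exonsB:
        emit("exon", *ex, "-", "GENEB", "GeneB", "protein_coding", "GENEB-T1")
    for c in cdsB:
        emit("CDS", *c, "-", "GENEB", "GeneB", "protein_coding", "GENEB-T1")

    # miRNA host: coding, + strand, miRNA inside its intron
    gH = (f(0.35), f(0.45))
    exonsH = [(f(0.35), f(0.37)), (f(0.43), f(0.45))]
    cdsH = [(f(0.355), f(0.37)), (f(0.43), f(0.445))]
    emit("gene", *gH, "+", "MIRHOST", "MirHost", "protein_coding")
    emit("transcript", *gH, "+", "MIRHOST", "MirHost", "protein_coding", "MIRHOST-T1")
    for ex in exonsH:
        emit("exon", *ex, "+", "MIRHOST", "MirHost", "protein_coding", "MIRHOST-T1")
    for c in cdsH:
        emit("CDS", *c, "+", "MIRHOST", "MirHost", "protein_coding", "MIRHOST-T1")
    mir = (f(0.40), f(0.40) + 22)
    emit("gene", *mir, "+", "MIR1", "Mir1", "miRNA")
    emit("transcript", *mir, "+", "MIR1", "Mir1", "miRNA", "MIR1-T1")
    emit("exon", *mir, "+", "MIR1", "Mir1", "miRNA", "MIR1-T1")

    # histone-like: single-exon coding gene, + strand
    gC = (f(0.50), f(0.52))
    emit("gene", *gC, "+", "HISTC", "HistC", "protein_coding")
    emit("transcript", *gC, "+", "HISTC", "HistC", "protein_coding", "HISTC-T1")
    emit("exon", *gC, "+", "HISTC", "HistC", "protein_coding", "HISTC-T1")
    emit("CDS", f(0.502), f(0.518), "+", "HISTC", "HistC", "protein_coding", "HISTC-T1")

    # lncRNA: noncoding, - strand, two exons
    gL = (f(0.60), f(0.68))
    exonsL = [(f(0.60), f(0.62)), (f(0.66), f(0.68))]
    emit("gene", *gL, "-", "LINC1", "Linc1", "lncRNA")
    emit("transcript", *gL, "-", "LINC1", "Linc1", "lncRNA", "LINC1-T1")
    for ex in exonsL:
        emit("exon", *ex, "-", "LINC1", "Linc1", "lncRNA", "LINC1-T1")

    return lines


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------


def _fastq_gz(path: Path, names: list[str], seqs: list[str]) -> None:
    """Deterministic gzip FASTQ (mtime pinned so reruns are byte-identical)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", filename="", mtime=0) as gz:
            chunks = []
            for name, seq in zip(names, seqs):
                chunks.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            gz.write("".join(chunks).encode())


def simulate_experiment(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate a complete synthetic experiment under ``out_dir``.

    Validates the config (including planted sites against the genome)
    before writing any file.
    """
    cfg.validate()
    out = Path(out_dir)
    rng = np.random.default_rng(cfg.seed)
    out.mkdir(parents=True, exist_ok=True)

    scheme = make_sim_scheme(cfg, rng)
    ab_seqs = _random_kmers(rng, len(cfg.antibodies), cfg.antibody_tag_length, 3)
    antibody_tags = dict(zip(cfg.antibodies, ab_seqs))

    genome_seq = _random_seq(rng, cfg.genome_length)

    # ---- beads -----------------------------------------------------------
    n_ab = len(cfg.antibodies)
    bead_ab = rng.integers(0, n_ab, size=cfg.n_beads)
    bead_tag_idx = rng.integers(0, cfg.tags_per_round, size=(cfg.n_beads, cfg.n_rounds))
    round_tag_names = [list(r.tags) for r in scheme.rounds]
    round_tag_seqs = [list(r.tags.values()) for r in scheme.rounds]

    if cfg.sample_conditions:
        bead_condition = [
            scheme.sample_labels[round_tag_names[0][bead_tag_idx[b, 0]]]
            for b in range(cfg.n_beads)
        ]
    else:
        bead_condition = [None] * cfg.n_beads

    def bead_barcode_string(b: int) -> str:
        # read order: terminal (last-ligated) round first
        parts = []
        for i in reversed(range(cfg.n_rounds)):
            parts.append(f"round{i + 1}={round_tag_names[i][bead_tag_idx[b, i]]}")
        return ".".join(parts)

    beads_df = pd.DataFrame(
        {
            "bead_id": np.arange(cfg.n_beads),
            "antibody": [cfg.antibodies[i] for i in bead_ab],
            "barcode": [bead_barcode_string(b) for b in range(cfg.n_beads)],
            "condition": ["" if c is None else c for c in bead_condition],
        }
    )

    # ---- oligo tag reads -------------------------------------------------
    n_tags = zero_truncated_poisson(rng, cfg.tags_per_cluster_mean, cfg.n_beads)
    oligo_bead = np.repeat(np.arange(cfg.n_beads), n_tags)
    n_oligo = len(oligo_bead)
    oligo_ab = bead_ab[oligo_bead].copy()
    if cfg.crosstalk_rate > 0 and n_ab > 1:
        stray = rng.random(n_oligo) < cfg.crosstalk_rate
        shift = rng.integers(1, n_ab, size=int(stray.sum()))
        oligo_ab[stray] = (oligo_ab[stray] + shift) % n_ab
    oligo_umi = [
        "".join(row)
        for row in BASES[rng.integers(0, 4, size=(n_oligo, cfg.umi_length))].astype(str)
    ]

    # ---- RNA reads -------------------------------------------------------
    r = cfg.rna_reads_dispersion
    p_nb = r / (r + cfg.rna_reads_mean)
    bg_per_bead = rng.negative_binomial(r, p_nb, size=cfg.n_beads)

    rna_bead: list[np.ndarray] = []
    rna_start: list[np.ndarray] = []
    rna_end: list[np.ndarray] = []
    rna_minus: list[np.ndarray] = []
    rna_site: list[np.ndarray] = []

    def draw_lengths(n: int) -> np.ndarray:
        ln = rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=n)
        return np.clip(np.round(ln), cfg.min_read_length, None).astype(np.int64)

    # uniform background, strand random, clipped inside the contig
    n_bg = int(bg_per_bead.sum())
    if n_bg:
        lens = draw_lengths(n_bg)
        starts = (rng.random(n_bg) * (cfg.genome_length - lens)).astype(np.int64)
        rna_bead.append(np.repeat(np.arange(cfg.n_beads), bg_per_bead))
        rna_start.append(starts)
        rna_end.append(starts + lens)
        rna_minus.append(rng.random(n_bg) < 0.5)
        rna_site.append(np.full(n_bg, -1, dtype=np.int64))

    mean_len = cfg.read_length_mean
    for s_idx, site in enumerate(cfg.planted_sites):
        eligible = np.nonzero(
            (bead_ab == cfg.antibodies.index(site.protein))
            & np.array(
                [
                    site.condition is None or c == site.condition
                    for c in bead_condition
                ]
            )
        )[0]
        if eligible.size == 0:
            raise SimulationError(
                f"no beads available for planted site on {site.protein!r}"
                + (f" in condition {site.condition!r}" if site.condition else "")
            )
        bg_total = int(bg_per_bead[eligible].sum())
        # expected background coverage of the footprint on one strand
        e_fp = bg_total * 0.5 * (site.footprint + mean_len - 1) / cfg.genome_length
        n_site = max(0, int(round((site.fold - 1.0) * e_fp)))
        if n_site == 0:
            continue
        lens = draw_lengths(n_site)
        truncated = rng.random(n_site) < site.truncation_fraction
        minus = site.strand == "-"
        if not minus:
            # read must overlap the footprint; truncated reads start at the crosslink
            lo = np.maximum(0, site.position - lens + 1)
            hi = np.minimum(cfg.genome_length - lens, site.position + site.footprint - 1)
            starts = (lo + rng.random(n_site) * (np.maximum(hi, lo) - lo)).astype(np.int64)
            starts[truncated] = site.position
            ends = starts + lens
        else:
            # minus strand: truncation coordinate is end - 1 == position
            lo = np.maximum(lens - 1, site.position - site.footprint + 1)
            hi = np.minimum(cfg.genome_length - 1, site.position + lens - 1)
            ends_m1 = (lo + rng.random(n_site) * (np.maximum(hi, lo) - lo)).astype(np.int64)
            ends_m1[truncated] = site.position
            ends = ends_m1 + 1
            starts = np.maximum(0, ends - lens)
        rna_bead.append(rng.choice(eligible, size=n_site))
        rna_start.append(starts)
        rna_end.append(ends)
        rna_minus.append(np.full(n_site, minus))
        rna_site.append(np.full(n_site, s_idx, dtype=np.int64))

    if rna_bead:
        rna_bead_a = np.concatenate(rna_bead)
        rna_start_a = np.concatenate(rna_start)
        rna_end_a = np.concatenate(rna_end)
        rna_minus_a = np.concatenate(rna_minus)
        rna_site_a = np.concatenate(rna_site)
    else:
        rna_bead_a = np.zeros(0, dtype=np.int64)
        rna_start_a = np.zeros(0, dtype=np.int64)
        rna_end_a = np.zeros(0, dtype=np.int64)
        rna_minus_a = np.zeros(0, dtype=bool)
        rna_site_a = np.zeros(0, dtype=np.int64)

    # ---- PCR duplicates --------------------------------------------------
    def duplicate_mask(n: int) -> np.ndarray:
        if cfg.pcr_duplication_rate == 0 or n == 0:
            return np.zeros(0, dtype=np.int64)
        return np.nonzero(rng.random(n) < cfg.pcr_duplication_rate)[0]

    oligo_dup_of = duplicate_mask(n_oligo)
    rna_dup_of = duplicate_mask(len(rna_bead_a))

    # ---- ligation failures ----------------------------------------------
    def failure_matrix(n: int) -> np.ndarray:
        if cfg.ligation_failure_rate == 0 or n == 0:
            return np.zeros((n, cfg.n_rounds), dtype=bool)
        return rng.random((n, cfg.n_rounds)) < cfg.ligation_failure_rate

    n_oligo_total = n_oligo + len(oligo_dup_of)
    n_rna_total = len(rna_bead_a) + len(rna_dup_of)
    oligo_fail = failure_matrix(n_oligo_total)
    rna_fail = failure_matrix(n_rna_total)

    # ---- emit oligo library ----------------------------------------------
    def barcode_read(bead: int, fails: np.ndarray) -> str:
        parts = []
        for i in reversed(range(cfg.n_rounds)):
            if fails[i]:
                parts.append("N" * cfg.tag_length)
            else:
                parts.append(round_tag_seqs[i][bead_tag_idx[bead, i]])
        seq = "".join(parts)
        if len(seq) < cfg.barcode_read_length:
            seq += "A" * (cfg.barcode_read_length - len(seq))
        return seq

    def barcode_tag_value(bead: int, fails: np.ndarray) -> str:
        parts = []
        for i in reversed(range(cfg.n_rounds)):
            if fails[i]:
                parts.append("-")
            else:
                parts.append(f"round{i + 1}={round_tag_names[i][bead_tag_idx[bead, i]]}")
        return ".".join(parts)

    oligo_names: list[str] = []
    oligo_r1: list[str] = []
    oligo_r2: list[str] = []
    oligo_rows = []
    for j in range(n_oligo):
        name = f"oligo{j}"
        bead = int(oligo_bead[j])
        ab_name = cfg.antibodies[oligo_ab[j]]
        oligo_names.append(name)
        oligo_r1.append(antibody_tags[ab_name] + oligo_umi[j])
        oligo_r2.append(barcode_read(bead, oligo_fail[j]))
        oligo_rows.append(
            {"read_id": name, "bead_id": bead, "antibody_tag": ab_name,
             "umi": oligo_umi[j], "duplicate_of": ""}
        )
    for k, j in enumerate(oligo_dup_of):
        name = f"oligo{n_oligo + k}"
        bead = int(oligo_bead[j])
        ab_name = cfg.antibodies[oligo_ab[j]]
        oligo_names.append(name)
        oligo_r1.append(antibody_tags[ab_name] + oligo_umi[j])
        oligo_r2.append(barcode_read(bead, oligo_fail[n_oligo + k]))
        oligo_rows.append(
            {"read_id": name, "bead_id": bead, "antibody_tag": ab_name,
             "umi": oligo_umi[j], "duplicate_of": f"oligo{j}"}
        )

    # ---- emit cDNA library + aligned SAM ---------------------------------
    rpm = scheme.rpm_sequence
    n_rna = len(rna_bead_a)
    cdna_names: list[str] = []
    cdna_r1: list[str] = []
    cdna_r2: list[str] = []
    rna_rows = []

    def rna_read_entry(idx: int, read_idx: int, dup_of: str) -> None:
        name = f"rna{read_idx}"
        bead = int(rna_bead_a[idx])
        start = int(rna_start_a[idx])
        end = int(rna_end_a[idx])
        minus = bool(rna_minus_a[idx])
        frag = genome_seq[start:end]
        if minus:
            frag = _revcomp(frag)
        cdna_names.append(name)
        cdna_r1.append(rpm + frag)
        cdna_r2.append(barcode_read(bead, rna_fail[read_idx]))
        rna_rows.append(
            {
                "read_id": name,
                "bead_id": bead,
                "reference": cfg.reference_name,
                "start": start,
                "end": end,
                "strand": "-" if minus else "+",
                "site_id": int(rna_site_a[idx]),
                "duplicate_of": dup_of,
                "barcode": barcode_tag_value(bead, rna_fail[read_idx]),
                "condition": beads_df.loc[bead, "condition"],
            }
        )

    for idx in range(n_rna):
        rna_read_entry(idx, idx, "")
    for k, idx in enumerate(rna_dup_of):
        rna_read_entry(int(idx), n_rna + k, f"rna{idx}")

    # ---- write files -----------------------------------------------------
    genome_fasta = out / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{cfg.reference_name}\n")
        for i in range(0, cfg.genome_length, 80):
            fh.write(genome_seq[i : i + 80] + "\n")

    annotation_gtf = out / "annotation.gtf"
    annotation_gtf.write_text(
        "\n".join(build_annotation(cfg.reference_name, cfg.genome_length)) + "\n"
    )

    dump_scheme(scheme, out / "scheme.yaml")
    with open(out / "antibody_tags.tsv", "w") as fh:
        fh.write("antibody\tsequence\n")
        for name, seq in antibody_tags.items():
            fh.write(f"{name}\t{seq}\n")

    oligo_fq1 = out / "oligo_R1.fastq.gz"
    oligo_fq2 = out / "oligo_R2.fastq.gz"
    _fastq_gz(oligo_fq1, oligo_names, oligo_r1)
    _fastq_gz(oligo_fq2, oligo_names, oligo_r2)
    cdna_fq1 = out / "cdna_R1.fastq.gz"
    cdna_fq2 = out / "cdna_R2.fastq.gz"
    _fastq_gz(cdna_fq1, cdna_names, cdna_r1)
    _fastq_gz(cdna_fq2, cdna_names, cdna_r2)

    rna_sam = out / "rna.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cfg.reference_name, "LN": cfg.genome_length}],
    }
    with pysam.AlignmentFile(str(rna_sam), "wh", header=header) as bam:
        for row in rna_rows:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = row["read_id"]
            a.reference_id = 0
            a.reference_start = row["start"]
            length = row["end"] - row["start"]
            a.cigarstring = f"{length}M"
            a.mapping_quality = 255
            a.flag = 16 if row["strand"] == "-" else 0
            seq = genome_seq[row["start"] : row["end"]]
            if row["strand"] == "-":
                seq = _revcomp(seq)
            a.query_sequence = seq
            a.set_tag("XB", row["barcode"])
            a.set_tag("NH", 1)
            if row["condition"]:
                a.set_tag("XS", row["condition"])
            bam.write(a)

    sites_df = pd.DataFrame(
        [
            {
                "site_id": i,
                "protein": s.protein,
                "reference": s.reference,
                "position": s.position,
                "footprint": s.footprint,
                "fold": s.fold,
                "truncation_fraction": s.truncation_fraction,
                "strand": s.strand,
                "condition": s.condition or "",
            }
            for i, s in enumerate(cfg.planted_sites)
        ],
        columns=[
            "site_id", "protein", "reference", "position", "footprint",
            "fold", "truncation_fraction", "strand", "condition",
        ],
    )
    oligo_df = pd.DataFrame(
        oligo_rows,
        columns=["read_id", "bead_id", "antibody_tag", "umi", "duplicate_of"],
    )
    rna_df = pd.DataFrame(
        rna_rows,
        columns=[
            "read_id", "bead_id", "reference", "start", "end", "strand",
            "site_id", "duplicate_of", "barcode", "condition",
        ],
    )

    truth = TruthTables(
        beads=beads_df, sites=sites_df, oligo_reads=oligo_df, rna_reads=rna_df
    )
    beads_df.to_csv(out / "truth_beads.tsv", sep="\t", index=False)
    sites_df.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    oligo_df.to_csv(out / "truth_oligo_reads.tsv", sep="\t", index=False)
    rna_df.to_csv(out / "truth_rna_reads.tsv", sep="\t", index=False)

    return SimResult(
        out_dir=out,
        scheme=scheme,
        antibody_tags=antibody_tags,
        truth=truth,
        genome_fasta=genome_fasta,
        annotation_gtf=annotation_gtf,
        rna_sam=rna_sam,
        oligo_fastq=(oligo_fq1, oligo_fq2),
        cdna_fastq=(cdna_fq1, cdna_fq2),
    )


def make_null_experiment(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """A calibration experiment: every protein draws from the same uniform
    background, so downstream enrichment p-values should be uniform-or-
    conservative.  Refuses configs with planted sites."""
    if cfg.planted_sites:
        raise SimulationError("make_null_experiment requires planted_sites to be empty")
    return simulate_experiment(cfg, out_dir)
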