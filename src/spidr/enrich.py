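"""Background correction and peak calling by matched-depth permutation.

The specificity engine of the pipeline.  For a protein of interest with N
assigned reads, the empirical null is built by repeatedly (>=100 times)
downsampling the pooled reads of all *other* proteins to exactly N reads
and counting them on the same fixed window grid.  Per window:

    enrichment = observed / mean(permutation counts)
    p          = (#permutations with count >= observed + 1) / (n_perms + 1)

i.e. the observed sample is included in both numerator and denominator, so
the smallest attainable p is 1/(n_perms + 1).  Windows with at least
``min_reads`` observed reads and p < alpha are significantly enriched
peaks.  The same machinery at window width 1 nt, applied to cDNA 3'-end
(reverse-transcription stop) coordinates, maps crosslink sites at
single-nucleotide resolution.

Counting is strand-aware and a read increments every window its interval
overlaps; observed and permuted reads are counted identically, so the
enrichment ratio is unbiased under either counting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .clusters import RnaRecord

DEFAULT_WINDOW = 100
DEFAULT_N_PERMS = 100
MIN_READS = 10
ALPHA = 0.05

STRANDS = ("+", "-")


class Genome:
    """Ordered reference names and lengths (the window-grid coordinate system)."""

    def __init__(self, lengths: dict[str, int]):
        if not lengths:
            raise ValueError("genome has no references")
        self.names: tuple[str, ...] = tuple(lengths)
        self.lengths: dict[str, int] = dict(lengths)
        self._index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_fasta(cls, fasta_path: str | Path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path))
        return cls({name: len(fa[name]) for name in fa.keys()})

    def index(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index


@dataclass
class ReadSet:
    """Aligned reads as parallel arrays, tied to a Genome."""

    genome: Genome
    ref: np.ndarray  # int32 index into genome.names
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    minus: np.ndarray  # bool

    @classmethod
    def from_records(cls, records: Iterable[RnaRecord], genome: Genome) -> "ReadSet":
        refs, starts, ends, minus = [], [], [], []
        for r in records:
            refs.append(genome.index(r.reference))
            starts.append(r.start)
            ends.append(r.end)
            minus.append(r.strand == "-")
        return cls(
            genome=genome,
            ref=np.asarray(refs, dtype=np.int32),
            start=np.asarray(starts, dtype=np.int64),
            end=np.asarray(ends, dtype=np.int64),
            minus=np.asarray(minus, dtype=bool),
        )

    @classmethod
    def concat(cls, readsets: Sequence["ReadSet"]) -> "ReadSet":
        if not readsets:
            raise ValueError("nothing to concatenate")
        g = readsets[0].genome
        return cls(
            genome=g,
            ref=np.concatenate([rs.ref for rs in readsets]),
            start=np.concatenate([rs.start for rs in readsets]),
            end=np.concatenate([rs.end for rs in readsets]),
            minus=np.concatenate([rs.minus for rs in readsets]),
        )

    def __len__(self) -> int:
        return len(self.start)

    def subset(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(self.genome, self.ref[idx], self.start[idx], self.end[idx], self.minus[idx])


class WindowGrid:
    """Non-overlapping fixed windows tiling every reference from coordinate 0."""

    def __init__(self, genome: Genome, window: int):
        if window < 1:
            raise ValueError("window width must be >= 1")
        self.genome = genome
        self.window = window
        self.n_windows = np.array(
            [-(-genome.lengths[n] // window) for n in genome.names], dtype=np.int64
        )
        self.offsets = np.concatenate([[0], np.cumsum(self.n_windows)])
        self.total = int(self.offsets[-1])

    def flat_windows(self, rs: ReadSet) -> tuple[np.ndarray, np.ndarray]:
        """First and last flat window index overlapped by each read."""
        lengths = np.array([self.genome.lengths[n] for n in self.genome.names])
        bad = (self.start_oob(rs, lengths)).nonzero()[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"read {i} ({self.genome.names[rs.ref[i]]}:{rs.start[i]}-{rs.end[i]}) "
                "extends beyond its reference"
            )
        w0 = self.offsets[rs.ref] + rs.start // self.window
        w1 = self.offsets[rs.ref] + (rs.end - 1) // self.window
        return w0, w1

    @staticmethod
    def start_oob(rs: ReadSet, lengths: np.ndarray) -> np.ndarray:
        return (rs.start < 0) | (rs.end > lengths[rs.ref])

    def coords(self, flat_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(reference index, window start, window end) for flat window ids."""
        ref = np.searchsorted(self.offsets, flat_idx, side="right") - 1
        local = flat_idx - self.offsets[ref]
        start = local * self.window
        lengths = np.array([self.genome.lengths[n] for n in self.genome.names])
        end = np.minimum(start + self.window, lengths[ref])
        return ref, start, end


def _count_flat(w0: np.ndarray, w1: np.ndarray, total: int) -> np.ndarray:
    """Counts per flat window; each read increments every overlapped window."""
    counts = np.zeros(total, dtype=np.int64)
    if len(w0) == 0:
        return counts
    span = w1 - w0
    max_span = int(span.max())
    for o in range(max_span + 1):
        sel = span >= o
        counts += np.bincount(w0[sel] + o, minlength=total)
    return counts


def count_windows(rs: ReadSet, grid: WindowGrid) -> dict[str, np.ndarray]:
    """Strand-separated window counts on the grid (flat arrays)."""
    w0, w1 = grid.flat_windows(rs)
    return {
        "+": _count_flat(w0[~rs.minus], w1[~rs.minus], grid.total),
        "-": _count_flat(w0[rs.minus], w1[rs.minus], grid.total),
    }


def permutation_background(
    target_n: int,
    other_reads: ReadSet,
    grid: WindowGrid,
    n_perms: int = DEFAULT_N_PERMS,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> dict[str, np.ndarray]:
    """Matched-depth permutation counts: (n_perms, n_windows) per strand.

    Each permutation draws exactly ``target_n`` reads uniformly without
    replacement from the pooled other-protein reads and counts them exactly
    like :func:`count_windows`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_pool = len(other_reads)
    if n_pool < target_n:
        raise ValueError(
            f"background pool has {n_pool} reads but {target_n} are required per "
            "permutation; add background data (sampling with replacement is not done)"
        )
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    w0, w1 = grid.flat_windows(other_reads)
    minus = other_reads.minus
    out = {
        "+": np.zeros((n_perms, grid.total), dtype=np.int32),
        "-": np.zeros((n_perms, grid.total), dtype=np.int32),
    }
    for p in range(n_perms):
        idx = rng.choice(n_pool, size=target_n, replace=False)
        sel_minus = minus[idx]
        for strand, sel in (("+", idx[~sel_minus]), ("-", idx[sel_minus])):
            out[strand][p] = _count_flat(w0[sel], w1[sel], grid.total)
    return out


def window_enrichment(
    observed: dict[str, np.ndarray],
    perms: dict[str, np.ndarray],
    grid: WindowGrid,
) -> pd.DataFrame:
    """Per-window statistics for every window with at least one observed read.

    Columns: reference, start, end, strand, observed, expected_mean,
    enrichment, p_value, n_perms, expected_floored.  When the permutation
    mean is zero the enrichment denominator is floored at 1/n_perms (the
    smallest nonzero mean the permutations could have produced) and the
    window is flagged ``expected_floored``; the p-value is unaffected.
    """
    frames = []
    for strand in STRANDS:
        obs = observed[strand]
        mat = perms[strand]
        n_perms = mat.shape[0]
        cols = np.nonzero(obs > 0)[0]
        if cols.size == 0:
            continue
        o = obs[cols].astype(float)
        sub = mat[:, cols]
        exp = sub.mean(axis=0)
        k = (sub >= obs[cols]).sum(axis=0)
        p = (k + 1) / (n_perms + 1)
        floored = exp == 0
        denom = np.where(floored, 1.0 / n_perms, exp)
        ref_idx, wstart, wend = grid.coords(cols)
        frames.append(
            pd.DataFrame(
                {
                    "reference": [grid.genome.names[i] for i in ref_idx],
                    "start": wstart,
                    "end": wend,
                    "strand": strand,
                    "observed": obs[cols],
                    "expected_mean": exp,
                    "enrichment": o / denom,
                    "p_value": p,
                    "n_perms": n_perms,
                    "expected_floored": floored,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "reference", "start", "end", "strand", "observed", "expected_mean",
                "enrichment", "p_value", "n_perms", "expected_floored",
            ]
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["reference", "start", "strand"], ignore_index=True)


def run_enrichment(
    target: ReadSet,
    others: ReadSet,
    window: int = DEFAULT_WINDOW,
    n_perms: int = DEFAULT_N_PERMS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Full background correction for one protein: counts, permutations, stats."""
    grid = WindowGrid(target.genome, window)
    observed = count_windows(target, grid)
    perms = permutation_background(
        len(target), others, grid, n_perms=n_perms, rng=rng, seed=seed
    )
    return window_enrichment(observed, perms, grid)


def call_peaks(
    stats: pd.DataFrame, min_reads: int = MIN_READS, alpha: float = ALPHA
) -> pd.DataFrame:
    """Windows with observed >= min_reads and p < alpha (strict)."""
    keep = (stats["observed"] >= min_reads) & (stats["p_value"] < alpha)
    return stats.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-nucleotide truncation (reverse-transcription stop) analysis
# ---------------------------------------------------------------------------


def truncation_coordinate(read: RnaRecord) -> int:
    """Genomic position of the cDNA 3' end (the RT stop).

    Reverse transcription proceeds 3'->5' along the RNA, so the cDNA 3' end
    is the alignment end nearest the RNA 5' terminus: the smallest
    coordinate for plus-strand RNA, the largest (end - 1) for minus-strand.
    """
    return read.start if read.strand == "+" else read.end - 1


def truncation_readset(rs: ReadSet) -> ReadSet:
    """Collapse each read to the 1-nt interval at its truncation coordinate."""
    pos = np.where(rs.minus, rs.end - 1, rs.start)
    return ReadSet(rs.genome, rs.ref, pos, pos + 1, rs.minus)


@dataclass
class TruncationProfile:
    """Per-position truncation counts plus their enrichment statistics."""

    genome: Genome
    counts: dict[str, np.ndarray] = field(default_factory=dict)  # strand -> flat counts
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total_truncations(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


def truncation_enrichment(
    target: ReadSet,
    others: ReadSet,
    n_perms: int = DEFAULT_N_PERMS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TruncationProfile:
    """Window machinery at 1-nt resolution on truncation coordinates."""
    grid = WindowGrid(target.genome, 1)
    if len(target) == 0:
        return TruncationProfile(
            genome=target.genome,
            counts={s: np.zeros(grid.total, dtype=np.int64) for s in STRANDS},
            table=window_enrichment(
                {s: np.zeros(grid.total, dtype=np.int64) for s in STRANDS},
                {s: np.zeros((1, grid.total), dtype=np.int32) for s in STRANDS},
                grid,
            ),
        )
    t_target = truncation_readset(target)
    t_others = truncation_readset(others)
    observed = count_windows(t_target, grid)
    perms = permutation_background(
        len(t_target), t_others, grid, n_perms=n_perms, rng=rng, seed=seed
    )
    table = window_enrichment(observed, perms, grid)
    table = table.rename(columns={"start": "position"}).drop(columns=["end"])
    return TruncationProfile(genome=target.genome, counts=observed, table=table)


def motif_centered_profile(
    profile: TruncationProfile,
    peaks: pd.DataFrame,
    motif_hits: Iterable[tuple[str, int, int, str]],
    half_width: int = 50,
) -> pd.DataFrame:
    """Aggregate truncation counts by signed offset from motif starts.

    ``motif_hits`` are (reference, start, end, strand) intervals from an
    external motif scan; only hits overlapping a significant peak on the
    same strand contribute.  Offsets are strand-aware (upstream of the
    motif's first base is negative).  Returns columns offset, count,
    frequency; empty when no motif hit survives the peak restriction.
    """
    genome = profile.genome
    grid = WindowGrid(genome, 1)
    peak_list = [
        (row.reference, int(row.start), int(row.end), row.strand)
        for row in peaks.itertuples()
    ]
    offsets = np.arange(-half_width, half_width + 1)
    agg = np.zeros(offsets.size, dtype=np.int64)
    any_hit = False
    for ref, mstart, mend, strand in motif_hits:
        if not any(
            ref == pr and strand == ps and mstart < pe and mend > pb
            for pr, pb, pe, ps in peak_list
        ):
            continue
        any_hit = True
        counts = profile.counts[strand]
        base = grid.offsets[genome.index(ref)]
        length = genome.lengths[ref]
        anchor = mstart if strand == "+" else mend - 1
        for j, off in enumerate(offsets):
            pos = anchor + off if strand == "+" else anchor - off
            if 0 <= pos < length:
                agg[j] += counts[base + pos]
    if not any_hit:
        return pd.DataFrame(columns=["offset", "count", "frequency"])
    total = agg.sum()
    freq = agg / total if total > 0 else np.zeros_like(agg, dtype=float)
    return pd.DataFrame({"offset": offsets, "count": agg, "frequency": freq})


def export_bedgraph(
    stats: pd.DataFrame,
    path: str | Path,
    strand: Optional[str] = None,
    value_column: str = "enrichment",
) -> int:
    """Write window statistics as 4-column bedGraph (zero-observed omitted).

    bedGraph carries no strand, so pass ``strand`` to restrict output when
    both strands are present.  Values round-trip to 6 decimals.
    """
    df = stats
    if strand is not None:
        df = df[df["strand"] == strand]
    df = df[df["observed"] > 0]
    n = 0
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{value_column}"\n')
        for row in df.itertuples():
            fh.write(
                f"{row.reference}\t{row.start}\t{row.end}\t"
                f"{getattr(row, value_column):.6f}\n"
            )
            n += 1
    return n


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph, skipping track/comment lines."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            ref, start, end, value = line.rstrip("\n").split("\t")
            rows.append((ref, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["reference", "start", "end", "value"])


def peak_reads_fasta(
    reads: Iterable[RnaRecord],
    peaks: pd.DataFrame,
    fasta_path: str | Path,
    out_path: str | Path,
) -> int:
    """Export the sequences of reads falling in significant peaks as FASTA.

    Motif discovery itself is delegated to external tools; this produces
    their input.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    peak_list = [
        (row.reference, int(row.start), int(row.end), row.strand)
        for row in peaks.itertuples()
    ]
    n = 0
    with open(out_path, "w") as out:
        for i, r in enumerate(reads):
            if any(
                r.reference == pr and r.strand == ps and r.start < pe and r.end > pb
                for pr, pb, pe, ps in peak_list
            ):
                seq = str(fa[r.reference][r.start : r.end])
                out.write(f">read{i}|{r.reference}:{r.start}-{r.end}:{r.strand}\n{seq}\n")
                n += 1
    return n
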