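"""Two-condition differential binding analysis (mTOR-inhibition style).

For each protein, background-corrected signal bedGraphs from the two
conditions are reduced to one value per gene (the maximum absolute signal
over the gene, taking the best-covered isoform), normalized by the number
of antibody bead clusters recovered in each condition (to correct for
detection bias from unequal bead recovery), and compared as per-gene
log2 ratios.  Genes are grouped by an externally supplied per-gene score
(e.g. the 5'TOP-motif strength of their mRNA) and groups are compared
with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 20  # combined group size up to which the exact path is used


@dataclass(frozen=True)
class GroupTestResult:
    u_statistic: float
    p_value: float
    method: str  # 'exact' or 'asymptotic'
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# gene-level signal
# ---------------------------------------------------------------------------


def gene_signal(
    bedgraph: pd.DataFrame | str | Path,
    transcripts: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene absmax signal, via the best-covered isoform.

    ``bedgraph`` is a 4-column table (reference, start, end, value) sorted
    by (reference, start); unsorted input raises.  ``transcripts`` needs
    columns gene_id, transcript_id, reference, start, end.  Per isoform
    the value is the maximum of |value| over bedGraph intervals
    intersecting the isoform span; per gene the isoform with the highest
    value is kept.  Genes with no coverage get 0.
    """
    if not isinstance(bedgraph, pd.DataFrame):
        from .enrich import read_bedgraph

        bedgraph = read_bedgraph(bedgraph)
    for ref, sub in bedgraph.groupby("reference", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"bedGraph is not sorted by start within {ref!r}")

    rows = []
    by_ref = {ref: sub.reset_index(drop=True) for ref, sub in bedgraph.groupby("reference")}
    for (gene_id,), gene_tx in transcripts.groupby(["gene_id"]):
        best_val = 0.0
        best_tx = gene_tx.iloc[0]["transcript_id"]
        for tx in gene_tx.itertuples():
            sub = by_ref.get(tx.reference)
            if sub is None:
                continue
            sel = (sub["start"] < tx.end) & (sub["end"] > tx.start)
            val = float(sub.loc[sel, "value"].abs().max()) if sel.any() else 0.0
            if val > best_val:
                best_val = val
                best_tx = tx.transcript_id
        rows.append({"gene_id": gene_id, "isoform": best_tx, "raw_value": best_val})
    return pd.DataFrame(rows, columns=["gene_id", "isoform", "raw_value"])


def normalize_by_beads(
    signals: pd.DataFrame,
    bead_counts: pd.DataFrame,
    protein: str,
    condition: Optional[str],
) -> pd.DataFrame:
    """Divide raw gene values by the (protein, condition) bead-cluster count.

    ``bead_counts`` is the table from ``assign.bead_cluster_counts``.  A
    missing or zero count raises: the protein is unusable in that
    condition.
    """
    sel = bead_counts["protein"] == protein
    if condition is not None:
        sel &= bead_counts["sample_label"] == condition
    matched = bead_counts.loc[sel, "n_clusters"]
    n = int(matched.sum())
    if n <= 0:
        raise ValueError(
            f"no bead clusters for protein {protein!r} in condition {condition!r}; "
            "cannot normalize"
        )
    out = signals.copy()
    out["corrected_value"] = out["raw_value"] / n
    out["protein"] = protein
    out["condition"] = condition
    return out


# ---------------------------------------------------------------------------
# score-grouped log ratios
# ---------------------------------------------------------------------------


def top_grouped_ratios(
    signals_numerator: pd.DataFrame,
    signals_denominator: pd.DataFrame,
    top_scores: pd.DataFrame,
    bin_edges: Sequence[float] = (),
    unscored_label: str = "unscored",
) -> pd.DataFrame:
    """Per-gene log2(numerator / denominator), grouped by score category.

    Both signal tables need gene_id and corrected_value.  Genes with zero
    signal in either condition are excluded (the log ratio is undefined
    for them).  ``top_scores`` needs gene_id and score; genes without a
    score land in the ``unscored`` category.  ``bin_edges`` are the
    interior edges of the score bins (k edges -> k+1 categories).
    """
    num = signals_numerator.set_index("gene_id")["corrected_value"]
    den = signals_denominator.set_index("gene_id")["corrected_value"]
    genes = num.index.intersection(den.index)
    if genes.empty:
        raise ValueError("no genes shared between the two conditions")
    usable = genes[(num.loc[genes] > 0) & (den.loc[genes] > 0)]
    score_map = top_scores.set_index("gene_id")["score"] if len(top_scores) else pd.Series(dtype=float)

    edges = list(bin_edges)
    labels = _bin_labels(edges)

    rows = []
    for g in usable:
        ratio = math.log2(num.loc[g] / den.loc[g])
        if g in score_map.index:
            score = float(score_map.loc[g])
            group = labels[int(np.digitize(score, edges))]
        else:
            score, group = float("nan"), unscored_label
        rows.append(
            {"gene_id": g, "log2_ratio": ratio, "score": score, "top_group": group}
        )
    return pd.DataFrame(rows, columns=["gene_id", "log2_ratio", "score", "top_group"])


def _bin_labels(edges: Sequence[float]) -> list[str]:
    if not edges:
        return ["all"]
    labels = [f"score<={edges[0]:g}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo:g}<score<={hi:g}")
    labels.append(f"score>{edges[-1]:g}")
    return labels


# ---------------------------------------------------------------------------
# Mann-Whitney group comparison
# ---------------------------------------------------------------------------


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """Two-sided exact Mann-Whitney by full enumeration of rank subsets.

    Midranks handle ties; the p-value is 2 * min(P(U <= u), P(U >= u))
    capped at 1, enumerating all C(n_a + n_b, n_a) assignments of the
    pooled (mid)ranks to group A.  Intended for combined n <= ~20.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a)
    n = n_a + n_b
    count_le = 0
    count_ge = 0
    total = 0
    for comb in itertools.combinations(range(n), n_a):
        u = _u_statistic(ranks[list(comb)], n_a)
        total += 1
        if u <= u_obs + 1e-9:
            count_le += 1
        if u >= u_obs - 1e-9:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return GroupTestResult(u_statistic=u_obs, p_value=p, method="exact", n_a=n_a, n_b=n_b)


def group_test(
    grouped: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_column: str = "log2_ratio",
    group_column: str = "top_group",
) -> GroupTestResult:
    """Two-sided Mann-Whitney comparison of two score categories.

    Exact enumeration (tie-aware) when the combined sample is small,
    normal approximation with tie correction and continuity otherwise.
    """
    a = grouped.loc[grouped[group_column] == group_a, value_column].to_numpy()
    b = grouped.loc[grouped[group_column] == group_b, value_column].to_numpy()
    return mann_whitney(a, b)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) + len(b) <= EXACT_MAX_N:
        return mann_whitney_exact(a, b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupTestResult(
        u_statistic=float(u), p_value=float(p), method="asymptotic",
        n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------------------------
# per-protein read-count ratios
# ---------------------------------------------------------------------------


def read_count_ratio(
    read_counts: pd.DataFrame,
    bead_counts: pd.DataFrame,
    numerator: str,
    denominator: str,
) -> pd.DataFrame:
    """Bead-normalized per-protein read-count ratio between two conditions.

    ``read_counts`` needs protein, condition, n_reads; ``bead_counts`` is
    the assign-module table.  The ratio is
    (reads/beads in numerator condition) / (reads/beads in denominator);
    a zero denominator yields inf and is flagged, never dropped.  Sorted
    by descending ratio.
    """
    rows = []
    proteins = sorted(read_counts["protein"].unique())
    for protein in proteins:
        vals = {}
        for cond in (numerator, denominator):
            n_reads = int(
                read_counts.loc[
                    (read_counts["protein"] == protein)
                    & (read_counts["condition"] == cond),
                    "n_reads",
                ].sum()
            )
            n_beads = int(
                bead_counts.loc[
                    (bead_counts["protein"] == protein)
                    & (bead_counts["sample_label"] == cond),
                    "n_clusters",
                ].sum()
            )
            vals[cond] = (n_reads, n_beads)
        (num_reads, num_beads), (den_reads, den_beads) = vals[numerator], vals[denominator]
        if num_beads == 0 or den_beads == 0:
            continue  # protein absent in one condition: not normalizable
        num_norm = num_reads / num_beads
        den_norm = den_reads / den_beads
        infinite = den_norm == 0
        ratio = float("inf") if infinite else num_norm / den_norm
        rows.append(
            {
                "protein": protein,
                "reads_numerator": num_reads,
                "reads_denominator": den_reads,
                "beads_numerator": num_beads,
                "beads_denominator": den_beads,
                "ratio": ratio,
                "infinite": infinite,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein", "reads_numerator", "reads_denominator",
            "beads_numerator", "beads_denominator", "ratio", "infinite",
        ],
    )
    return df.sort_values("ratio", ascending=False, ignore_index=True)
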