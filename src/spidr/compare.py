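"""Cross-dataset statistics: peak-set overlap and composition similarity.

Two complementary questions about two binding maps of the same protein
(e.g. from this assay and from eCLIP):

* Do they call the same windows?  Answered with a 2x2 table over a common
  window universe: odds ratio (n11*n00)/(n10*n01) and the exact
  hypergeometric upper-tail probability of observing at least n11 shared
  windows.
* Do they bind the same kinds of RNA features?  Answered by the L2 norm
  between two protein-by-annotation-category fraction matrices, compared
  with a null built by shuffling whole protein rows (within-protein
  composition preserved), alternating which matrix is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapResult:
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_value: float
    universe_size: int
    continuity_corrected: bool

    def as_dict(self) -> dict:
        return {
            "n11": self.n11, "n10": self.n10, "n01": self.n01, "n00": self.n00,
            "odds_ratio": self.odds_ratio, "p_value": self.p_value,
            "universe_size": self.universe_size,
            "continuity_corrected": self.continuity_corrected,
        }


def hypergeometric_overlap(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> OverlapResult:
    """Exact overlap significance of two window sets within a universe.

    The p-value is the hypergeometric upper tail P(X >= |A & B|) for
    drawing |A| windows out of a universe containing |B| marked ones.  The
    odds ratio comes from the 2x2 table; a Haldane-Anscombe 0.5 is added
    to every cell only when some cell is zero (flagged in the result).
    """
    uni = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= uni:
        raise ValueError("set A is not a subset of the universe")
    if not b <= uni:
        raise ValueError("set B is not a subset of the universe")
    n = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    # P(X >= n11), X ~ Hypergeom(N=n, K=|B|, n=|A|)
    p = float(stats.hypergeom.sf(n11 - 1, n, len(b), len(a)))
    corrected = 0 in (n11, n10, n01, n00)
    if corrected:
        odds = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
    else:
        odds = (n11 * n00) / (n10 * n01)
    return OverlapResult(
        n11=n11, n10=n10, n01=n01, n00=n00,
        odds_ratio=float(odds), p_value=min(p, 1.0),
        universe_size=n, continuity_corrected=corrected,
    )


def peaks_to_windows(
    peaks: pd.DataFrame, window: int
) -> set[tuple[str, int, str]]:
    """Canonical window keys (reference, window start, strand) for a peak table."""
    out: set[tuple[str, int, str]] = set()
    for row in peaks.itertuples():
        w0 = int(row.start) // window
        w1 = (int(row.end) - 1) // window
        for w in range(w0, w1 + 1):
            out.add((row.reference, w * window, row.strand))
    return out


@dataclass
class L2ShuffleResult:
    observed_l2: float
    null_distribution: np.ndarray
    empirical_p: float
    n_samples: int


def l2_shuffle_test(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    n_samples: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> L2ShuffleResult:
    """Row-shuffle null for the L2 distance between composition matrices.

    Both matrices are proteins (rows) x annotation categories (columns)
    with rows summing to 1 and must share labels.  The observed statistic
    is the Euclidean norm of the difference of the flattened matrices.
    Each null draw permutes the protein rows of one matrix (keeping each
    protein's composition intact) while holding the other fixed,
    alternating which matrix is shuffled.  The empirical p is the fraction
    of null draws with L2 <= observed (small distance = similar), with the
    observed draw included in numerator and denominator.
    """
    missing_rows = set(mat_a.index).symmetric_difference(mat_b.index)
    missing_cols = set(mat_a.columns).symmetric_difference(mat_b.columns)
    if missing_rows or missing_cols:
        raise ValueError(
            "matrices must share labels; mismatched rows: "
            f"{sorted(map(str, missing_rows))}, columns: {sorted(map(str, missing_cols))}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    b = mat_b.loc[mat_a.index, mat_a.columns].to_numpy(dtype=float)
    a = mat_a.to_numpy(dtype=float)
    observed = float(np.linalg.norm(a - b))
    n_rows = a.shape[0]
    null = np.empty(n_samples)
    for i in range(n_samples):
        perm = rng.permutation(n_rows)
        if i % 2 == 0:
            null[i] = np.linalg.norm(a - b[perm])
        else:
            null[i] = np.linalg.norm(a[perm] - b)
    p = (int((null <= observed).sum()) + 1) / (n_samples + 1)
    return L2ShuffleResult(
        observed_l2=observed, null_distribution=null,
        empirical_p=float(p), n_samples=n_samples,
    )
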