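"""Protein assignment: call each cluster's antibody by majority vote.

Each bead carries a single antibody, so the deduplicated oligo tags of a
cluster should be dominated by one antibody identity.  A cluster is
assigned to the modal antibody when it has at least ``min_oligos`` tags,
the mode accounts for at least ``frac_unique`` of them (boundary
inclusive), and the cluster holds at most ``max_rnas`` RNA reads; anything
else -- including a tie for the mode -- is AMBIGUOUS and its reads are
excluded from downstream maps.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .clusters import RnaRecord, SpidrCluster

AMBIGUOUS = "AMBIGUOUS"

MIN_OLIGOS = 3
FRAC_UNIQUE = 0.8
MAX_RNAS = 100


@dataclass(frozen=True)
class ProteinAssignment:
    barcode: str
    protein: str
    n_oligos: int
    top_fraction: float
    n_rnas: int
    sample_label: Optional[str] = None

    @property
    def assigned(self) -> bool:
        return self.protein != AMBIGUOUS


def assign_protein(
    cluster: SpidrCluster,
    min_oligos: int = MIN_OLIGOS,
    frac_unique: float = FRAC_UNIQUE,
    max_rnas: int = MAX_RNAS,
) -> ProteinAssignment:
    """Apply the >=min_oligos / >=frac_unique / <=max_rnas voting rules.

    The cluster must already be deduplicated; votes are counted over unique
    (antibody tag, UMI) oligo records.
    """
    counts = Counter(o.antibody_tag for o in cluster.oligos)
    n = sum(counts.values())
    if n == 0:
        return ProteinAssignment(
            cluster.barcode_string(), AMBIGUOUS, 0, 0.0, len(cluster.rnas),
            cluster.sample_label,
        )
    top = counts.most_common()
    top_count = top[0][1]
    modal = [ab for ab, c in top if c == top_count]
    frac = top_count / n
    protein = AMBIGUOUS
    if (
        len(modal) == 1
        and n >= min_oligos
        and frac >= frac_unique
        and len(cluster.rnas) <= max_rnas
    ):
        protein = modal[0]
    return ProteinAssignment(
        barcode=cluster.barcode_string(),
        protein=protein,
        n_oligos=n,
        top_fraction=frac,
        n_rnas=len(cluster.rnas),
        sample_label=cluster.sample_label,
    )


def assign_all(
    clusters: Iterable[SpidrCluster],
    min_oligos: int = MIN_OLIGOS,
    frac_unique: float = FRAC_UNIQUE,
    max_rnas: int = MAX_RNAS,
) -> list[ProteinAssignment]:
    return [assign_protein(c, min_oligos, frac_unique, max_rnas) for c in clusters]


def split_by_protein(
    clusters: Iterable[SpidrCluster],
    assignments: Iterable[ProteinAssignment],
) -> tuple[dict[tuple[str, Optional[str]], list[RnaRecord]], list[RnaRecord]]:
    """Partition RNA records by (protein, sample label).

    Returns (per-(protein, sample) RNA records, ambiguous sink).  Every RNA
    record of every cluster appears exactly once across the two outputs.
    """
    by_key: dict[tuple[str, Optional[str]], list[RnaRecord]] = defaultdict(list)
    ambiguous: list[RnaRecord] = []
    for cl, asg in zip(clusters, assignments):
        if cl.barcode_string() != asg.barcode:
            raise ValueError("clusters and assignments are not aligned")
        if asg.assigned:
            by_key[(asg.protein, asg.sample_label)].extend(cl.rnas)
        else:
            ambiguous.extend(cl.rnas)
    return dict(by_key), ambiguous


def bead_cluster_counts(assignments: Iterable[ProteinAssignment]) -> pd.DataFrame:
    """Assigned clusters per (protein, sample); the bead-count normalizer.

    AMBIGUOUS clusters are never counted.  Columns: protein, sample_label,
    n_clusters.
    """
    counts: Counter[tuple[str, Optional[str]]] = Counter()
    for asg in assignments:
        if asg.assigned:
            counts[(asg.protein, asg.sample_label)] += 1
    rows = [
        {"protein": p, "sample_label": s, "n_clusters": c}
        for (p, s), c in sorted(counts.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))
    ]
    return pd.DataFrame(rows, columns=["protein", "sample_label", "n_clusters"])


def assignments_table(assignments: Iterable[ProteinAssignment]) -> pd.DataFrame:
    """All vote statistics as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "barcode": a.barcode,
                "protein": a.protein,
                "n_oligos": a.n_oligos,
                "top_fraction": a.top_fraction,
                "n_rnas": a.n_rnas,
                "sample_label": a.sample_label,
            }
            for a in assignments
        ],
        columns=["barcode", "protein", "n_oligos", "top_fraction", "n_rnas", "sample_label"],
    )
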