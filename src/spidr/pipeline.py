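"""End-to-end orchestration: reads -> clusters -> assignments -> peaks.

Glue between the stage modules, used by the command-line interface and by
scripted analyses.  Per-protein enrichment seeds are spawned from one
root seed via SeedSequence in sorted key order, so results are identical
regardless of execution order or parallelism.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import barcodes as bc
from . import clusters as cl
from . import enrich as en
from .scheme import BarcodeScheme


def load_antibody_tags(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["antibody"], df["sequence"]))


@dataclass
class ClusteredExperiment:
    clusters: list[cl.SpidrCluster]
    assignments: list[assign_mod.ProteinAssignment]
    reads_by_key: dict[tuple[str, Optional[str]], list[cl.RnaRecord]]
    ambiguous_reads: list[cl.RnaRecord]
    log: cl.ClusterLog
    ligation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def bead_counts(self) -> pd.DataFrame:
        return assign_mod.bead_cluster_counts(self.assignments)


def cluster_experiment(
    oligo_fastq: tuple[str | Path, str | Path],
    rna_sam: str | Path,
    scheme: BarcodeScheme,
    antibody_tags: dict[str, str],
    min_oligos: int = assign_mod.MIN_OLIGOS,
    frac_unique: float = assign_mod.FRAC_UNIQUE,
    max_rnas: int = assign_mod.MAX_RNAS,
) -> ClusteredExperiment:
    """Barcode-ID the oligo library, merge with aligned RNA, assign proteins."""
    tagged = list(
        bc.identify_all(bc.read_fastq_pairs(*oligo_fastq), scheme, antibody_tags)
    )
    ligation = bc.ligation_report(tagged, scheme)
    clusters, log = cl.build_clusters(tagged, cl.rna_records_from_sam(rna_sam))
    clusters, log = cl.filter_barcode_strings(clusters, scheme, log)
    clusters = [cl.dedup_cluster(c) for c in clusters]
    assignments = assign_mod.assign_all(clusters, min_oligos, frac_unique, max_rnas)
    reads_by_key, ambiguous = assign_mod.split_by_protein(clusters, assignments)
    return ClusteredExperiment(
        clusters=clusters,
        assignments=assignments,
        reads_by_key=reads_by_key,
        ambiguous_reads=ambiguous,
        log=log,
        ligation=ligation,
    )


def readsets_by_key(
    exp: ClusteredExperiment, genome: en.Genome
) -> dict[tuple[str, Optional[str]], en.ReadSet]:
    return {
        key: en.ReadSet.from_records(records, genome)
        for key, records in sorted(exp.reads_by_key.items(), key=lambda kv: _key_order(kv[0]))
        if records
    }


def _key_order(key: tuple[str, Optional[str]]) -> tuple[str, str]:
    protein, sample = key
    return (protein, "" if sample is None else sample)


def enrich_all(
    readsets: dict[tuple[str, Optional[str]], en.ReadSet],
    window: int = en.DEFAULT_WINDOW,
    n_perms: int = en.DEFAULT_N_PERMS,
    seed: int = 0,
    min_reads: int = en.MIN_READS,
    alpha: float = en.ALPHA,
) -> dict[tuple[str, Optional[str]], dict[str, pd.DataFrame]]:
    """Permutation enrichment and peaks for every (protein, sample).

    The background pool for a protein is the concatenation of all *other*
    proteins' reads within the same sample (negative controls included).
    Returns per key a dict with 'stats' and 'peaks' tables.
    """
    keys = sorted(readsets, key=_key_order)
    children = np.random.SeedSequence(seed).spawn(len(keys))
    out: dict[tuple[str, Optional[str]], dict[str, pd.DataFrame]] = {}
    for key, seed_child in zip(keys, children):
        protein, sample = key
        others = [
            rs for k, rs in readsets.items() if k[0] != protein and k[1] == sample
        ]
        if not others:
            continue
        pool = en.ReadSet.concat(others)
        target = readsets[key]
        if len(target) == 0 or len(pool) < len(target):
            continue
        rng = np.random.default_rng(seed_child)
        stats = en.run_enrichment(
            target, pool, window=window, n_perms=n_perms, rng=rng
        )
        stats = stats.assign(protein=protein, sample=sample)
        out[key] = {"stats": stats, "peaks": en.call_peaks(stats, min_reads, alpha)}
    return out


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, paths: list[Path], manifest_name: str = "manifest.json") -> Path:
    out_dir = Path(out_dir)
    entries = [
        {"path": str(p.relative_to(out_dir)), "sha256": sha256_file(p)}
        for p in sorted(paths)
    ]
    manifest = out_dir / manifest_name
    manifest.write_text(json.dumps(entries, indent=2) + "\n")
    return manifest
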