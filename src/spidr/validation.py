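"""Synthetic benchmark studies: end-to-end calibration of the pipeline.

Each study simulates an experiment with known truth, runs the full
pipeline (barcode identification, clustering, assignment, enrichment) and
measures how well the truth is recovered.  The default arguments define
the study conditions; all randomness derives from the single ``seed``
argument, so a study is reproducible from one integer.

Studies
-------
* null calibration -- no planted signal: the per-protein fraction of grid
  windows called as peaks (>=10 reads and p < 0.05) must stay at or below
  the nominal level.
* planted-peak recovery -- 50 footprints at 10-fold enrichment: recall of
  planted windows and precision of called peaks against per-read truth.
* assignment accuracy -- median-4-tag clusters with 5% crosstalk:
  agreement of protein calls with the bead truth table.
* truncation resolution -- one crosslink site per protein with half the
  planted reads truncated at it: is the planted nucleotide the argmax of
  single-nucleotide enrichment?
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import numpy as np

from . import enrich as en
from . import pipeline as pl
from . import simgen

TEN_PROTEINS = tuple([f"RBP{i}" for i in range(1, 9)] + ["IgG", "GFP"])


def _pipeline_readsets(res: simgen.SimResult):
    exp = pl.cluster_experiment(
        res.oligo_fastq, res.rna_sam, res.scheme, res.antibody_tags
    )
    genome = en.Genome.from_fasta(res.genome_fasta)
    return exp, genome, pl.readsets_by_key(exp, genome)


def null_calibration_study(
    seed: int,
    out_dir: Optional[str | Path] = None,
    n_beads: int = 18_200,
    genome_length: int = 100_000,
    n_perms: int = 100,
    window: int = en.DEFAULT_WINDOW,
    min_reads: int = en.MIN_READS,
    alpha: float = en.ALPHA,
) -> dict:
    """Null peak-call rate per protein on a signal-free experiment.

    ~200k RNA reads over 10 proteins on a 100 kb contig at the defaults.
    Returns the worst per-protein fraction of grid windows that pass the
    combined peak criterion; under a valid permutation null this stays at
    or below alpha (up to Monte-Carlo noise).
    """
    with _workdir(out_dir) as work:
        cfg = simgen.SimConfig(
            n_beads=n_beads,
            antibodies=TEN_PROTEINS,
            rna_reads_mean=10.0,
            genome_length=genome_length,
            tags_per_round=24,
            seed=seed,
        )
        res = simgen.make_null_experiment(cfg, work)
        _exp, genome, readsets = _pipeline_readsets(res)
        results = pl.enrich_all(
            readsets, window=window, n_perms=n_perms, seed=seed + 1,
            min_reads=min_reads, alpha=alpha,
        )
        grid = en.WindowGrid(genome, window)
        n_windows = 2 * grid.total  # both strands
        rates = {}
        for (protein, _sample), tables in results.items():
            rates[protein] = len(tables["peaks"]) / n_windows
        return {
            "rates": rates,
            "worst_rate": max(rates.values()) if rates else 0.0,
            "n_windows": n_windows,
            "n_rna_reads": len(res.truth.rna_reads),
            "alpha": alpha,
        }


def _planted_sites_50(proteins: tuple[str, ...]) -> tuple[simgen.PlantedSite, ...]:
    positions = [(1000 + i * 560) // 100 * 100 for i in range(50)]
    return tuple(
        simgen.PlantedSite(
            protein=proteins[i % 8],
            reference="chrS",
            position=positions[i],
            footprint=100,
            fold=10.0,
            truncation_fraction=0.5,
            strand="+",
        )
        for i in range(50)
    )


def planted_recovery_study(
    seed: int,
    out_dir: Optional[str | Path] = None,
    n_beads: int = 2000,
    genome_length: int = 30_000,
    n_perms: int = 100,
) -> dict:
    """Recall and precision of peak calling on 50 planted footprints.

    Recall: fraction of planted footprints overlapped by a called peak of
    the right protein.  Precision: fraction of called peaks containing at
    least one planted read of that protein (truth-table provenance; reads
    extend past the footprint, so flanking windows holding planted reads
    are genuine signal).
    """
    with _workdir(out_dir) as work:
        sites = _planted_sites_50(TEN_PROTEINS)
        cfg = simgen.SimConfig(
            n_beads=n_beads,
            antibodies=TEN_PROTEINS,
            rna_reads_mean=10.0,
            genome_length=genome_length,
            planted_sites=sites,
            tags_per_round=24,
            seed=seed,
        )
        res = simgen.simulate_experiment(cfg, work)
        _exp, _genome, readsets = _pipeline_readsets(res)
        results = pl.enrich_all(readsets, n_perms=n_perms, seed=seed + 1)

        truth = res.truth
        planted = truth.rna_reads[truth.rna_reads.site_id >= 0]
        site_protein = dict(zip(truth.sites.site_id, truth.sites.protein))
        tp = fp = 0
        recovered: set[tuple[str, int]] = set()
        for (protein, _sample), tables in results.items():
            protein_reads = planted[planted.site_id.map(site_protein) == protein]
            for row in tables["peaks"].itertuples():
                contains = (
                    (protein_reads.start < row.end)
                    & (protein_reads.end > row.start)
                    & (protein_reads.strand == row.strand)
                ).any()
                tp += bool(contains)
                fp += not contains
            for s in truth.sites.itertuples():
                if s.protein != protein:
                    continue
                m = tables["peaks"]
                if (
                    (m.start < s.position + s.footprint)
                    & (m.end > s.position)
                    & (m.strand == s.strand)
                ).any():
                    recovered.add((s.protein, int(s.position)))
        site_reads = planted.groupby("site_id").size()
        return {
            "n_sites": len(sites),
            "recall": len(recovered) / len(sites),
            "precision": tp / max(1, tp + fp),
            "n_called": tp + fp,
            "min_site_reads": int(site_reads.min()) if len(site_reads) else 0,
            "median_site_reads": float(site_reads.median()) if len(site_reads) else 0.0,
        }


def assignment_accuracy_study(
    seed: int,
    out_dir: Optional[str | Path] = None,
    n_beads: int = 5000,
    crosstalk_rate: float = 0.05,
) -> dict:
    """Protein-call accuracy against the bead truth table.

    Clusters simulated at the defaults (tag count median 4, 5% crosstalk);
    accuracy is measured over non-ambiguous assignments whose barcode maps
    to exactly one truth bead.
    """
    with _workdir(out_dir) as work:
        cfg = simgen.SimConfig(
            n_beads=n_beads,
            antibodies=TEN_PROTEINS,
            crosstalk_rate=crosstalk_rate,
            tags_per_cluster_mean=4.0,
            rna_reads_mean=5.0,
            genome_length=20_000,
            tags_per_round=24,
            seed=seed,
        )
        res = simgen.simulate_experiment(cfg, work)
        exp = pl.cluster_experiment(
            res.oligo_fastq, res.rna_sam, res.scheme, res.antibody_tags
        )
        barcode_counts = res.truth.beads["barcode"].value_counts()
        unique_barcodes = set(barcode_counts[barcode_counts == 1].index)
        truth_map = dict(zip(res.truth.beads.barcode, res.truth.beads.antibody))
        n_ok = n_bad = 0
        for a in exp.assignments:
            if not a.assigned or a.barcode not in unique_barcodes:
                continue
            if truth_map[a.barcode] == a.protein:
                n_ok += 1
            else:
                n_bad += 1
        tags_per_bead = res.truth.oligo_reads[
            res.truth.oligo_reads.duplicate_of == ""
        ].groupby("bead_id").size()
        return {
            "n_assigned": n_ok + n_bad,
            "accuracy": n_ok / max(1, n_ok + n_bad),
            "median_tags_per_bead": float(tags_per_bead.median()),
        }


def truncation_resolution_study(
    seed: int,
    out_dir: Optional[str | Path] = None,
    n_proteins: int = 20,
    n_beads: int = 6000,
    genome_length: int = 30_000,
    n_perms: int = 100,
) -> dict:
    """Single-nucleotide recovery of planted crosslink sites.

    One site per protein, truncation_fraction 0.5; a site is recovered
    when the planted nucleotide is the argmax of the protein's truncation
    enrichment on the contig (same strand).
    """
    with _workdir(out_dir) as work:
        proteins = tuple([f"RBP{i}" for i in range(1, n_proteins + 1)] + ["IgG", "GFP"])
        sites = tuple(
            simgen.PlantedSite(
                protein=proteins[i],
                reference="chrS",
                position=1009 + i * ((genome_length - 2500) // n_proteins),
                footprint=100,
                fold=25.0,
                truncation_fraction=0.5,
                strand="+",
            )
            for i in range(n_proteins)
        )
        cfg = simgen.SimConfig(
            n_beads=n_beads,
            antibodies=proteins,
            rna_reads_mean=10.0,
            genome_length=genome_length,
            planted_sites=sites,
            tags_per_round=24,
            seed=seed,
        )
        res = simgen.simulate_experiment(cfg, work)
        _exp, _genome, readsets = _pipeline_readsets(res)
        keys = sorted(readsets, key=lambda k: k[0])
        children = np.random.SeedSequence(seed + 1).spawn(len(keys))
        n_correct = 0
        trunc_reads = []
        for key, child in zip(keys, children):
            protein = key[0]
            site = next((s for s in sites if s.protein == protein), None)
            if site is None:
                continue
            others = en.ReadSet.concat(
                [rs for k, rs in readsets.items() if k[0] != protein]
            )
            profile = en.truncation_enrichment(
                readsets[key], others, n_perms=n_perms,
                rng=np.random.default_rng(child),
            )
            plus = profile.table[profile.table.strand == site.strand]
            if plus.empty:
                continue
            best = plus.loc[plus["enrichment"].idxmax()]
            n_correct += int(best["position"]) == site.position
            at_site = plus[plus["position"] == site.position]
            trunc_reads.append(int(at_site["observed"].iloc[0]) if len(at_site) else 0)
        return {
            "n_sites": len(sites),
            "argmax_accuracy": n_correct / len(sites),
            "min_truncation_reads": min(trunc_reads) if trunc_reads else 0,
            "median_truncation_reads": (
                float(np.median(trunc_reads)) if trunc_reads else 0.0
            ),
        }


class _workdir:
    """Temporary directory unless an explicit output directory is given."""

    def __init__(self, out_dir: Optional[str | Path]):
        self.out_dir = out_dir
        self._tmp: Optional[tempfile.TemporaryDirectory] = None

    def __enter__(self) -> Path:
        if self.out_dir is not None:
            p = Path(self.out_dir)
            p.mkdir(parents=True, exist_ok=True)
            return p
        self._tmp = tempfile.TemporaryDirectory(prefix="spidr-study-")
        return Path(self._tmp.name)

    def __exit__(self, *exc) -> None:
        if self._tmp is not None:
            self._tmp.cleanup()
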