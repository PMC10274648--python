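"""Shared fixtures: hand-built schemes and small simulated experiments."""

from __future__ import annotations

import pytest

from spidr import simgen
from spidr.scheme import BarcodeScheme, RoundCategory, RoundSpec


@pytest.fixture(scope="session")
def toy_scheme() -> BarcodeScheme:
    """Three rounds of hand-picked tags (pairwise Hamming distance >= 3)."""
    return BarcodeScheme(
        rounds=(
            RoundSpec(
                name="round1",
                category=RoundCategory.ODD,
                tags={"A1": "AAAAAA", "A2": "CCCCCC", "A3": "GGGGGG"},
            ),
            RoundSpec(
                name="round2",
                category=RoundCategory.EVEN,
                tags={"B1": "AAACCC", "B2": "CCCAAA", "B3": "GGGTTT"},
            ),
            RoundSpec(
                name="round3",
                category=RoundCategory.TERMINAL,
                tags={"T1": "AATTGG", "T2": "TTAACC"},
            ),
        ),
        umi_length=4,
    )


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small complete experiment with one planted site."""
    cfg = simgen.SimConfig(
        n_beads=300,
        rna_reads_mean=8.0,
        genome_length=20_000,
        planted_sites=(
            simgen.PlantedSite(
                protein="RBP1", reference="chrS", position=5000,
                footprint=100, fold=10.0, truncation_fraction=0.5,
            ),
        ),
        seed=42,
    )
    return simgen.simulate_experiment(cfg, tmp_path_factory.mktemp("sim_small"))


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """No ligation failures, no crosstalk, no PCR duplicates: lossless truth."""
    cfg = simgen.SimConfig(
        n_beads=200,
        rna_reads_mean=5.0,
        genome_length=20_000,
        ligation_failure_rate=0.0,
        crosstalk_rate=0.0,
        pcr_duplication_rate=0.0,
        seed=7,
    )
    return simgen.simulate_experiment(cfg, tmp_path_factory.mktemp("sim_clean"))


@pytest.fixture(scope="session")
def sim_big_beads(tmp_path_factory):
    """Many beads, no RNA: for tag-count and ligation-efficiency statistics."""
    cfg = simgen.SimConfig(
        n_beads=12_000,
        rna_reads_mean=0.0,
        genome_length=20_000,
        ligation_failure_rate=0.1,
        pcr_duplication_rate=0.0,
        seed=11,
    )
    return simgen.simulate_experiment(cfg, tmp_path_factory.mktemp("sim_big"))


@pytest.fixture(scope="session")
def annotation_db(tmp_path_factory):
    from spidr.annotate import AnnotationDB

    gtf = tmp_path_factory.mktemp("anno") / "annotation.gtf"
    gtf.write_text("\n".join(simgen.build_annotation("chrS", 100_000)) + "\n")
    return AnnotationDB.from_gtf(gtf)
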