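"""Shared fixtures: a small synthetic cohort and one full default run."""

from __future__ import annotations

import time

import pytest

from circnet.config import PipelineConfig
from circnet.pipeline import Pipeline
from circnet.simulate import SimConfig, generate_genome_and_models, simulate_all


def small_sim_config(seed: int = 3, **overrides) -> SimConfig:
    """A fast, reduced cohort that still exercises every feature."""
    kwargs = dict(
        seed=seed,
        n_samples_per_group=4,
        chrom_lengths={"chr1": 120_000},
        n_genes=8,
        n_circ_true=16,
        n_mirnas=6,
        n_sponge_circ=2,
        mirnas_per_sponge=1,
        seed_planted_sites=5,
        n_universe_genes=80,
        n_de_genes=15,
        n_pathways=6,
        n_enriched_pathways=2,
        pathway_size=12,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Emitted files + ground truth for the reduced cohort."""
    outdir = tmp_path_factory.mktemp("small_sim")
    manifest = simulate_all(small_sim_config(), outdir)
    return manifest


@pytest.fixture(scope="session")
def small_truth():
    """In-memory ground truth only (no files) for the reduced cohort."""
    truth = generate_genome_and_models(small_sim_config())
    truth.ensure_expression()
    return truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default 10+10 cohort, fixed seed.

    Returns (pipeline, wall-clock seconds). Session-scoped because the
    prediction stage dominates the suite's runtime.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(outdir=str(outdir), seed=1)
    pipe = Pipeline(cfg)
    t0 = time.perf_counter()
    pipe.run_all()
    elapsed = time.perf_counter() - t0
    return pipe, elapsed
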