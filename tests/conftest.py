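"""Shared fixtures: one default synthetic study and one full pipeline run
per session; everything is generated programmatically, no stored data."""

from __future__ import annotations

import pathlib

import pytest

from cghkit.pipeline import PipelineConfig, run_pipeline
from cghkit.simulate import SimConfig, generate_genome_pair


@pytest.fixture(scope="session")
def default_study():
    """Default-condition genome pair + truth (seed fixed)."""
    cfg = SimConfig(seed=11)
    pair, truth = generate_genome_pair(cfg)
    return cfg, pair, truth


@pytest.fixture(scope="session")
def clean_pair():
    """Identity-condition pair: nothing deleted, nothing divergent."""
    cfg = SimConfig(n_islands=0, n_single_deletions=0, n_divergent=0,
                    divergence_rate=0.0, seed=7)
    pair, truth = generate_genome_pair(cfg)
    return cfg, pair, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-condition pipeline run shared across tests."""
    outdir = pathlib.Path(tmp_path_factory.mktemp("run"))
    cfg = PipelineConfig(seed=11)
    manifest = run_pipeline(cfg, outdir)
    return cfg, outdir, manifest
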