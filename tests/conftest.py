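"""Shared fixtures: seeded synthetic bundles reused across the suite."""

from __future__ import annotations

import pytest

from rlpscape import pipeline, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """The reference study layout (3 chromosomes, ~280 genes) with noise."""
    genome, truth = simulate.make_genome(simulate.GenomeParams.default(), seed=11)
    return genome, truth


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced layout for fast structural tests."""
    genome, truth = simulate.make_genome(simulate.GenomeParams.small(), seed=5)
    return genome, truth


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline output on a noiseless synthetic genome.

    Returns (genome, truth, summary): the end-to-end ground-truth recovery
    scenario shared by the pipeline and acceptance tests.
    """
    genome, truth = simulate.make_genome(simulate.GenomeParams.noiseless(), seed=7)
    nw, w = simulate.make_expression(genome, truth, noise_sd=0.0)
    cfg = pipeline.PipelineConfig(seed=7, n_perm=300)
    outdir = tmp_path_factory.mktemp("noiseless_run")
    summary = pipeline.run_all(genome, cfg, outdir, nw, w)
    return genome, truth, summary
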