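import pytest

from pa_surveil import pipeline, simdata


@pytest.fixture(scope="session")
def toy():
    """Default toy genome, annotations and truth table (seed 1)."""
    return simdata.build_toy_genome(seed=1)


@pytest.fixture(scope="session")
def small_run():
    """A reduced-depth end-to-end pipeline run shared by unit tests."""
    cfg = simdata.SimConfig(n_read_pairs=30_000, seed=1)
    return pipeline.run_pipeline(cfg=cfg, seed=1)


@pytest.fixture(scope="session")
def full_run():
    """Full-depth (2 x 10^5 pairs per condition) pipeline run with planted
    effects: leaders at fold 60, snoRNA offsets at fold 9, 5'ETS A0 at fold
    8, null mRNA complement at fold 1."""
    return pipeline.run_pipeline(seed=1)


def truth_by_id(truth):
    return {r.site_id: r for r in truth.records}
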