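import numpy as np
import pytest

import lobulesim as ls

ENSEMBLE_SEEDS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)


@pytest.fixture(scope="session")
def default_ensemble():
    """Ten default 120-step runs keyed by seed (seed 1 with a step-100
    snapshot), shared by the dynamics and acceptance tests."""
    runs = {}
    for seed in ENSEMBLE_SEEDS:
        snaps = (100,) if seed == 1 else ()
        cfg = ls.default_config(seed=seed, snapshot_steps=snaps)
        runs[seed] = ls.run(cfg)
    return runs


@pytest.fixture(scope="session")
def injection_arms():
    """2- versus 3-injection arms (10-step interval, horizon 100)."""
    arms = {}
    for n_inj in (2, 3):
        for seed in ENSEMBLE_SEEDS:
            cfg = ls.default_config(seed=seed, n_steps=100)
            cfg.schedule.n_injections = n_inj
            arms[(n_inj, seed)] = ls.run(cfg).timecourse
    return arms


@pytest.fixture(scope="session")
def interval_ensemble():
    """Endpoint collagen per injection interval, 5 seeds each."""
    out = {}
    for interval in (6, 10, 14, 18):
        for seed in ENSEMBLE_SEEDS:
            cfg = ls.default_config(seed=seed, interval=interval)
            out[(interval, seed)] = ls.run(cfg).timecourse
    return out


@pytest.fixture
def small_grid():
    """A bare 21x21 grid with a central vein block and two portal tracts."""
    geo = ls.default_geometry(height=21, width=21, portal_inset=0.1)
    return ls.LobuleGrid(
        21, 21, geo.central_vein_sites, geo.portal_sites, portal_tracts=geo.portal_tracts
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
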