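import logging

import numpy as np
import pytest

from metafoci import (
    MaskGeometry,
    MCMCConfig,
    Priors,
    ScenarioConfig,
    generate_database,
    make_toy_mask_atlas,
)
from metafoci.mcmc import run_mcmc

logging.getLogger("metafoci").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_world():
    """Default toy mask/atlas plus geometry (40x48x40 grid, 2 mm voxels)."""
    cfg = ScenarioConfig()
    mask, atlas = make_toy_mask_atlas(cfg)
    return cfg, mask, atlas, MaskGeometry(mask)


@pytest.fixture(scope="session")
def recovery_fit():
    """One-category recovery scenario (3 centers, sigma 8, 6-sigma apart,
    20 studies) fitted at a compact chain length; reused by several tests."""
    cfg = ScenarioConfig(n_categories=1, studies_per_category=20)
    db, truth, mask, atlas = generate_database(cfg, seed=1)
    geom = MaskGeometry(mask)
    mc = MCMCConfig(n_iter=1200, burn_in=400, thinning=1, seed=3)
    data = {c: [r.foci for r in db.by_category(c)] for c in db.categories}
    samples = run_mcmc(data, geom, Priors(), mc)
    return dict(config=cfg, db=db, truth=truth, mask=mask, atlas=atlas,
                geom=geom, samples=samples)


@pytest.fixture(scope="session")
def separated_fit():
    """Three well-separated categories fitted compactly (classification toys)."""
    cfg = ScenarioConfig(n_categories=3, studies_per_category=10, n_centers=2,
                         sigma_study=6.0, separation=36.0)
    db, truth, mask, atlas = generate_database(cfg, seed=7)
    geom = MaskGeometry(mask)
    mc = MCMCConfig(n_iter=700, burn_in=300, thinning=1, seed=11)
    data = {c: [r.foci for r in db.by_category(c)] for c in db.categories}
    samples = run_mcmc(data, geom, Priors(), mc)
    return dict(config=cfg, db=db, truth=truth, mask=mask, atlas=atlas,
                geom=geom, samples=samples)
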