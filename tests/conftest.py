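import logging

import numpy as np
import pandas as pd
import pytest

from stopover_rsf.selection_stats import fit_pca
from stopover_rsf.synthetic_world import WorldConfig, generate_raster, simulate_tracks

logging.getLogger("stopover_rsf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def demo_world():
    """One demo-scale world shared by the slower integration tests."""
    cfg = WorldConfig.demo(seed=1)
    rng = np.random.default_rng(1)
    raster = generate_raster(cfg, rng)
    fixes, truths = simulate_tracks(cfg, raster, rng)
    return cfg, raster, fixes, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_glmm_table(seed=0, n_birds=9, rows_per_bird=9, sigma_u=0.5, beta=(), use_ratio=1 / 3):
    """Grouped binary table with iid normal scores and a known random intercept.

    With ``beta=()`` the response depends only on the base rate and the bird
    effect, so the marginal intercept is ln(use_ratio/(1-use_ratio)).
    """
    rng = np.random.default_rng(seed)
    b0 = np.log(use_ratio / (1.0 - use_ratio))
    terms = [f"PC{i + 1}" for i in range(5)]
    rows = []
    for g in range(n_birds):
        u = rng.normal(0.0, sigma_u)
        for _ in range(rows_per_bird):
            x = rng.normal(size=5)
            eta = b0 + u + sum(bj * xj for bj, xj in zip(beta, x))
            y = float(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append({"bird_id": f"B{g:02d}", "y": y, "lon": rng.uniform(0, 40), "lat": rng.uniform(40, 60),
                         **dict(zip(terms, x))})
    return pd.DataFrame(rows)


@pytest.fixture()
def glmm_table():
    return make_glmm_table(seed=7)


@pytest.fixture()
def random_compositions(rng):
    """Random closed composition table (rows sum to 100) with 6 classes."""
    labels = ["CRO2", "MOS1", "MOS2", "BFO2", "MFO1", "WATE"]
    raw = rng.dirichlet(np.ones(6) * 1.5, size=50) * 100.0
    df = pd.DataFrame(raw, columns=labels)
    df.insert(0, "point_id", [f"p{i}" for i in range(50)])
    df.insert(1, "bird_id", ["B1"] * 50)
    df.insert(2, "label", ["use"] * 50)
    return df


@pytest.fixture()
def pca_model(random_compositions):
    return fit_pca(random_compositions, k=5)
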