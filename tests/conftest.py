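import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from felicoex import diet, scr, synth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def traits():
    return diet.load_prey_traits()


@pytest.fixture(scope="session")
def leopard_scats():
    return diet.load_scat_reconstruction("leopard")


@pytest.fixture(scope="session")
def goldencat_scats():
    return diet.load_scat_reconstruction("golden_cat")


@pytest.fixture(scope="session")
def published_table():
    return diet.load_published_diet_table()


@pytest.fixture(scope="session")
def nested_grid():
    return synth.make_nested_grid(seed=3)


def make_small_history(seed, pmix=0.5, g0=0.35, sigma=800.0, n_occasions=8,
                       density_per_km2=2.5, sex_known=True):
    """Compact simulated capture history on a 3×3 km trap grid (fast fits)."""
    rng = np.random.default_rng(seed)
    traps = np.array([[i * 1000.0, j * 1000.0] for i in range(3) for j in range(3)])
    buf = 2500.0
    lo, hi = traps.min(0) - buf, traps.max(0) + buf
    area = (hi - lo).prod() / 1e6
    n_total = rng.poisson(density_per_km2 * area)
    centers = rng.uniform(lo, hi, (n_total, 2))
    female = rng.uniform(size=n_total) < pmix
    rows, det = [], 0
    for i in range(n_total):
        d = np.sqrt(((traps - centers[i]) ** 2).sum(1))
        p = g0 * np.exp(-d * d / (2 * sigma**2))
        hits = rng.uniform(size=(n_occasions, len(traps))) < p[None, :]
        occ, trap = np.nonzero(hits)
        if len(occ) == 0:
            continue
        det += 1
        sex = ("F" if female[i] else "M") if sex_known else "U"
        for o, k in zip(occ, trap):
            rows.append((f"I{det:03d}", sex, int(o) + 1, int(k)))
    df = pd.DataFrame(rows, columns=["individual", "sex", "occasion", "trap"])
    inds = list(pd.unique(df["individual"]))
    sex_arr = np.array([df.loc[df["individual"] == i, "sex"].iloc[0] for i in inds])
    return scr.CaptureHistory(
        individuals=inds, sex=sex_arr,
        detections=df[["individual", "occasion", "trap"]],
        n_occasions=n_occasions, traps=traps,
    )


@pytest.fixture(scope="session")
def small_history():
    return make_small_history(12345)


@pytest.fixture(scope="session")
def small_mask(small_history):
    return scr.build_mask(small_history.traps, 2.5, 1.0)
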