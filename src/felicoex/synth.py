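"""Synthetic datasets with the statistical structure the analyses assume.

The generators emulate a two-site tropical-forest camera-trap study design: a
nested station grid (a 1 km sub-grid for the mesocarnivore inside a 2 km grid
sized for the apex carnivore), multi-month daily survey occasions, SCR capture
histories under the half-normal Bernoulli encounter model, two-species
time-stamped detections from nonhomogeneous Poisson processes with
crepuscular/diurnal diel intensity, and small scat datasets.

Defaults are presets taken from the study conditions they emulate (leopard
density ≈ 5–6 / 100 km², sex-specific σ of 1.5–3.4 km, 63-station grids,
110–200 occasions, 9–16 scats with 1–3 items).  All generators are
deterministic given their seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmso import CTMSOData, StationData, fourier_design, psi_from_f, time_since_covariate
from .scr import CaptureHistory, halfnormal_g


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GridConfig:
    inner_spacing_km: float = 1.0
    inner_cells: int = 6  # inner grid is inner_cells × inner_cells
    outer_spacing_km: float = 2.0
    outer_cells: int = 6  # outer grid extent in 2 km cells per side
    jitter_m: float = 200.0


@dataclass
class SCRTruth:
    density_per_100km2: float = 6.11
    g0: tuple = (0.009, 0.012)  # (female, male)
    sigma_m: tuple = (1570.0, 3406.0)
    pmix: float = 0.77  # female proportion
    n_occasions: int = 110
    sim_buffer_km: float = 16.0  # centers simulated on this buffered extent
    p_sex_unknown: float = 0.0


@dataclass
class CTMSOTruth:
    beta_f1: dict = field(default_factory=lambda: {"(Intercept)": 1.2, "dist_linear": -0.5})
    beta_f2: dict = field(default_factory=lambda: {"(Intercept)": 0.8, "dist_linear": -0.5, "prey_rai": 0.5})
    beta_f12: dict = field(default_factory=lambda: {"(Intercept)": 0.0, "dist_linear": 0.8})
    # diel shapes: species 1 diurnal (midday first-harmonic peak),
    # species 2 crepuscular (second harmonic peaking at 06:00 and 18:00)
    alpha: dict = field(default_factory=lambda: {"golden_cat": -6.8, "leopard": -6.6})
    gamma: dict = field(
        default_factory=lambda: {
            "golden_cat": (-1.0, 0.0, 0.0, 0.0),
            "leopard": (0.0, 0.0, -0.8, 0.0),
        }
    )
    eta: float = 0.0  # lag effect of species 2 on species 1 (per raw hour)
    u_max: float = 72.0
    survey_days: int = 150


@dataclass
class DietTruth:
    prey_probs: dict = field(default_factory=dict)  # taxon -> probability
    n_scats: int = 16
    extra_item_p: float = 0.19  # items per scat = 1 + Binomial(2, p)
    predator: str = "golden_cat"


@dataclass
class SimConfig:
    seed: int = 1
    grid: GridConfig = field(default_factory=GridConfig)
    scr: SCRTruth = field(default_factory=SCRTruth)
    ctmso: CTMSOTruth = field(default_factory=CTMSOTruth)
    diet: DietTruth = field(default_factory=DietTruth)

    def rng(self, stream: str) -> np.random.Generator:
        """One independent, reproducible random stream per generator."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


def preset(name: str, seed: int = 1) -> SimConfig:
    """Named presets for the two survey sites and a matching diet profile.

    ``nnnp``: 110 occasions, strongly female-biased sex ratio and contrasting
    sex-specific movement; ``cib``: 198 occasions, near-parity and similar
    movement between the sexes.
    """
    name = name.lower()
    if name == "nnnp":
        scr_truth = SCRTruth(
            density_per_100km2=6.11, g0=(0.009, 0.012), sigma_m=(1570.0, 3406.0),
            pmix=0.77, n_occasions=110,
        )
    elif name == "cib":
        scr_truth = SCRTruth(
            density_per_100km2=5.52, g0=(0.007, 0.007), sigma_m=(2965.0, 2480.0),
            pmix=0.5, n_occasions=198,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    diet = DietTruth(
        prey_probs={
            "Murinae": 0.31, "Philantomba monticola": 0.25, "Cephalophus callipygus": 0.10,
            "Cricetomys emini": 0.09, "Cercopithecus nictitans": 0.06,
            "Atherurus africanus": 0.06, "Genetta servalina": 0.06,
            "Cephalophus sp.": 0.03, "Birds": 0.04,
        },
        n_scats=16,
        extra_item_p=0.19,
        predator="golden_cat",
    )
    return SimConfig(seed=seed, scr=scr_truth, diet=diet)


# ---------------------------------------------------------------------------
# station grid


def make_nested_grid(config: GridConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Nested station grid: fine sub-grid embedded in a coarse grid.

    One station per cell of a ``outer_cells²`` coarse grid, except inside the
    central block occupied by the fine ``inner_cells²`` sub-grid, whose cells
    each get a station instead.  Defaults yield 63 stations: 36 inner 1 km
    cells (36 km²) plus 27 outer 2 km cells (the 6×6 coarse grid covers
    144 km²).  Stations are jittered uniformly within ``jitter_m`` of cell
    centroids.  The linear forest feature runs along x = 0, so
    ``dist_linear_km`` is the station's x coordinate in km.
    """
    cfg = config or GridConfig()
    rng = np.random.default_rng(seed)
    outer_m = cfg.outer_spacing_km * 1000.0
    inner_m = cfg.inner_spacing_km * 1000.0
    extent = cfg.outer_cells * outer_m
    inner_extent = cfg.inner_cells * inner_m
    if inner_extent > extent:
        raise ValueError("inner grid larger than outer grid")
    # center the inner block on whole outer cells
    inner_cells_span = inner_extent / outer_m
    if abs(inner_cells_span - round(inner_cells_span)) > 1e-9:
        raise ValueError("inner grid must tile whole outer cells")
    span = int(round(inner_cells_span))
    start_cell = (cfg.outer_cells - span) // 2
    lo = start_cell * outer_m
    hi = lo + inner_extent
    centers = []
    for ix in range(cfg.outer_cells):
        for iy in range(cfg.outer_cells):
            cx = (ix + 0.5) * outer_m
            cy = (iy + 0.5) * outer_m
            if lo <= cx <= hi and lo <= cy <= hi:
                continue  # replaced by the fine sub-grid
            centers.append((cx, cy))
    for ix in range(cfg.inner_cells):
        for iy in range(cfg.inner_cells):
            centers.append((lo + (ix + 0.5) * inner_m, lo + (iy + 0.5) * inner_m))
    centers = np.asarray(centers)
    theta = rng.uniform(0, 2 * math.pi, len(centers))
    r = cfg.jitter_m * np.sqrt(rng.uniform(0, 1, len(centers)))
    xy = centers + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    order = np.lexsort((xy[:, 0], xy[:, 1]))
    xy = xy[order]
    return pd.DataFrame(
        {
            "station_id": [f"S{i + 1:02d}" for i in range(len(xy))],
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
            "dist_linear_km": xy[:, 0] / 1000.0,
        }
    )


# ---------------------------------------------------------------------------
# SCR capture histories


def simulate_scr(
    config: SimConfig, stations: pd.DataFrame | None = None
) -> tuple[CaptureHistory, dict]:
    """Capture history under the half-normal Bernoulli SCR model.

    Activity centers are a homogeneous Poisson draw at the preset density over
    the trap bounding box buffered by ``sim_buffer_km`` (kept at least as wide
    as any fitted buffer to avoid edge bias); sexes are Bernoulli(pmix
    female); daily station-level detections are Bernoulli with half-normal
    probability.  Individuals never detected are dropped from the history but
    counted in the truth metadata.
    """
    t = config.scr
    rng = config.rng("scr")
    if stations is None:
        stations = make_nested_grid(config.grid, seed=config.rng("grid").integers(2**31))
    traps = stations[["x_m", "y_m"]].to_numpy(dtype=float)
    buf = t.sim_buffer_km * 1000.0
    lo = traps.min(axis=0) - buf
    hi = traps.max(axis=0) + buf
    area_km2 = (hi - lo).prod() / 1e6
    n_total = rng.poisson(t.density_per_100km2 / 100.0 * area_km2)
    centers = rng.uniform(lo, hi, size=(n_total, 2))
    female = rng.uniform(size=n_total) < t.pmix
    rows = []
    detected = 0
    for i in range(n_total):
        g0 = t.g0[0] if female[i] else t.g0[1]
        sig = t.sigma_m[0] if female[i] else t.sigma_m[1]
        d = np.sqrt(((traps - centers[i]) ** 2).sum(axis=1))
        p = halfnormal_g(d, g0, sig)
        hits = rng.uniform(size=(t.n_occasions, len(traps))) < p[None, :]
        occ, trap = np.nonzero(hits)
        if len(occ) == 0:
            continue
        detected += 1
        ind = f"I{detected:03d}"
        sex = "F" if female[i] else "M"
        if t.p_sex_unknown > 0 and rng.uniform() < t.p_sex_unknown:
            sex = "U"
        for o, k in zip(occ, trap):
            rows.append((ind, sex, int(o) + 1, k))
    truth = {
        "density_per_100km2": t.density_per_100km2,
        "n_simulated": int(n_total),
        "n_detected": detected,
        "sim_area_km2": float(area_km2),
        "pmix": t.pmix,
    }
    if detected == 0:
        hist = None
    else:
        df = pd.DataFrame(rows, columns=["individual", "sex", "occasion", "trap"])
        inds = list(pd.unique(df["individual"]))
        sex = np.array([df.loc[df["individual"] == i, "sex"].iloc[0] for i in inds])
        hist = CaptureHistory(
            individuals=inds,
            sex=sex,
            detections=df[["individual", "occasion", "trap"]],
            n_occasions=t.n_occasions,
            traps=traps,
        )
    return hist, truth


def capture_history_to_tables(hist: CaptureHistory, stations: pd.DataFrame):
    """Export a history as (captures, traps) CSV-schema DataFrames."""
    ids = stations["station_id"].to_numpy()
    sex_map = dict(zip(hist.individuals, hist.sex))
    captures = pd.DataFrame(
        {
            "individual_id": hist.detections["individual"].to_numpy(),
            "sex": [sex_map[i] if sex_map[i] != "U" else "" for i in hist.detections["individual"]],
            "occasion": hist.detections["occasion"].to_numpy(),
            "station_id": ids[hist.detections["trap"].to_numpy()],
        }
    )
    traps = stations[["station_id", "x_m", "y_m"]].copy()
    return captures, traps


# ---------------------------------------------------------------------------
# continuous-time two-species detections


def _thin_poisson(rng, window_h, log_rate_fn, log_rate_bound):
    t0, t1 = window_h
    n = rng.poisson(math.exp(log_rate_bound) * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    if n == 0:
        return cand
    accept = np.log(rng.uniform(size=n)) < log_rate_fn(cand) - log_rate_bound
    return cand[accept]


def simulate_ctmso(
    config: SimConfig, stations: pd.DataFrame | None = None
) -> tuple[CTMSOData, dict]:
    """Two-species detection-time data from the generative occupancy model.

    Station covariates (standardized internally): distance to the linear
    feature from the grid, a gamma-distributed prey RAI, and a two-level site
    indicator.  Latent states follow ψ(x); detection times are thinned
    nonhomogeneous Poisson draws, the subordinate species' intensity modulated
    by η times the (raw-hours) time since the last dominant-species detection.
    """
    t = config.ctmso
    rng = config.rng("ctmso")
    if stations is None:
        stations = make_nested_grid(config.grid, seed=config.rng("grid").integers(2**31))
    n = len(stations)
    raw = pd.DataFrame(
        {
            "dist_linear": stations["dist_linear_km"].to_numpy(),
            "prey_rai": rng.gamma(2.0, 4.0, n),
            "site": (np.arange(n) >= n // 2).astype(float),
        }
    )
    std = (raw - raw.mean()) / raw.std(ddof=1)

    def lin(beta: dict, frame: pd.DataFrame) -> np.ndarray:
        out = np.full(len(frame), beta.get("(Intercept)", 0.0))
        for k, v in beta.items():
            if k != "(Intercept)":
                out = out + v * frame[k].to_numpy()
        return out

    f1, f2, f12 = lin(t.beta_f1, std), lin(t.beta_f2, std), lin(t.beta_f12, std)
    p00, p10, p01, p11 = psi_from_f(f1, f2, f12)
    probs = np.stack([p00, p10, p01, p11], axis=1)
    states = np.array([rng.choice(4, p=probs[j]) for j in range(n)])
    z1 = np.isin(states, (1, 3))
    z2 = np.isin(states, (2, 3))
    window = (0.0, 24.0 * t.survey_days)
    sp1, sp2 = "golden_cat", "leopard"
    g1 = np.asarray(t.gamma[sp1], dtype=float)
    g2 = np.asarray(t.gamma[sp2], dtype=float)
    station_data = []
    for j in range(n):
        times2 = np.empty(0)
        if z2[j]:
            bound2 = t.alpha[sp2] + np.abs(g2).sum()
            times2 = _thin_poisson(
                rng, window,
                lambda x: t.alpha[sp2] + fourier_design(x % 24.0) @ g2,
                bound2,
            )
        times1 = np.empty(0)
        if z1[j]:
            bound1 = t.alpha[sp1] + np.abs(g1).sum() + max(0.0, t.eta * t.u_max)

            def lr1(x, _t2=times2):
                u = time_since_covariate(_t2, x, t.u_max)
                return t.alpha[sp1] + fourier_design(x % 24.0) @ g1 + t.eta * u

            times1 = _thin_poisson(rng, window, lr1, bound1)
        station_data.append(
            StationData(
                station_id=stations["station_id"].iloc[j],
                covariates={c: float(std[c].iloc[j]) for c in std.columns},
                window=window,
                times={sp1: times1, sp2: times2},
            )
        )
    data = CTMSOData(stations=station_data, species=(sp1, sp2), u_max=t.u_max)
    truth = {
        "states": states,
        "psi": probs,
        "beta_f1": t.beta_f1,
        "beta_f2": t.beta_f2,
        "beta_f12": t.beta_f12,
        "alpha": dict(t.alpha),
        "gamma": {k: tuple(v) for k, v in t.gamma.items()},
        "eta": t.eta,
        "raw_covariates": raw,
        "std_covariates": std,
        "marginal_psi_sp1": float((p10 + p11).mean()),
        "marginal_psi_sp2": float((p01 + p11).mean()),
    }
    return data, truth


# ---------------------------------------------------------------------------
# scats


def simulate_scats(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Scat table draws: per scat, 1 + Binomial(2, p) distinct prey items
    sampled without replacement by the configured multinomial weights."""
    t = config.diet
    rng = config.rng("diet")
    taxa = list(t.prey_probs)
    probs = np.array([t.prey_probs[k] for k in taxa], dtype=float)
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("prey probabilities must sum to 1")
    rows = []
    for s in range(t.n_scats):
        n_items = 1 + rng.binomial(2, t.extra_item_p)
        n_items = min(n_items, len(taxa))
        # weighted sampling without replacement (Gumbel top-k)
        keys = np.log(probs) + rng.gumbel(size=len(taxa))
        pick = np.argsort(keys)[-n_items:]
        for i in pick:
            rows.append((f"SC{s + 1:03d}", t.predator, taxa[i]))
    table = pd.DataFrame(rows, columns=["scat_id", "predator", "prey_taxon"])
    truth = {"prey_probs": dict(t.prey_probs), "n_scats": t.n_scats,
             "mean_items": 1 + 2 * t.extra_item_p}
    return table, truth
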