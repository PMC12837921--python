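"""Maximum-likelihood spatial capture–recapture (SCR) for camera-trap data.

Model
-----
Individual activity centers form a homogeneous Poisson process of density D
over a discretized habitat mask.  Detection of an individual with center x at
trap k on one occasion is Bernoulli with half-normal probability
``g(d) = g0·exp(−d²/(2σ²))``.  Either detection parameter may differ between
the sexes; sex is a two-class finite mixture with female proportion ``pmix``,
and unknown-sex individuals contribute through both classes (hybrid mixture).

The full (Poisson-N) log likelihood used throughout is::

    logL = Σ_i log[ D·a·Σ_c w_ic π_c Σ_x Pr(ω_i | x, c) ]
           − D·a·Σ_x Σ_c π_c p·(x, c)

with a the mask cell area, π = (pmix, 1−pmix), w_ic selecting the known sex
class (all classes for unknown sex), Pr(ω_i|x,c) the Bernoulli product over
traps and occasions, and p·(x,c) the probability an individual centered at x
is detected at least once.  The additive −log n! constant is omitted.

Densities are reported per 100 km²; coordinates and σ are in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

SEX_CLASSES = ("F", "M")  # mixture order: pmix is the female proportion


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CaptureHistory:
    """Individual × occasion × trap binary capture data (station-level traps).

    ``detections`` holds one row per (individual, occasion, trap) detection;
    derived arrays are built on construction.
    """

    individuals: list
    sex: np.ndarray  # per-individual 'F' / 'M' / 'U'
    detections: pd.DataFrame  # columns: individual, occasion (1-based), trap
    n_occasions: int
    traps: np.ndarray  # (K, 2) meters

    counts: np.ndarray = field(init=False)  # (n, K) occasions detected per trap
    occasion_sets: list = field(init=False)  # distinct 1-based occasions per ind

    def __post_init__(self) -> None:
        self.sex = np.asarray(self.sex, dtype="U1")
        self.traps = np.asarray(self.traps, dtype=float)
        n, k = len(self.individuals), len(self.traps)
        idx = {ind: i for i, ind in enumerate(self.individuals)}
        occ = self.detections["occasion"].to_numpy()
        if occ.min() < 1 or occ.max() > self.n_occasions:
            raise ValueError("occasion outside 1..n_occasions")
        counts = np.zeros((n, k), dtype=float)
        for ind, trap in zip(self.detections["individual"], self.detections["trap"]):
            counts[idx[ind], trap] += 1
        if (counts.sum(axis=1) == 0).any():
            raise ValueError("every individual must have at least one detection")
        if (counts > self.n_occasions).any():
            raise ValueError("more detections at a trap than occasions")
        self.counts = counts
        self.occasion_sets = [
            np.unique(self.detections.loc[self.detections["individual"] == ind, "occasion"])
            for ind in self.individuals
        ]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_traps(self) -> int:
        return len(self.traps)


def capture_history_from_tables(
    captures: pd.DataFrame, traps: pd.DataFrame, n_occasions: int | None = None
) -> CaptureHistory:
    """Build a :class:`CaptureHistory` from captures and trap tables.

    ``captures`` columns: individual_id, sex (M/F/blank), occasion (1-based),
    station_id; ``traps`` columns: station_id, x_m, y_m.
    """
    trap_ids = list(traps["station_id"])
    trap_idx = {t: i for i, t in enumerate(trap_ids)}
    unknown = sorted(set(captures["station_id"]) - set(trap_ids))
    if unknown:
        raise ValueError(f"capture stations missing from trap table: {unknown}")
    inds = list(pd.unique(captures["individual_id"]))
    sex_map = {}
    for ind, s in zip(captures["individual_id"], captures["sex"]):
        s = str(s).strip().upper()[:1] if pd.notna(s) else "U"
        s = s if s in ("F", "M") else "U"
        prev = sex_map.setdefault(ind, s)
        if prev != s and "U" not in (prev, s):
            raise ValueError(f"conflicting sex labels for individual {ind!r}")
        if prev == "U" and s != "U":
            sex_map[ind] = s
    det = pd.DataFrame(
        {
            "individual": captures["individual_id"].to_numpy(),
            "occasion": captures["occasion"].astype(int).to_numpy(),
            "trap": [trap_idx[s] for s in captures["station_id"]],
        }
    )
    # duplicate (ind, occasion, trap) rows collapse to one binary detection
    det = det.drop_duplicates()
    if n_occasions is None:
        n_occasions = int(det["occasion"].max())
    return CaptureHistory(
        individuals=inds,
        sex=np.array([sex_map[i] for i in inds]),
        detections=det,
        n_occasions=n_occasions,
        traps=traps[["x_m", "y_m"]].to_numpy(dtype=float),
    )


def restrict_to_window(hist: CaptureHistory, first: int, last: int) -> CaptureHistory:
    """Sub-history over occasions ``first..last`` (1-based, inclusive).

    Occasions are renumbered from 1; individuals without detections inside the
    window are dropped.
    """
    det = hist.detections
    keep = det[(det["occasion"] >= first) & (det["occasion"] <= last)].copy()
    if keep.empty:
        raise ValueError("no detections inside the requested window")
    keep["occasion"] = keep["occasion"] - first + 1
    inds = [i for i in hist.individuals if i in set(keep["individual"])]
    sex = np.array([hist.sex[hist.individuals.index(i)] for i in inds])
    return CaptureHistory(
        individuals=inds,
        sex=sex,
        detections=keep,
        n_occasions=last - first + 1,
        traps=hist.traps.copy(),
    )


@dataclass
class HabitatMask:
    """Discretized state space of candidate activity-center locations."""

    points: np.ndarray  # (M, 2) meters
    cell_area: float  # km² per point
    spacing_km: float
    buffer_km: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area_km2(self) -> float:
        return self.n_points * self.cell_area

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_m": self.points[:, 0], "y_m": self.points[:, 1], "cell_area_km2": self.cell_area}
        )


@dataclass(frozen=True)
class SCRModelSpec:
    """Which detection parameters vary by sex, and whether pmix is free."""

    g0_by_sex: bool = False
    sigma_by_sex: bool = False
    pmix_free: bool = True
    name: str = ""

    @property
    def n_params(self) -> int:
        return 1 + (2 if self.g0_by_sex else 1) + (2 if self.sigma_by_sex else 1) + (
            1 if self.pmix_free else 0
        )


MODEL_SET = {
    "null": SCRModelSpec(False, False, name="null"),
    "g0sex": SCRModelSpec(True, False, name="g0sex"),
    "sigsex": SCRModelSpec(False, True, name="sigsex"),
    "both": SCRModelSpec(True, True, name="both"),
}


# ---------------------------------------------------------------------------
# detection function and movement summaries


def halfnormal_g(d: np.ndarray | float, g0: float, sigma: float):
    """Half-normal detection probability g0·exp(−d²/(2σ²))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be nonnegative")
    out = g0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def rpsv(hist: CaptureHistory) -> float:
    """Root-pooled spatial variance of capture locations (meters).

    Pools squared deviations of each individual's capture coordinates from its
    own centroid over individuals with ≥2 detections; the divisor is
    2·(N_det − N_ind) over those individuals.
    """
    ss = 0.0
    n_det = 0
    n_ind = 0
    multi = False
    for i in range(hist.n_individuals):
        counts = hist.counts[i]
        m = int(counts.sum())
        if m < 2:
            continue
        xy = np.repeat(hist.traps, counts.astype(int), axis=0)
        if len(np.unique(xy, axis=0)) > 1:
            multi = True
        ss += ((xy - xy.mean(axis=0)) ** 2).sum()
        n_det += m
        n_ind += 1
    if n_ind == 0 or not multi or n_det == n_ind:
        raise ValueError("no spatial recaptures; RPSV undefined")
    return math.sqrt(ss / (2.0 * (n_det - n_ind)))


def build_mask(
    traps: np.ndarray,
    buffer_km: float,
    spacing_km: float = 1.0,
    metric: str = "chebyshev",
) -> HabitatMask:
    """Regular-grid habitat mask within ``buffer_km`` of any trap.

    Cell centers are laid on a grid of ``spacing_km`` aligned to the trap
    bounding box; a center is kept when its distance to the nearest trap is at
    most the buffer (Chebyshev metric by default; ``metric="euclidean"``
    available).
    """
    if spacing_km <= 0:
        raise ValueError("spacing must be positive")
    if buffer_km < 0:
        raise ValueError("buffer must be nonnegative")
    traps = np.asarray(traps, dtype=float)
    sp = spacing_km * 1000.0
    buf = buffer_km * 1000.0
    lo = traps.min(axis=0) - buf
    hi = traps.max(axis=0) + buf
    xs = np.arange(lo[0], hi[0] + sp / 2, sp)
    ys = np.arange(lo[1], hi[1] + sp / 2, sp)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    diff = np.abs(pts[:, None, :] - traps[None, :, :])
    if metric == "chebyshev":
        dist = diff.max(axis=2).min(axis=1)
    elif metric == "euclidean":
        dist = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    keep = pts[dist <= buf + 1e-9]
    if len(keep) == 0:
        raise ValueError("mask is empty")
    return HabitatMask(keep, cell_area=spacing_km**2, spacing_km=spacing_km, buffer_km=buffer_km)


# ---------------------------------------------------------------------------
# likelihood


def _unpack(params: np.ndarray, spec: SCRModelSpec):
    """Unconstrained parameter vector -> (D per 100 km², g0[2], sigma[2], pmix)."""
    i = 0
    d100 = math.exp(params[i]); i += 1
    if spec.g0_by_sex:
        g0 = special.expit(params[i : i + 2]); i += 2
    else:
        g0 = np.repeat(special.expit(params[i]), 2); i += 1
    if spec.sigma_by_sex:
        sigma = np.exp(params[i : i + 2]); i += 2
    else:
        sigma = np.repeat(math.exp(params[i]), 2); i += 1
    pmix = special.expit(params[i]) if spec.pmix_free else 0.5
    return d100, np.asarray(g0, float), np.asarray(sigma, float), float(pmix)


def _dist2(hist: CaptureHistory, mask: HabitatMask) -> np.ndarray:
    d = hist.traps[:, None, :] - mask.points[None, :, :]
    return (d**2).sum(axis=2)  # (K, M)


def scr_negloglik(
    params: np.ndarray,
    hist: CaptureHistory,
    mask: HabitatMask,
    spec: SCRModelSpec,
    dist2: np.ndarray | None = None,
) -> float:
    """Negative full (Poisson-N) SCR log likelihood; +inf on non-finite input."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return np.inf
    if mask.n_points == 0:
        raise ValueError("mask is empty")
    d100, g0, sigma, pmix = _unpack(params, spec)
    dens = d100 / 100.0  # per km²
    a = mask.cell_area
    occ = hist.n_occasions
    counts = hist.counts  # (n, K)
    if dist2 is None:
        dist2 = _dist2(hist, mask)
    log_pi = np.log([pmix, 1.0 - pmix])
    s_class = np.empty((2, hist.n_individuals))
    pdot_sum = 0.0
    for c in range(2):
        logp = math.log(g0[c]) - dist2 / (2.0 * sigma[c] ** 2)  # (K, M), exact
        log1mp = np.log1p(-np.exp(logp))
        log_pr = counts @ logp + (occ - counts) @ log1mp  # (n, M)
        s_class[c] = special.logsumexp(log_pr, axis=1)
        pdot = -np.expm1(occ * log1mp.sum(axis=0))  # (M,)
        pdot_sum += math.exp(log_pi[c]) * pdot.sum()
    # per-individual class mixing with sex weights
    terms = np.full((2, hist.n_individuals), -np.inf)
    for c, label in enumerate(SEX_CLASSES):
        allowed = (hist.sex == label) | (hist.sex == "U")
        terms[c, allowed] = log_pi[c] + s_class[c, allowed]
    ind_ll = math.log(dens * a) + special.logsumexp(terms, axis=0)
    ll = ind_ll.sum() - dens * a * pdot_sum
    if not np.isfinite(ll):
        return np.inf
    return -ll


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SCRFit:
    """A fitted SCR model on the natural parameter scale."""

    model: str
    spec: SCRModelSpec
    params: np.ndarray  # unconstrained MLE
    logL: float
    K: int
    aic: float
    D: float  # per 100 km²
    se_D: float | None
    ci_D: tuple | None
    g0: dict
    sigma: dict
    pmix: float
    se: dict
    cov: np.ndarray | None
    converged: bool
    message: str = ""
    delta_aic: float | None = None

    def summary(self) -> dict:
        return {
            "model": self.model,
            "logL": self.logL,
            "K": self.K,
            "AIC": self.aic,
            "dAIC": self.delta_aic,
            "D_per_100km2": self.D,
            "SE_D": self.se_D,
            "CI_D": list(self.ci_D) if self.ci_D else None,
            "g0": self.g0,
            "sigma_m": self.sigma,
            "pmix": self.pmix,
            "SE": self.se,
            "converged": self.converged,
        }


def _start_params(hist: CaptureHistory, mask: HabitatMask, spec: SCRModelSpec, sigma0: float):
    n = hist.n_individuals
    d0 = max(n / mask.area_km2 * 100.0, 1e-3)  # per 100 km²
    p0 = min(max(hist.counts.sum() / (n * hist.n_occasions * 3.0), 1e-4), 0.4)
    x = [math.log(d0)]
    x += [special.logit(p0)] * (2 if spec.g0_by_sex else 1)
    x += [math.log(sigma0)] * (2 if spec.sigma_by_sex else 1)
    if spec.pmix_free:
        x += [0.0]
    return np.array(x)


def _natural_se(fit_params, cov, spec):
    """Delta-method SEs on the natural scale, keyed by parameter name."""
    d100, g0, sigma, pmix = _unpack(fit_params, spec)
    se_raw = np.sqrt(np.clip(np.diag(cov), 0, None))
    out, i = {}, 0
    out["D"] = d100 * se_raw[i]; i += 1
    if spec.g0_by_sex:
        out["g0_F"] = g0[0] * (1 - g0[0]) * se_raw[i]
        out["g0_M"] = g0[1] * (1 - g0[1]) * se_raw[i + 1]
        i += 2
    else:
        out["g0"] = g0[0] * (1 - g0[0]) * se_raw[i]; i += 1
    if spec.sigma_by_sex:
        out["sigma_F"] = sigma[0] * se_raw[i]
        out["sigma_M"] = sigma[1] * se_raw[i + 1]
        i += 2
    else:
        out["sigma"] = sigma[0] * se_raw[i]; i += 1
    if spec.pmix_free:
        out["pmix"] = pmix * (1 - pmix) * se_raw[i]
    return out


def density_ci(d: float, se: float, level_z: float = 1.96) -> tuple:
    """Lognormal-style CI: D/C, D·C with C = exp(z·sqrt(ln(1+(SE/D)²)))."""
    c = math.exp(level_z * math.sqrt(math.log(1.0 + (se / d) ** 2)))
    return (d / c, d * c)


def fit_single(
    hist: CaptureHistory,
    mask: HabitatMask,
    spec: SCRModelSpec,
    compute_se: bool = True,
    sigma_start: float | None = None,
    n_starts: int = 3,
) -> SCRFit:
    """Fit one SCR model specification by quasi-Newton optimization.

    Deterministic multiple starts vary the σ initialization (RPSV × {1, ½, 2});
    the best converged optimum is kept.
    """
    dist2 = _dist2(hist, mask)
    if sigma_start is None:
        try:
            sigma_start = rpsv(hist)
        except ValueError:
            sigma_start = 0.5 * np.ptp(hist.traps, axis=0).mean() or 1000.0
    mults = [1.0, 0.5, 2.0][: max(1, n_starts)]
    best = None
    for m in mults:
        x0 = _start_params(hist, mask, spec, sigma_start * m)
        res = optimize.minimize(
            scr_negloglik,
            x0,
            args=(hist, mask, spec, dist2),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    res = best
    d100, g0, sigma, pmix = _unpack(res.x, spec)
    k = spec.n_params
    logl = -res.fun
    se_map, cov, se_d, ci = {}, None, None, None
    converged = bool(res.success) and np.isfinite(res.fun)
    if compute_se and converged:
        try:
            hess = approx_hess(res.x, scr_negloglik, args=(hist, mask, spec, dist2))
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError("negative variance")
            se_map = _natural_se(res.x, cov, spec)
            se_d = se_map["D"]
            ci = density_ci(d100, se_d)
        except np.linalg.LinAlgError:
            converged = False
    g0_out = {"F": float(g0[0]), "M": float(g0[1])} if spec.g0_by_sex else {"all": float(g0[0])}
    sig_out = (
        {"F": float(sigma[0]), "M": float(sigma[1])} if spec.sigma_by_sex else {"all": float(sigma[0])}
    )
    return SCRFit(
        model=spec.name or "custom",
        spec=spec,
        params=res.x,
        logL=logl,
        K=k,
        aic=-2.0 * logl + 2.0 * k,
        D=d100,
        se_D=se_d,
        ci_D=ci,
        g0=g0_out,
        sigma=sig_out,
        pmix=pmix,
        se=se_map,
        cov=cov,
        converged=converged,
        message=str(res.message),
    )


def fit_scr(
    hist: CaptureHistory,
    mask: HabitatMask,
    models=("null", "g0sex", "sigsex", "both"),
    compute_se: bool = True,
    n_starts: int = 3,
) -> list[SCRFit]:
    """Fit a candidate model set and rank converged fits by AIC.

    Non-converged fits are returned last with ``delta_aic`` unset.  With fewer
    than two individuals a single flagged, unranked failure entry is returned.
    """
    if hist.n_individuals < 2:
        spec = MODEL_SET[models[0]] if isinstance(models[0], str) else models[0]
        return [
            SCRFit(
                model=spec.name, spec=spec, params=np.array([]), logL=np.nan, K=spec.n_params,
                aic=np.nan, D=np.nan, se_D=None, ci_D=None, g0={}, sigma={}, pmix=np.nan,
                se={}, cov=None, converged=False, message="fewer than two individuals",
            )
        ]
    fits = []
    for m in models:
        spec = MODEL_SET[m] if isinstance(m, str) else m
        fits.append(fit_single(hist, mask, spec, compute_se=compute_se, n_starts=n_starts))
    ranked = sorted([f for f in fits if f.converged], key=lambda f: f.aic)
    if ranked:
        best = ranked[0].aic
        for f in ranked:
            f.delta_aic = f.aic - best
    return ranked + [f for f in fits if not f.converged]


def mask_adequacy(
    hist: CaptureHistory,
    spec: SCRModelSpec,
    start_buffer_km: float,
    step_km: float = 1.0,
    spacing_km: float = 1.0,
    tol: float = 0.01,
    max_steps: int = 10,
    metric: str = "chebyshev",
) -> dict:
    """Refit at incrementally larger buffers until density stabilizes.

    Stabilization means two successive relative changes in D̂ below ``tol``.
    Returns the buffer series with densities, the stabilization buffer (None
    when not reached within ``max_steps``) and a ``stabilized`` flag.
    """
    buffers, dens = [], []
    small_changes = 0
    stabilization = None
    for step in range(max_steps + 1):
        buf = start_buffer_km + step * step_km
        mask = build_mask(hist.traps, buf, spacing_km, metric=metric)
        fit = fit_single(hist, mask, spec, compute_se=False)
        buffers.append(buf)
        dens.append(fit.D)
        if len(dens) >= 2 and np.isfinite(dens[-1]) and dens[-2] > 0:
            rel = abs(dens[-1] - dens[-2]) / dens[-2]
            small_changes = small_changes + 1 if rel < tol else 0
            if small_changes >= 2:
                stabilization = buf
                break
    return {
        "buffer_km": buffers,
        "density": dens,
        "stabilization_buffer_km": stabilization,
        "stabilized": stabilization is not None,
    }


# ---------------------------------------------------------------------------
# closure test and precision metrics


def _range_distribution(c: int, k: int) -> np.ndarray:
    """P(d = r) for the span of c occasions sampled WOR from {1..k}; index r."""
    p = np.zeros(k)
    for r in range(c - 1, k):
        p[r] = (k - r) * special.comb(r - 1, c - 2) / special.comb(k, c)
    return p


def closure_moments(c: int, k: int) -> tuple[float, float]:
    """Exact mean and variance of the capture span under demographic closure."""
    if not 2 <= c <= k:
        raise ValueError("need 2 <= c <= k")
    p = _range_distribution(c, k)
    r = np.arange(k, dtype=float)
    e = float((r * p).sum())
    v = float((r**2 * p).sum() - e**2)
    return e, v


def closure_test(hist: CaptureHistory) -> tuple[float, float]:
    """One-sided closure test on individual capture spans.

    Under closure, an individual captured on c occasions has those occasions
    as a simple random sample without replacement from the k survey occasions;
    the statistic standardizes the summed spans.  Small p (left tail) rejects
    closure, since gains/losses shorten spans.
    """
    k = hist.n_occasions
    spans, es, vs = [], [], []
    for occs in hist.occasion_sets:
        c = len(occs)
        if c < 2:
            continue
        spans.append(int(occs.max() - occs.min()))
        e, v = closure_moments(c, k)
        es.append(e)
        vs.append(v)
    if not spans:
        raise ValueError("no individual captured on two or more occasions")
    var = sum(vs)
    if var <= 0:
        return 0.0, 0.5
    z = (sum(spans) - sum(es)) / math.sqrt(var)
    return float(z), float(stats.norm.cdf(z))


def longest_closed_window(hist: CaptureHistory, alpha: float = 0.05) -> tuple[int, int]:
    """Longest contiguous occasion window on which closure is not rejected.

    Individuals with no captures inside a window are dropped from its test;
    windows with no testable individual (none with ≥2 capture occasions) have
    no closure p-value and are skipped.  Ties break to the earliest start;
    ``alpha >= 1`` disables restriction.  Returns a 1-based inclusive
    (first, last) pair; when no window passes, the full survey is returned.
    """
    k = hist.n_occasions
    if alpha >= 1.0:
        return 1, k
    cache: dict[tuple[int, int], tuple[float, float]] = {}

    def window_p(first: int, last: int) -> float | None:
        kk = last - first + 1
        spans = es = vs = 0.0
        testable = False
        for occs in hist.occasion_sets:
            inside = occs[(occs >= first) & (occs <= last)]
            c = len(inside)
            if c < 2:
                continue
            testable = True
            key = (c, kk)
            if key not in cache:
                cache[key] = closure_moments(c, kk)
            e, v = cache[key]
            spans += int(inside.max() - inside.min())
            es += e
            vs += v
        if not testable:
            return None
        if vs <= 0:
            return 1.0  # e.g. every testable individual captured on all occasions
        z = (spans - es) / math.sqrt(vs)
        return float(stats.norm.cdf(z))

    for length in range(k, 1, -1):
        for first in range(1, k - length + 2):
            p = window_p(first, first + length - 1)
            if p is not None and p > alpha:
                return first, first + length - 1
    return 1, k  # no testable window passed; leave the survey unrestricted


def sex_ratio_lrt(fit_free: SCRFit, fit_fixed: SCRFit) -> tuple[float, float]:
    """Likelihood-ratio test of pmix = 0.5 (1 df)."""
    chi2 = 2.0 * (fit_free.logL - fit_fixed.logL)
    if chi2 < -1e-6:
        raise ValueError("free model has lower likelihood than its nested model")
    chi2 = max(chi2, 0.0)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def hrciw(estimate: float, lcl: float, ucl: float) -> float:
    """Half relative confidence interval width, percent."""
    if not (0 < lcl <= estimate <= ucl):
        raise ValueError("require 0 < lcl <= estimate <= ucl")
    return 100.0 * (ucl - lcl) / (2.0 * estimate)
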