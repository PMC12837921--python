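"""Two-species occupancy with continuous-time Poisson detection.

The latent state of each station is one of four combinations of presence of
species 1 (the subordinate felid) and species 2 (the dominant felid).  State
probabilities are parameterized by natural (log-linear) parameters::

    psi_z  ∝  exp(z1·f1 + z2·f2 + z1·z2·f12)

where f1, f2 and f12 are linear predictors in station covariates; f12 = 0
recovers independence.  Conditional on presence, time-stamped detections at a
station follow a temporal Poisson point process with log intensity::

    log λ_s(t) = α_s + Σ_{k=1,2} [a_k cos(2πkτ/24) + b_k sin(2πkτ/24)]
                 (+ η·u(t)  for species 1)

with τ the time of day in hours and u(t) the standardized elapsed time since
the most recent species-2 detection at the station (capped at ``u_max``;
species-2 detection times are conditioned on as fixed covariate data).
Detection integrals use midpoint quadrature (60 min bins by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess

N_HARMONICS = 2
STATE_LABELS = ("00", "10", "01", "11")


# ---------------------------------------------------------------------------
# data containers


@dataclass
class StationData:
    """One station's covariates, operational window and detection times.

    ``window`` is (start, end) in hours from survey start; detection times are
    hours from survey start (time of day is the value mod 24, with the survey
    assumed to start at local midnight unless offset in the window).
    """

    station_id: object
    covariates: dict
    window: tuple
    times: dict  # species -> sorted array of detection hours

    def __post_init__(self):
        t0, t1 = self.window
        if t1 <= t0:
            raise ValueError(f"station {self.station_id}: window length must be positive")
        for sp, t in self.times.items():
            t = np.sort(np.asarray(t, dtype=float))
            if len(t) and (t[0] < t0 - 1e-9 or t[-1] > t1 + 1e-9):
                raise ValueError(
                    f"station {self.station_id}: {sp} detection outside operational window"
                )
            self.times[sp] = t


@dataclass
class CTMSOData:
    """Station list plus the (subordinate, dominant) species pair."""

    stations: list
    species: tuple = ("golden_cat", "leopard")
    u_max: float = 72.0

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    def covariate_values(self, name: str) -> np.ndarray:
        return np.array([s.covariates[name] for s in self.stations], dtype=float)


@dataclass
class CTMSOModel:
    """Covariate placement on the natural parameters, plus the lag flag."""

    name: str
    occ_covs: dict  # {'f1': [names], 'f2': [...], 'f12': [...]}
    lag: bool = False

    def n_params(self) -> int:
        p = sum(1 + len(v) for v in self.occ_covs.values())
        return p + 2 * (1 + 2 * N_HARMONICS) + (1 if self.lag else 0)


def spatial_model_set(site: bool = True, prey: bool = True) -> list:
    """The candidate spatial model set: distance-only, ±site, ±prey RAI.

    Distance to linear forest features enters all three natural parameters;
    prey RAI enters only the dominant species' f2 and the interaction f12.
    """
    models = [CTMSOModel("dist", {"f1": ["dist_linear"], "f2": ["dist_linear"], "f12": ["dist_linear"]})]
    if site:
        models.append(
            CTMSOModel(
                "site",
                {
                    "f1": ["dist_linear", "site"],
                    "f2": ["dist_linear", "site"],
                    "f12": ["dist_linear", "site"],
                },
            )
        )
    if prey:
        models.append(
            CTMSOModel(
                "prey",
                {
                    "f1": ["dist_linear"],
                    "f2": ["dist_linear", "prey_rai"],
                    "f12": ["dist_linear", "prey_rai"],
                },
            )
        )
    return models


def add_lag(model: CTMSOModel) -> CTMSOModel:
    return CTMSOModel(name=model.name + "+lag", occ_covs=model.occ_covs, lag=True)


# ---------------------------------------------------------------------------
# elemental operations


def psi_from_f(f1, f2, f12):
    """State probabilities (ψ00, ψ10, ψ01, ψ11) from natural parameters."""
    f1, f2, f12 = (np.asarray(v, dtype=float) for v in (f1, f2, f12))
    logw = np.stack([np.zeros_like(f1), f1, f2, f1 + f2 + f12], axis=-1)
    logz = special.logsumexp(logw, axis=-1, keepdims=True)
    psi = np.exp(logw - logz)
    return tuple(np.moveaxis(psi, -1, 0))


def fourier_design(tau) -> np.ndarray:
    """Two-harmonic Fourier design over the 24 h day: columns a1,b1,a2,b2."""
    tau = np.asarray(tau, dtype=float)
    w = 2.0 * math.pi * tau / 24.0
    return np.stack([np.cos(w), np.sin(w), np.cos(2 * w), np.sin(2 * w)], axis=-1)


def intensity(t, alpha: float, gamma, eta: float = 0.0, u=0.0):
    """Detection intensity (per hour) at time ``t`` (hours)."""
    tau = np.asarray(t, dtype=float) % 24.0
    gamma = np.asarray(gamma, dtype=float)
    out = np.exp(alpha + fourier_design(tau) @ gamma + eta * np.asarray(u, dtype=float))
    return float(out) if out.ndim == 0 else out


def cumulative_intensity(
    alpha: float, gamma, window: tuple, quad_minutes: float = 60.0,
    eta: float = 0.0, u_fn=None,
) -> float:
    """Expected detection count over a window by midpoint quadrature."""
    t0, t1 = window
    if t1 - t0 <= 0:
        raise ValueError("window length must be positive")
    mids, w = _quad_grid(t0, t1, quad_minutes)
    u = u_fn(mids) if u_fn is not None else 0.0
    return float(np.sum(w * intensity(mids, alpha, gamma, eta, u)))


def time_since_covariate(prior_times, t, u_max: float = 72.0):
    """Hours since the most recent prior event, capped at ``u_max``.

    With no prior event (or an empty event list) the covariate sits at the
    cap.  Standardization happens at model-preparation time alongside the
    other detection covariates.
    """
    prior = np.sort(np.asarray(prior_times, dtype=float))
    t = np.asarray(t, dtype=float)
    if len(prior) == 0:
        u = np.full_like(t, float(u_max))
        return float(u) if u.ndim == 0 else u
    idx = np.searchsorted(prior, t, side="left") - 1
    u = np.where(idx >= 0, t - prior[np.clip(idx, 0, None)], u_max)
    u = np.minimum(u, u_max)
    return float(u) if u.ndim == 0 else u


def _quad_grid(t0: float, t1: float, quad_minutes: float):
    """Midpoints and weights (hours) of equal bins, final bin truncated."""
    dt = quad_minutes / 60.0
    n_full = int((t1 - t0) // dt)
    edges = t0 + dt * np.arange(n_full + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    w = np.full(n_full, dt)
    rem = (t1 - t0) - n_full * dt
    if rem > 1e-9:
        mids = np.append(mids, edges[-1] + rem / 2.0)
        w = np.append(w, rem)
    return mids, w


# ---------------------------------------------------------------------------
# likelihood machinery


class _Prepared:
    """Design matrices, quadrature grids and detection designs for one model."""

    def __init__(self, data: CTMSOData, model: CTMSOModel, quad_minutes: float):
        self.data, self.model, self.quad_minutes = data, model, quad_minutes
        st = data.stations
        n = len(st)
        self.n_stations = n
        self.X = {}
        for f, covs in model.occ_covs.items():
            cols = [np.ones(n)] + [data.covariate_values(c) for c in covs]
            self.X[f] = np.column_stack(cols)
        self.coef_names = []
        for f, covs in model.occ_covs.items():
            self.coef_names += [f"{f}:(Intercept)"] + [f"{f}:{c}" for c in covs]
        sp1, sp2 = data.species
        # quadrature grids, concatenated over stations
        q_station, q_mid, q_w = [], [], []
        for j, s in enumerate(st):
            mids, w = _quad_grid(*s.window, quad_minutes)
            q_station.append(np.full(len(mids), j))
            q_mid.append(mids)
            q_w.append(w)
        self.q_station = np.concatenate(q_station)
        self.q_mid = np.concatenate(q_mid)
        self.q_w = np.concatenate(q_w)
        self.Fq = fourier_design(self.q_mid % 24.0)
        # detections, concatenated
        self.det = {}
        for s_i, sp in enumerate(data.species):
            idx, times = [], []
            for j, s in enumerate(st):
                t = s.times.get(sp, np.empty(0))
                idx.append(np.full(len(t), j))
                times.append(t)
            idx = np.concatenate(idx).astype(int)
            times = np.concatenate(times)
            self.det[sp] = {
                "station": idx,
                "F": fourier_design(times % 24.0),
                "n": np.bincount(idx, minlength=n).astype(float),
            }
        # lag covariate of species 1, from species-2 times (fixed data)
        if model.lag:
            uq = np.empty_like(self.q_mid)
            for j, s in enumerate(st):
                m = self.q_station == j
                uq[m] = time_since_covariate(s.times.get(sp2, []), self.q_mid[m], data.u_max)
            mu, sd = uq.mean(), uq.std(ddof=1)
            if sd <= 0:
                mu, sd = 0.0, 1.0
            self.u_mean, self.u_sd = mu, sd
            self.uq = (uq - mu) / sd
            t1 = np.concatenate([st[j].times.get(sp1, np.empty(0)) for j in range(n)])
            stn1 = self.det[sp1]["station"]
            udet = np.empty(len(t1))
            for j in range(n):
                m = stn1 == j
                if m.any():
                    udet[m] = time_since_covariate(st[j].times.get(sp2, []), t1[m], data.u_max)
            self.udet1 = (udet - mu) / sd
            self.coef_names_det_extra = ["eta:time_since_sp2"]
        self.n_occ_params = sum(x.shape[1] for x in self.X.values())
        for sp in data.species:
            self.coef_names += [f"alpha:{sp}", f"a1:{sp}", f"b1:{sp}", f"a2:{sp}", f"b2:{sp}"]
        if model.lag:
            self.coef_names += ["eta:time_since_sp2"]
        self.n_params = len(self.coef_names)

    def split(self, theta: np.ndarray):
        i = 0
        beta = {}
        for f in ("f1", "f2", "f12"):
            p = self.X[f].shape[1]
            beta[f] = theta[i : i + p]
            i += p
        det = {}
        for sp in self.data.species:
            det[sp] = (theta[i], theta[i + 1 : i + 5])
            i += 5
        eta = theta[i] if self.model.lag else 0.0
        return beta, det, eta

    def negloglik(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            return np.inf
        beta, det_par, eta = self.split(theta)
        f1 = self.X["f1"] @ beta["f1"]
        f2 = self.X["f2"] @ beta["f2"]
        f12 = self.X["f12"] @ beta["f12"]
        logw = np.stack([np.zeros_like(f1), f1, f2, f1 + f2 + f12], axis=1)
        logpsi = logw - special.logsumexp(logw, axis=1, keepdims=True)
        sp1, sp2 = self.data.species
        log_pp = {}
        log_abs = {}
        for sp in (sp1, sp2):
            alpha, gamma = det_par[sp]
            lam_log_q = alpha + self.Fq @ gamma
            if sp == sp1 and self.model.lag:
                lam_log_q = lam_log_q + eta * self.uq
            big_lambda = np.bincount(
                self.q_station, weights=self.q_w * np.exp(lam_log_q), minlength=self.n_stations
            )
            d = self.det[sp]
            lam_log_det = alpha + d["F"] @ gamma
            if sp == sp1 and self.model.lag and len(lam_log_det):
                lam_log_det = lam_log_det + eta * self.udet1
            sum_log = np.bincount(d["station"], weights=lam_log_det, minlength=self.n_stations)
            log_pp[sp] = -big_lambda + sum_log
            log_abs[sp] = np.where(d["n"] == 0, 0.0, -np.inf)
        term = logpsi + np.stack(
            [
                log_abs[sp1] + log_abs[sp2],
                log_pp[sp1] + log_abs[sp2],
                log_abs[sp1] + log_pp[sp2],
                log_pp[sp1] + log_pp[sp2],
            ],
            axis=1,
        )
        ll = special.logsumexp(term, axis=1).sum()
        return np.inf if not np.isfinite(ll) else -ll

    def state_log_terms(self, theta: np.ndarray) -> np.ndarray:
        """Per-station log joint terms over the four states (for posteriors)."""
        beta, det_par, eta = self.split(theta)
        # recompute via negloglik internals; duplicated cheaply for clarity
        f1 = self.X["f1"] @ beta["f1"]
        f2 = self.X["f2"] @ beta["f2"]
        f12 = self.X["f12"] @ beta["f12"]
        logw = np.stack([np.zeros_like(f1), f1, f2, f1 + f2 + f12], axis=1)
        logpsi = logw - special.logsumexp(logw, axis=1, keepdims=True)
        sp1, sp2 = self.data.species
        comp = {}
        for sp in (sp1, sp2):
            alpha, gamma = det_par[sp]
            lam_log_q = alpha + self.Fq @ gamma
            if sp == sp1 and self.model.lag:
                lam_log_q = lam_log_q + eta * self.uq
            big_lambda = np.bincount(
                self.q_station, weights=self.q_w * np.exp(lam_log_q), minlength=self.n_stations
            )
            d = self.det[sp]
            lam_log_det = alpha + d["F"] @ gamma
            if sp == sp1 and self.model.lag and len(lam_log_det):
                lam_log_det = lam_log_det + eta * self.udet1
            sum_log = np.bincount(d["station"], weights=lam_log_det, minlength=self.n_stations)
            comp[sp] = (-big_lambda + sum_log, np.where(d["n"] == 0, 0.0, -np.inf))
        pp1, ab1 = comp[sp1]
        pp2, ab2 = comp[sp2]
        return logpsi + np.stack([ab1 + ab2, pp1 + ab2, ab1 + pp2, pp1 + pp2], axis=1)


def ctmso_negloglik(
    theta: np.ndarray, data: CTMSOData, model: CTMSOModel, quad_minutes: float = 60.0
) -> float:
    """Negative log likelihood of the two-species continuous-time model."""
    return _Prepared(data, model, quad_minutes).negloglik(theta)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CTMSOFit:
    """A converged (or flagged) fit with Wald intervals."""

    model: CTMSOModel
    params: np.ndarray
    coef_names: list
    logL: float
    aic: float
    cov: np.ndarray | None
    converged: bool
    message: str = ""
    delta_aic: float | None = None
    prepared: _Prepared = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return len(self.params)

    def coef_table(self) -> pd.DataFrame:
        se = (
            np.sqrt(np.clip(np.diag(self.cov), 0, None))
            if self.cov is not None
            else np.full(self.K, np.nan)
        )
        lo, hi = self.params - 1.96 * se, self.params + 1.96 * se
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.params,
                "se": se,
                "lcl": lo,
                "ucl": hi,
                "informative": (lo > 0) | (hi < 0),
            }
        )

    def coef(self, name: str) -> float:
        return float(self.params[self.coef_names.index(name)])


def fit_single(
    data: CTMSOData,
    model: CTMSOModel,
    quad_minutes: float = 60.0,
    compute_se: bool = True,
    maxiter: int = 600,
) -> CTMSOFit:
    prep = _Prepared(data, model, quad_minutes)
    theta0 = np.zeros(prep.n_params)
    total_hours = sum(s.window[1] - s.window[0] for s in data.stations)
    i = prep.n_occ_params
    for sp in data.species:
        rate = max(prep.det[sp]["n"].sum(), 0.5) / total_hours
        theta0[i] = math.log(rate)
        i += 5
    res = optimize.minimize(
        prep.negloglik, theta0, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    cov = None
    converged = bool(res.success) and np.isfinite(res.fun)
    if compute_se and converged:
        try:
            cov = np.linalg.inv(approx_hess(res.x, prep.negloglik))
        except np.linalg.LinAlgError:
            cov, converged = None, False
    logl = -res.fun
    return CTMSOFit(
        model=model,
        params=res.x,
        coef_names=prep.coef_names,
        logL=logl,
        aic=-2.0 * logl + 2.0 * len(res.x),
        cov=cov,
        converged=converged,
        message=str(res.message),
        prepared=prep,
    )


def fit_ctmso(
    data: CTMSOData,
    models: list,
    quad_minutes: float = 60.0,
    compute_se: bool = True,
) -> list:
    """Fit a model list and rank converged fits by AIC."""
    fits = [fit_single(data, m, quad_minutes, compute_se) for m in models]
    ranked = sorted([f for f in fits if f.converged], key=lambda f: f.aic)
    if ranked:
        best = ranked[0].aic
        for f in ranked:
            f.delta_aic = f.aic - best
    return ranked + [f for f in fits if not f.converged]


def two_stage_fit(
    data: CTMSOData,
    spatial_models: list | None = None,
    quad_minutes: float = 60.0,
    compute_se: bool = True,
) -> dict:
    """Spatial model selection first, then the lag covariate on the winner."""
    spatial_models = spatial_models or spatial_model_set()
    fits = fit_ctmso(data, spatial_models, quad_minutes, compute_se)
    winner = next((f for f in fits if f.converged), None)
    if winner is None:
        raise RuntimeError("no spatial model converged")
    lag_fit = fit_single(data, add_lag(winner.model), quad_minutes, compute_se)
    final = lag_fit if (lag_fit.converged and lag_fit.aic < winner.aic) else winner
    return {"spatial_fits": fits, "winner": winner, "lag_fit": lag_fit, "final": final}


# ---------------------------------------------------------------------------
# prediction curves


def occupancy_curves(
    fit: CTMSOFit,
    data: CTMSOData,
    covariate: str = "dist_linear",
    grid: np.ndarray | None = None,
    fix: dict | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Marginal and co-occurrence occupancy along a covariate gradient.

    Other covariates sit at ``fix`` values (0 = their mean on the
    standardized scale).  95% bands come from a parametric bootstrap of the
    coefficient vector; grid values beyond the observed covariate range are
    flagged as extrapolation.
    """
    obs = data.covariate_values(covariate)
    if grid is None:
        grid = np.linspace(obs.min(), obs.max(), 50)
    grid = np.asarray(grid, dtype=float)
    fix = dict(fix or {})

    def curves(theta):
        b = {}
        i = 0
        for f in ("f1", "f2", "f12"):
            p = fit.prepared.X[f].shape[1]
            b[f] = theta[i : i + p]
            i += p
        fs = {}
        for f, covs in fit.model.occ_covs.items():
            x = np.column_stack(
                [np.ones(len(grid))]
                + [grid if c == covariate else np.full(len(grid), fix.get(c, 0.0)) for c in covs]
            )
            fs[f] = x @ b[f]
        p00, p10, p01, p11 = psi_from_f(fs["f1"], fs["f2"], fs["f12"])
        return np.stack([p10 + p11, p01 + p11, p11])  # sp1 marginal, sp2 marginal, both

    est = curves(fit.params)
    out = pd.DataFrame(
        {
            covariate: grid,
            "psi_sp1": est[0],
            "psi_sp2": est[1],
            "psi_both": est[2],
            "extrapolated": (grid < obs.min() - 1e-9) | (grid > obs.max() + 1e-9),
        }
    )
    if fit.cov is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.params, fit.cov, size=n_boot)
        boot = np.stack([curves(d) for d in draws])  # (B, 3, G)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        for i, name in enumerate(["psi_sp1", "psi_sp2", "psi_both"]):
            out[name + "_lcl"], out[name + "_ucl"] = lo[i], hi[i]
    return out


def _station_weights(fit: CTMSOFit, species: str, condition: str | None, mode: str):
    """Station weights for conditioning on the other species' presence."""
    data = fit.prepared.data
    other = [s for s in data.species if s != species][0]
    n = fit.prepared.n_stations
    if condition is None:
        w = np.ones(n)
    elif mode == "detected":
        det = fit.prepared.det[other]["n"] > 0
        w = det.astype(float) if condition == "co-occurring" else (~det).astype(float)
    elif mode == "latent":
        terms = fit.prepared.state_log_terms(fit.params)
        post = np.exp(terms - special.logsumexp(terms, axis=1, keepdims=True))
        p_other = post[:, 2] + post[:, 3] if other == data.species[1] else post[:, 1] + post[:, 3]
        w = p_other if condition == "co-occurring" else 1.0 - p_other
    else:
        raise ValueError(f"unknown condition mode {mode!r}")
    if w.sum() <= 0:
        raise ValueError("no stations in the requested condition class")
    return w / w.sum()


def _mean_intensity_by_tau(fit: CTMSOFit, species: str, weights: np.ndarray, theta=None):
    """Class-weighted mean intensity in whole-hour time-of-day bins."""
    prep = fit.prepared
    theta = fit.params if theta is None else theta
    _, det_par, eta = prep.split(theta)
    alpha, gamma = det_par[species]
    lam_log = alpha + prep.Fq @ gamma
    if species == prep.data.species[0] and prep.model.lag:
        lam_log = lam_log + eta * prep.uq
    lam = np.exp(lam_log) * weights[prep.q_station]
    tau_bin = (prep.q_mid % 24.0).astype(int) % 24
    tot_w = np.bincount(tau_bin, weights=prep.q_w * weights[prep.q_station], minlength=24)
    tot = np.bincount(tau_bin, weights=prep.q_w * lam, minlength=24)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lam = np.where(tot_w > 0, tot / tot_w, 0.0)
    return mean_lam  # per-hour intensity in 24 hourly bins


def activity_curve(
    fit: CTMSOFit,
    species: str,
    condition: str | None = None,
    condition_mode: str = "detected",
) -> pd.DataFrame:
    """Normalized diel activity density over the 24 h cycle.

    ``condition`` restricts to stations where the other species was
    ("co-occurring") or was not ("alone") present, classified by detections by
    default or by latent-state posteriors (``condition_mode="latent"``).
    Returns hourly bin centers and a density integrating to 1 over 24 h.
    """
    w = _station_weights(fit, species, condition, condition_mode)
    lam = _mean_intensity_by_tau(fit, species, w)
    dens = lam / lam.sum()  # per 1 h bin; integrates to 1 over the day
    return pd.DataFrame({"tau": np.arange(24) + 0.5, "density": dens})


def binned_detection_proportions(
    fit: CTMSOFit,
    species: str,
    bin_hours: int = 3,
    condition: str | None = None,
    condition_mode: str = "detected",
    n_boot: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected share of detections per time-of-day bin, with bootstrap CIs."""
    if 24 % bin_hours:
        raise ValueError("bin_hours must divide 24")
    w = _station_weights(fit, species, condition, condition_mode)
    nb = 24 // bin_hours

    def props(theta):
        lam = _mean_intensity_by_tau(fit, species, w, theta)
        binned = lam.reshape(nb, bin_hours).sum(axis=1)
        return binned / binned.sum()

    est = props(fit.params)
    out = pd.DataFrame(
        {"bin_start": np.arange(nb) * bin_hours, "bin_end": (np.arange(nb) + 1) * bin_hours,
         "proportion": est}
    )
    if fit.cov is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.params, fit.cov, size=n_boot)
        boot = np.stack([props(d) for d in draws])
        out["lcl"], out["ucl"] = np.percentile(boot, [2.5, 97.5], axis=0)
    return out
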