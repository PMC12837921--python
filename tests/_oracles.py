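"""Independent brute-force oracles used to validate the fast likelihoods.

These deliberately use plain Python loops and literal expansions of the model
definitions so that they share no code path with the implementations they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from felicoex import ctmso, scr


def brute_scr_negloglik(params, hist, mask, spec) -> float:
    """Literal triple-sum SCR likelihood (individuals × mask × classes)."""
    d100, g0, sigma, pmix = scr._unpack(np.asarray(params, float), spec)
    dens = d100 / 100.0
    a = mask.cell_area
    occ = hist.n_occasions
    pi = [pmix, 1 - pmix]
    n, k = hist.counts.shape
    y = np.zeros((n, k, occ))
    idx = {ind: i for i, ind in enumerate(hist.individuals)}
    for ind, o, kk in zip(
        hist.detections["individual"], hist.detections["occasion"], hist.detections["trap"]
    ):
        y[idx[ind], kk, o - 1] = 1
    ll = 0.0
    for i in range(n):
        tot = 0.0
        for c in range(2):
            if hist.sex[i] not in ("U", scr.SEX_CLASSES[c]):
                continue
            sx = 0.0
            for x in mask.points:
                pr = 1.0
                for kk in range(k):
                    d = math.dist(hist.traps[kk], x)
                    p = g0[c] * math.exp(-d * d / (2 * sigma[c] ** 2))
                    for o in range(occ):
                        pr *= p if y[i, kk, o] else (1 - p)
                sx += pr
            tot += pi[c] * sx
        ll += math.log(dens * a * tot)
    expected = 0.0
    for x in mask.points:
        for c in range(2):
            prod = 1.0
            for kk in range(k):
                d = math.dist(hist.traps[kk], x)
                p = g0[c] * math.exp(-d * d / (2 * sigma[c] ** 2))
                prod *= (1 - p) ** occ
            expected += pi[c] * (1 - prod)
    return -(ll - dens * a * expected)


def brute_ctmso_negloglik(theta, data, model, quad_minutes=60.0) -> float:
    """State-enumerating two-species continuous-time likelihood."""
    prep = ctmso._Prepared(data, model, quad_minutes)
    beta, det, eta = prep.split(np.asarray(theta, float))
    total = 0.0
    for st in data.stations:
        f = {}
        for key in ("f1", "f2", "f12"):
            x = [1.0] + [st.covariates[c] for c in model.occ_covs[key]]
            f[key] = sum(a * b for a, b in zip(x, beta[key]))
        logw = [0.0, f["f1"], f["f2"], f["f1"] + f["f2"] + f["f12"]]
        z_norm = sum(math.exp(v) for v in logw)
        psi = [math.exp(v) / z_norm for v in logw]
        lj = 0.0
        for s_idx, (z1, z2) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
            term = psi[s_idx]
            for sp, z in zip(data.species, (z1, z2)):
                times = st.times.get(sp, [])
                alpha, gamma = det[sp]

                def lam(t):
                    u = 0.0
                    if sp == data.species[0] and model.lag:
                        raw = ctmso.time_since_covariate(
                            st.times[data.species[1]], t, data.u_max
                        )
                        u = (raw - prep.u_mean) / prep.u_sd
                    tau = t % 24.0
                    fr = [
                        math.cos(2 * math.pi * tau / 24),
                        math.sin(2 * math.pi * tau / 24),
                        math.cos(4 * math.pi * tau / 24),
                        math.sin(4 * math.pi * tau / 24),
                    ]
                    return math.exp(alpha + sum(a * b for a, b in zip(fr, gamma)) + eta * u)

                if z == 0:
                    term *= 1.0 if len(times) == 0 else 0.0
                else:
                    t0, t1 = st.window
                    dt = quad_minutes / 60.0
                    nf = int((t1 - t0) // dt)
                    lam_int = sum(dt * lam(t0 + (i + 0.5) * dt) for i in range(nf))
                    rem = (t1 - t0) - nf * dt
                    if rem > 1e-9:
                        lam_int += rem * lam(t0 + nf * dt + rem / 2)
                    pr = math.exp(-lam_int)
                    for t in times:
                        pr *= lam(t)
                    term *= pr
            lj += term
        total += math.log(lj)
    return -total


def enumerate_span_moments(c: int, k: int) -> tuple[float, float]:
    """Mean/variance of the occasion span by exhaustive subset enumeration."""
    spans = [max(s) - min(s) for s in itertools.combinations(range(1, k + 1), c)]
    e = sum(spans) / len(spans)
    v = sum((s - e) ** 2 for s in spans) / len(spans)
    return e, v


def plackett_luce_inclusion(probs, taxon_idx: int, m: int) -> float:
    """P(item in the first m successive weighted draws WOR) by enumeration."""
    n = len(probs)
    total = 0.0
    for perm in itertools.permutations(range(n), m):
        p = 1.0
        rem = 1.0
        for j in perm:
            p *= probs[j] / rem
            rem -= probs[j]
        if taxon_idx in perm:
            total += p
    return total
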