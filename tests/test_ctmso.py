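import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from felicoex import ctmso, synth
from _oracles import brute_ctmso_negloglik

SP1, SP2 = "golden_cat", "leopard"
DIST_MODEL = ctmso.CTMSOModel(
    "dist", {"f1": ["dist_linear"], "f2": ["dist_linear"], "f12": ["dist_linear"]}
)


def toy_data(lag_times=True):
    a = ctmso.StationData(
        "A", {"dist_linear": 0.5}, (0.0, 72.0),
        {SP1: np.array([5.0, 30.0]), SP2: np.array([10.0]) if lag_times else np.array([])},
    )
    b = ctmso.StationData(
        "B", {"dist_linear": -1.0}, (0.0, 72.0),
        {SP1: np.array([]), SP2: np.array([40.0, 41.5])},
    )
    return ctmso.CTMSOData([a, b], species=(SP1, SP2))


class TestPsi:
    def test_uniform_at_zero(self):
        assert np.allclose(ctmso.psi_from_f(0.0, 0.0, 0.0), 0.25)

    def test_independence_when_f12_zero(self):
        f1, f2 = 0.7, -1.2
        p00, p10, p01, p11 = ctmso.psi_from_f(f1, f2, 0.0)
        m1, m2 = p10 + p11, p01 + p11
        assert p11 == pytest.approx(m1 * m2, rel=1e-12)
        assert m1 == pytest.approx(1 / (1 + math.exp(-f1)), rel=1e-12)

    def test_log_linear_definition(self):
        # hand enumeration of psi_z ∝ exp(z1 f1 + z2 f2 + z1 z2 f12)
        f1, f2, f12 = 1.0, 1.0, -2.0
        w = [math.exp(0), math.exp(f1), math.exp(f2), math.exp(f1 + f2 + f12)]
        expect = np.array(w) / sum(w)
        assert np.allclose(ctmso.psi_from_f(f1, f2, f12), expect, atol=1e-12)
        assert expect[0] == pytest.approx(expect[3])  # f1+f2+f12 = 0 here

    @given(st.floats(-8, 8), st.floats(-8, 8), st.floats(-8, 8))
    def test_normalization(self, f1, f2, f12):
        assert sum(ctmso.psi_from_f(f1, f2, f12)) == pytest.approx(1.0, abs=1e-12)


class TestIntensity:
    def test_flat_when_no_harmonics(self):
        t = np.linspace(0, 48, 97)
        lam = ctmso.intensity(t, alpha=-2.0, gamma=np.zeros(4))
        assert np.allclose(lam, math.exp(-2.0))

    def test_first_harmonic_peak_locations(self):
        tau = np.linspace(0, 24, 2401)
        lam = ctmso.intensity(tau, 0.0, np.array([1.0, 0.0, 0.0, 0.0]))
        assert tau[np.argmax(lam)] in (0.0, 24.0)
        assert tau[np.argmin(lam)] == pytest.approx(12.0, abs=0.02)

    def test_daily_integral_closed_form(self):
        lam_int = ctmso.cumulative_intensity(-1.5, np.zeros(4), (0.0, 24.0), quad_minutes=60)
        assert lam_int == pytest.approx(24 * math.exp(-1.5), rel=1e-12)


class TestCumulativeIntensity:
    def test_constant_rate(self):
        assert ctmso.cumulative_intensity(math.log(0.1), np.zeros(4), (0.0, 48.0)) == (
            pytest.approx(4.8, rel=1e-12)
        )

    def test_harmonic_integrates_like_constant_over_full_days(self):
        # ∫ exp(a2 cos(4πτ/24)) over whole days is τ-shift free; compare with
        # fine quadrature as the reference
        g = np.array([0.0, 0.0, 0.6, 0.0])
        coarse = ctmso.cumulative_intensity(-2.0, g, (0.0, 96.0), quad_minutes=60)
        fine = ctmso.cumulative_intensity(-2.0, g, (0.0, 96.0), quad_minutes=1)
        assert coarse == pytest.approx(fine, rel=5e-3)

    def test_refinement_changes_little(self):
        g = np.array([0.8, -0.3, 0.2, 0.1])
        l60 = ctmso.cumulative_intensity(-2.0, g, (0.0, 240.0), quad_minutes=60)
        l30 = ctmso.cumulative_intensity(-2.0, g, (0.0, 240.0), quad_minutes=30)
        assert abs(l30 - l60) / l60 < 0.005

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            ctmso.cumulative_intensity(0.0, np.zeros(4), (10.0, 10.0))


class TestTimeSince:
    def test_basic_and_cap(self):
        assert ctmso.time_since_covariate([10.0], 12.0) == 2.0
        assert ctmso.time_since_covariate([], 12.0, u_max=72.0) == 72.0
        assert ctmso.time_since_covariate([10.0, 20.0], 21.0) == 1.0
        assert ctmso.time_since_covariate([1.0], 200.0, u_max=72.0) == 72.0


class TestLikelihood:
    def test_no_detection_station_expansion(self):
        st_empty = ctmso.StationData("E", {"dist_linear": 0.0}, (0.0, 48.0),
                                     {SP1: np.array([]), SP2: np.array([])})
        data = ctmso.CTMSOData([st_empty], species=(SP1, SP2))
        theta = np.array([0.3, 0.1, -0.2, 0.4, 0.5, -0.3,
                          -2.0, 0.1, -0.1, 0.2, 0.0,
                          -2.5, 0.0, 0.3, -0.2, 0.1])
        nll = ctmso.ctmso_negloglik(theta, data, DIST_MODEL)
        p00, p10, p01, p11 = ctmso.psi_from_f(0.3, -0.2, 0.5)
        l1 = ctmso.cumulative_intensity(-2.0, np.array([0.1, -0.1, 0.2, 0.0]), (0, 48.0))
        l2 = ctmso.cumulative_intensity(-2.5, np.array([0.0, 0.3, -0.2, 0.1]), (0, 48.0))
        expect = p00 + p10 * math.exp(-l1) + p01 * math.exp(-l2) + p11 * math.exp(-l1 - l2)
        assert nll == pytest.approx(-math.log(expect), rel=1e-12)

    def test_both_detected_leaves_only_joint_state(self):
        st_both = ctmso.StationData("B", {"dist_linear": 0.0}, (0.0, 48.0),
                                    {SP1: np.array([3.0]), SP2: np.array([7.0])})
        data = ctmso.CTMSOData([st_both], species=(SP1, SP2))
        theta = np.zeros(16)
        theta[6] = theta[11] = -2.0
        nll = ctmso.ctmso_negloglik(theta, data, DIST_MODEL)
        lam = math.exp(-2.0)
        lam_int = 48 * lam
        expect = 0.25 * (math.exp(-lam_int) * lam) ** 2
        assert nll == pytest.approx(-math.log(expect), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 2])
    def test_matches_state_enumeration_oracle(self, seed):
        data = toy_data()
        model = ctmso.add_lag(DIST_MODEL)
        rng = np.random.default_rng(seed)
        theta = rng.normal(0, 0.5, model.n_params())
        fast = ctmso.ctmso_negloglik(theta, data, model)
        slow = brute_ctmso_negloglik(theta, data, model)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_detection_outside_window_rejected(self):
        with pytest.raises(ValueError):
            ctmso.StationData("X", {}, (0.0, 24.0), {SP1: np.array([30.0]), SP2: np.array([])})

    def test_factorizes_into_single_species_models_at_f12_zero(self):
        """With f12 ≡ 0 the joint likelihood is the product of two
        independent single-species continuous-time occupancy likelihoods."""
        model = ctmso.CTMSOModel("nocov", {"f1": [], "f2": [], "f12": []})
        data = toy_data()
        theta = np.array([0.4, -0.6, 0.0,
                          -2.2, 0.3, -0.1, 0.2, 0.0,
                          -2.6, 0.1, 0.2, -0.4, 0.1])
        joint = ctmso.ctmso_negloglik(theta, data, model)

        def single(f, alpha, gamma, sp):
            psi = 1 / (1 + math.exp(-f))
            total = 0.0
            for s in data.stations:
                lam_int = ctmso.cumulative_intensity(alpha, gamma, s.window)
                times = s.times[sp]
                if len(times) == 0:
                    lik = (1 - psi) + psi * math.exp(-lam_int)
                else:
                    lik = psi * math.exp(-lam_int) * np.prod(
                        ctmso.intensity(times, alpha, gamma)
                    )
                total += math.log(lik)
            return -total

        split = single(0.4, -2.2, np.array([0.3, -0.1, 0.2, 0.0]), SP1) + single(
            -0.6, -2.6, np.array([0.1, 0.2, -0.4, 0.1]), SP2
        )
        assert joint == pytest.approx(split, rel=1e-12)


@pytest.fixture(scope="module")
def small_fit():
    cfg = synth.preset("nnnp", seed=21)
    cfg.ctmso.survey_days = 45
    grid = synth.make_nested_grid(seed=2)
    data, truth = synth.simulate_ctmso(cfg, grid)
    fit = ctmso.fit_single(data, DIST_MODEL, quad_minutes=60)
    return data, truth, fit


class TestFitAndCurves:
    def test_fit_converges_with_wald_table(self, small_fit):
        _, _, fit = small_fit
        assert fit.converged
        tab = fit.coef_table()
        assert len(tab) == fit.K
        assert ((tab["lcl"] <= tab["estimate"]) & (tab["estimate"] <= tab["ucl"])).all()
        assert fit.aic == pytest.approx(-2 * fit.logL + 2 * fit.K, rel=1e-12)

    def test_quadrature_refinement_shifts_logl_below_tenth_percent(self, small_fit):
        data, _, fit60 = small_fit
        fit5 = ctmso.fit_single(data, DIST_MODEL, quad_minutes=5, compute_se=False)
        assert abs(fit5.logL - fit60.logL) / abs(fit60.logL) < 1e-3

    def test_occupancy_curves_product_rule_and_extrapolation_flag(self, small_fit):
        data, _, fit = small_fit
        # zero out the interaction block: psi11 must equal product of marginals
        theta = fit.params.copy()
        i12 = fit.coef_names.index("f12:(Intercept)")
        theta[i12 : i12 + 2] = 0.0
        fit0 = ctmso.CTMSOFit(fit.model, theta, fit.coef_names, fit.logL, fit.aic,
                              None, True, prepared=fit.prepared)
        cur = ctmso.occupancy_curves(fit0, data, n_boot=0)
        assert np.allclose(cur["psi_both"], cur["psi_sp1"] * cur["psi_sp2"], atol=1e-12)
        wide = ctmso.occupancy_curves(fit0, data, grid=np.array([-50.0, 0.0, 50.0]), n_boot=0)
        assert list(wide["extrapolated"]) == [True, False, True]

    def test_prey_covariate_moves_only_dominant_marginal(self, small_fit):
        data, _, _ = small_fit
        model = ctmso.CTMSOModel(
            "prey", {"f1": ["dist_linear"], "f2": ["dist_linear", "prey_rai"],
                     "f12": ["dist_linear"]},
        )
        fit = ctmso.fit_single(data, model, compute_se=False)
        lo = ctmso.occupancy_curves(fit, data, fix={"prey_rai": -1.0}, n_boot=0)
        hi = ctmso.occupancy_curves(fit, data, fix={"prey_rai": 1.0}, n_boot=0)
        # species-1 conditional log-odds f1 excludes prey RAI, so its "alone"
        # weight is untouched while the dominant species' marginal moves
        assert not np.allclose(lo["psi_sp2"], hi["psi_sp2"])

    def test_activity_curve_flat_and_normalized(self, small_fit):
        data, _, fit = small_fit
        theta = fit.params.copy()
        for sp in (SP1, SP2):
            i = fit.coef_names.index(f"a1:{sp}")
            theta[i : i + 4] = 0.0
        flat_fit = ctmso.CTMSOFit(fit.model, theta, fit.coef_names, fit.logL, fit.aic,
                                  None, True, prepared=fit.prepared)
        cur = ctmso.activity_curve(flat_fit, SP2)
        assert np.allclose(cur["density"], 1 / 24, atol=1e-12)
        cur2 = ctmso.activity_curve(fit, SP1, condition="co-occurring")
        assert cur2["density"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_diurnal_peak_falls_in_midday_bin(self, small_fit):
        _, _, fit = small_fit
        # species 1 truth is diurnal (first harmonic trough at midnight)
        bins = ctmso.binned_detection_proportions(fit, SP1, bin_hours=3, n_boot=0)
        assert bins["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        peak = bins.loc[bins["proportion"].idxmax()]
        assert 9 <= peak["bin_start"] <= 12

    def test_crepuscular_truth_yields_bimodal_curve(self, small_fit):
        _, _, fit = small_fit
        cur = ctmso.activity_curve(fit, SP2)["density"].to_numpy()
        # second-harmonic truth peaks near 06:00 and 18:00
        assert cur[6] > cur[12] and cur[18] > cur[12]
        assert cur[6] > cur[0] and cur[18] > cur[0]

    def test_binned_flat_intensity_is_one_eighth(self, small_fit):
        data, _, fit = small_fit
        theta = fit.params.copy()
        for sp in (SP1, SP2):
            i = fit.coef_names.index(f"a1:{sp}")
            theta[i : i + 4] = 0.0
        flat_fit = ctmso.CTMSOFit(fit.model, theta, fit.coef_names, fit.logL, fit.aic,
                                  None, True, prepared=fit.prepared)
        bins = ctmso.binned_detection_proportions(flat_fit, SP2, bin_hours=3, n_boot=0)
        assert np.allclose(bins["proportion"], 0.125, atol=1e-12)

    def test_negative_marginal_positive_interaction_distance_pattern(self, small_fit):
        """With negative distance effects on both conditional log-odds and a
        positive one on the interaction, marginals fall while co-occurrence
        rises along the distance gradient (the qualitative field pattern)."""
        data, _, fit = small_fit
        theta = np.zeros_like(fit.params)
        for name, val in [("f1:(Intercept)", 0.1), ("f1:dist_linear", -0.68),
                          ("f2:(Intercept)", 0.17), ("f2:dist_linear", -0.56),
                          ("f12:(Intercept)", -1.63), ("f12:dist_linear", 1.12)]:
            theta[fit.coef_names.index(name)] = val
        toy = ctmso.CTMSOFit(fit.model, theta, fit.coef_names, 0.0, 0.0, None, True,
                             prepared=fit.prepared)
        cur = ctmso.occupancy_curves(toy, data, grid=np.linspace(-1.5, 1.5, 9), n_boot=0)
        assert (np.diff(cur["psi_sp1"]) < 0).all()
        assert (np.diff(cur["psi_sp2"]) < 0).all()
        assert (np.diff(cur["psi_both"]) > 0).all()

    def test_single_species_degenerate_data_flagged_or_bounded(self):
        """With species 2 never detected, f2 drifts to its boundary; the fit
        must either flag non-convergence or report a strongly negative f2."""
        st_list = [
            ctmso.StationData(f"S{i}", {"dist_linear": x}, (0.0, 240.0),
                              {SP1: np.array([10.0 + i]), SP2: np.array([])})
            for i, x in enumerate(np.linspace(-1, 1, 12))
        ]
        data = ctmso.CTMSOData(st_list, species=(SP1, SP2))
        fit = ctmso.fit_single(data, DIST_MODEL, compute_se=True)
        assert (not fit.converged) or fit.coef("f2:(Intercept)") < -2.0
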