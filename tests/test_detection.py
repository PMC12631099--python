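import math

import numpy as np
import pytest

from groupdens.detection import (
    AngleFit,
    DetectionFit,
    DetectionModel,
    _p_hat_edr,
    candidate_models,
    detection_curve,
    estimate_overdispersion,
    fit_all_candidates,
    fit_detection_function,
    fit_effective_angle,
    qaic,
    select_model,
    truncate_distances,
)
from groupdens.observations import band_for_distance, distance_bands

from .conftest import sample_point_transect_halfnormal, sample_point_transect_hazard


def bands_from_distances(r, max_d=25.0):
    return [band_for_distance(x, max_d) for x in r]


class TestClosedForms:
    def test_uniform_degenerate(self, rng):
        r = rng.uniform(1, 23, 200)
        fit = fit_detection_function(
            bands_from_distances(r), DetectionModel("uniform", 0), 0.0, 24.0
        )
        assert fit.p_hat == pytest.approx(1.0)
        assert fit.edr == pytest.approx(24.0)

    def test_half_normal_sigma5_w24(self):
        # P = (2 s^2 / w^2)(1 - exp(-w^2 / 2 s^2)) = 0.08680; rho = 7.071
        m = DetectionModel("half-normal", 0, params=np.array([math.log(5.0)]))
        p, edr = _p_hat_edr(m, m.params, 0.0, 24.0)
        assert p == pytest.approx(0.08680, rel=5e-4)
        assert edr == pytest.approx(7.071, rel=5e-4)

    def test_p_hat_monotone_decreasing_in_w(self):
        m = DetectionModel("half-normal", 0, params=np.array([math.log(5.0)]))
        ps = [_p_hat_edr(m, m.params, 0.0, w)[0] for w in (10, 15, 20, 24)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_edr_limit_sigma_sqrt2(self):
        # rho -> sigma * sqrt(2) as w -> infinity for half-normal
        m = DetectionModel("half-normal", 0, params=np.array([math.log(5.0)]))
        _, edr = _p_hat_edr(m, m.params, 0.0, 200.0)
        assert edr == pytest.approx(5.0 * math.sqrt(2), rel=1e-3)


class TestFitting:
    def test_mle_consistency_half_normal(self, rng):
        r = sample_point_transect_halfnormal(8.0, 24.0, 20000, rng)
        fit = fit_detection_function(
            bands_from_distances(r, 24.0), DetectionModel("half-normal", 0), 0.0, 24.0
        )
        assert math.exp(fit.model.params[0]) == pytest.approx(8.0, rel=0.03)
        assert np.isfinite(fit.se_edr) and fit.se_edr > 0

    def test_too_few_bins(self):
        bands = [(0.0, 0.5)] * 30
        with pytest.raises(ValueError):
            fit_detection_function(bands, DetectionModel("hazard-rate", 2), 0.0, 25.0)

    def test_edr_invariant_to_observed_band_refinement(self, rng):
        # p_hat depends on the fitted curve, not the histogram resolution used
        r = sample_point_transect_halfnormal(6.0, 24.0, 5000, rng)
        fit = fit_detection_function(
            bands_from_distances(r, 24.0), DetectionModel("half-normal", 0), 0.0, 24.0
        )
        m = fit.model
        p1, e1 = _p_hat_edr(m, m.params, 0.0, 24.0)
        assert e1 == pytest.approx(fit.edr, rel=1e-9)
        assert math.sqrt(p1 * 24.0**2) == pytest.approx(e1, rel=1e-9)


class TestTruncation:
    def test_fixed_window(self):
        bands = distance_bands(25.0)
        kept, wl, w = truncate_distances(list(bands), left=2.0, right_rule=24.0)
        assert wl == 2.0 and w == 24.0
        assert all(lo >= 2.0 and hi <= 24.0 for lo, hi in kept)
        assert (1.5, 2.0) not in kept and (24.0, 25.0) not in kept

    def test_identity(self):
        bands = distance_bands(25.0)
        kept, wl, w = truncate_distances(list(bands), left=0.0, right_rule=25.0)
        assert kept == bands

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            truncate_distances([(0.0, 0.5)], left=1.0, right_rule=24.0)

    def test_detection_prob_rule(self, rng):
        r = sample_point_transect_halfnormal(6.0, 25.0, 4000, rng)
        bands = bands_from_distances(r, 25.0)
        kept, wl, w = truncate_distances(
            bands, left=0.0, right_rule="detection-prob-0.15",
            model=DetectionModel("half-normal", 0),
        )
        # rule re-evaluation oracle: g(w) >= 0.15 at the returned w ...
        fit = fit_detection_function(kept, DetectionModel("half-normal", 0), wl, w)
        g = detection_curve(fit.model, w)
        assert float(g(np.array([w]))[0]) >= 0.15
        # ... and the next-wider window was rejected
        assert w < 25.0
        w_next = w + (0.5 if w < 10 else 1.0)
        kept2 = [b for b in bands if b[1] <= w_next + 1e-9]
        fit2 = fit_detection_function(kept2, DetectionModel("half-normal", 0), 0.0, w_next)
        g2 = detection_curve(fit2.model, w_next)
        assert float(g2(np.array([w_next]))[0]) < 0.15


class TestOverdispersion:
    def _perfect_fit(self):
        # uniform model with counts exactly equal to expectation -> chi2 = 0
        edges = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        widths_rg = np.diff(edges**2) / 2  # integral of r over each bin
        counts = 1000 * widths_rg / widths_rg.sum()
        model = DetectionModel("uniform", 0, params=np.zeros(0))
        return DetectionFit(
            model=model, w_left=0.0, w_right=2.0, loglik=0.0, n_obs=1000,
            p_hat=1.0, edr=2.0, bin_edges=edges, bin_counts=counts,
        )

    def test_exact_agreement_floors_at_one(self):
        assert estimate_overdispersion(self._perfect_fit()) == 1.0

    def test_df_guard(self):
        fit = self._perfect_fit()
        fit.bin_edges = np.array([0.0, 0.5, 1.0])
        fit.bin_counts = np.array([10.0, 20.0])
        fit.model = DetectionModel("half-normal", 0, params=np.array([0.0]))
        with pytest.raises(ValueError):
            estimate_overdispersion(fit)

    def test_duplication_roughly_doubles_c_hat(self, rng):
        r = sample_point_transect_halfnormal(7.0, 24.0, 3000, rng)
        bands = bands_from_distances(r, 24.0)
        fit1 = fit_detection_function(bands, DetectionModel("half-normal", 0), 0.0, 24.0)
        fit2 = fit_detection_function(bands * 2, DetectionModel("half-normal", 0), 0.0, 24.0)
        c1 = estimate_overdispersion(fit1)
        c2 = estimate_overdispersion(fit2)
        assert c2 == pytest.approx(2 * c1, rel=0.35)

    def test_independent_data_near_one(self):
        cs = []
        for seed in range(8):
            r = sample_point_transect_halfnormal(
                7.0, 24.0, 2000, np.random.default_rng(seed)
            )
            fit = fit_detection_function(
                bands_from_distances(r, 24.0), DetectionModel("half-normal", 0), 0.0, 24.0
            )
            cs.append(estimate_overdispersion(fit))
        assert 1.0 <= np.mean(cs) < 1.4


class TestQaicSelection:
    def _fit(self, loglik, family="half-normal", n_adjust=0):
        n_params = DetectionModel(family, n_adjust).n_params
        return DetectionFit(
            model=DetectionModel(family, n_adjust, params=np.zeros(n_params)),
            w_left=0.0, w_right=24.0, loglik=loglik, n_obs=100, p_hat=0.5, edr=17.0,
        )

    def test_chat_one_equals_aic(self):
        fit = self._fit(-123.0)
        assert qaic(fit, 1.0) == pytest.approx(-2 * -123.0 + 2 * 2)

    def test_extra_param_costs_two(self):
        a = self._fit(-100.0, "half-normal", 0)
        b = self._fit(-100.0, "half-normal", 1)
        assert qaic(b, 2.0) - qaic(a, 2.0) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        fit = self._fit(-100.0, "hazard-rate", 0)  # 2 params
        assert qaic(fit, 4.0) == pytest.approx(56.0)

    def test_single_candidate_returned(self):
        fit = self._fit(-50.0)
        assert select_model([fit], 1.0) is fit

    def test_tie_prefers_fewer_params(self):
        # equal QAIC requires loglik compensating the parameter penalty
        a = self._fit(-100.0, "half-normal", 0)
        b = self._fit(-99.0, "half-normal", 1)
        assert qaic(a, 1.0) == pytest.approx(qaic(b, 1.0))
        assert select_model([b, a], 1.0) is a

    def test_tie_family_order(self):
        a = self._fit(-100.0, "half-normal", 1)  # 2 params
        b = self._fit(-100.0, "hazard-rate", 0)  # 2 params
        assert select_model([b, a], 1.0) is a

    def test_candidate_set_is_the_documented_seven(self):
        models = candidate_models()
        assert [(m.family, m.n_adjust) for m in models] == [
            ("half-normal", 0), ("half-normal", 1),
            ("uniform", 1), ("uniform", 2),
            ("hazard-rate", 0), ("hazard-rate", 1), ("hazard-rate", 2),
        ]

    @pytest.mark.slow
    def test_hazard_generated_data_selects_hazard_family(self):
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            r = sample_point_transect_hazard(
                7.0, 3.0, 24.0, 1000, np.random.default_rng(1000 + seed)
            )
            sel, _, _ = fit_all_candidates(bands_from_distances(r, 24.0), 0.0, 24.0)
            wins += sel.model.family == "hazard-rate"
        assert wins / n_rep >= 0.8


class TestEffectiveAngle:
    def test_uniform_angles_give_full_fov(self, rng):
        h = 0.4
        a = rng.uniform(0, h, 2000)
        fit = fit_effective_angle(a, h)
        assert fit.effective_angle == pytest.approx(2 * h, rel=0.02)

    def test_tight_falloff_gives_small_angle(self, rng):
        h = 0.4
        a = np.abs(rng.normal(0, 0.02, 2000))
        fit = fit_effective_angle(a, h)
        assert fit.effective_angle < 0.2 * h

    def test_halfnormal_recovery_closed_form(self, rng):
        h, sa = 0.4, 0.25
        a = []
        while len(a) < 3000:
            x = rng.uniform(0, h, 5000)
            keep = rng.random(5000) < np.exp(-0.5 * (x / sa) ** 2)
            a.extend(x[keep][: 3000 - len(a)])
        fit = fit_effective_angle(np.array(a), h)
        theta_true = 2 * min(math.sqrt(2 * sa**2 * (1 - math.exp(-(h**2) / (2 * sa**2)))), h)
        assert fit.effective_angle == pytest.approx(theta_true, rel=0.05)
        assert np.isfinite(fit.se) and fit.se > 0

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            fit_effective_angle(np.array([0.1] * 9), 0.4)

    def test_out_of_range_angles(self):
        with pytest.raises(ValueError):
            fit_effective_angle(np.array([0.5] * 20), 0.4)
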