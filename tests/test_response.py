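"""Response-curve fitting and EONR derivation, checked against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eonrcast.response import (
    DEFAULT_N_RATES,
    FitError,
    FittedResponse,
    NResponseData,
    compute_eonr,
    eonr_from_data,
    fit_quad_plateau,
    fit_quadratic,
    profit_grid_eonr,
    select_model,
)

RATES = np.asarray(DEFAULT_N_RATES)


def quad_yields(a, b, c, rates=RATES):
    return a + b * rates + c * rates**2


def qp_yields(a, b, c, rates=RATES):
    n0 = -b / (2 * c)
    return np.where(rates <= n0, a + b * rates + c * rates**2, a - b**2 / (4 * c))


def make_fit(b, c, a=6000.0, form="quadratic"):
    """A significant synthetic fit with given coefficients."""
    return FittedResponse(
        form=form, a=a, b=b, c=c, sse=0.0, r_squared=1.0, p_value=0.0,
        significant=True, join_n0=(-b / (2 * c) if form == "quad_plateau" else None),
    )


class TestQuadraticFit:
    def test_noiseless_recovery(self):
        fit = fit_quadratic(NResponseData(RATES, quad_yields(6000, 40, -0.08)))
        assert fit.a == pytest.approx(6000, abs=1e-6)
        assert fit.b == pytest.approx(40, abs=1e-6)
        assert fit.c == pytest.approx(-0.08, abs=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0) and fit.significant

    def test_constant_yields_nonsignificant(self):
        fit = fit_quadratic(NResponseData(RATES, np.full(5, 9000.0)))
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0 and not fit.significant

    def test_convex_fit_never_significant(self):
        fit = fit_quadratic(NResponseData(RATES, quad_yields(6000, -5, 0.05)))
        assert fit.c > 0 and not fit.significant

    def test_too_few_distinct_rates(self):
        with pytest.raises(ValueError):
            NResponseData(np.array([0.0, 0.0, 100.0, 100.0]), np.full(4, 1.0))

    def test_monte_carlo_unbiased(self):
        """Mean recovered coefficients land within 3 SE of truth (500 reps)."""
        rng = np.random.default_rng(7)
        truth = (5000.0, 30.0, -0.06)
        y0 = quad_yields(*truth)
        est = np.array(
            [
                [f.a, f.b, f.c]
                for f in (
                    fit_quadratic(NResponseData(RATES, y0 + rng.normal(0, 100, 5)))
                    for _ in range(500)
                )
            ]
        )
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * se)


class TestQuadPlateauFit:
    def test_noiseless_join_recovery(self):
        # b=40, c=-0.1 puts the smooth join at N0=200
        fit = fit_quad_plateau(NResponseData(RATES, qp_yields(6000, 40, -0.1)))
        assert fit.join_n0 == pytest.approx(200.0, abs=1e-3)
        assert fit.significant

    def test_plateau_is_continuous_with_zero_slope(self):
        fit = fit_quad_plateau(NResponseData(RATES, qp_yields(6000, 40, -0.1)))
        n0 = fit.join_n0
        eps = 1e-6
        below, above = fit.predict(n0 - eps), fit.predict(n0 + eps)
        assert above == pytest.approx(below, abs=1e-3)
        # numerical slope vanishes on both sides of the join
        assert (fit.predict(n0) - fit.predict(n0 - eps)) / eps == pytest.approx(0.0, abs=1e-2)
        assert (fit.predict(n0 + eps) - fit.predict(n0)) / eps == 0.0

    def test_linear_data_flagged_nonsignificant(self):
        fit = fit_quad_plateau(NResponseData(RATES, 5000.0 + 20.0 * RATES))
        assert fit.form == "quad_plateau" and not fit.significant

    def test_noisy_join_recovery_median(self):
        """Median recovered join over 500 noisy replicates is within 15 of truth."""
        rng = np.random.default_rng(11)
        y0 = qp_yields(6000, 40, -0.1)
        n0s = [
            fit_quad_plateau(NResponseData(RATES, y0 + rng.normal(0, 150, 5))).join_n0
            for _ in range(500)
        ]
        assert abs(float(np.median(n0s)) - 200.0) < 15.0


class TestModelSelection:
    def test_smaller_sse_wins(self):
        quad = make_fit(40, -0.08)
        qp = make_fit(40, -0.1, form="quad_plateau")
        quad = FittedResponse(**{**quad.__dict__, "sse": 1e5})
        qp = FittedResponse(**{**qp.__dict__, "sse": 8e4})
        assert select_model(quad, qp) is qp

    def test_only_significant_candidate_wins(self):
        quad = make_fit(40, -0.08)
        qp = FittedResponse(
            form="quad_plateau", a=0, b=0, c=-1e-12, sse=1.0, r_squared=0.0,
            p_value=0.9, significant=False, join_n0=0.0,
        )
        assert select_model(quad, qp) is quad

    def test_exact_tie_goes_to_plateau(self):
        quad = make_fit(40, -0.08)
        qp = make_fit(40, -0.1, form="quad_plateau")
        assert select_model(quad, qp) is qp  # both sse 0

    def test_neither_significant_returns_flagged_quadratic(self):
        quad = FittedResponse("quadratic", 0, 0, 0, 1.0, 0.0, 1.0, False)
        qp = FittedResponse("quad_plateau", 0, 0, -1e-12, 1.0, 0.0, 1.0, False, 0.0)
        out = select_model(quad, qp)
        assert out.form == "quadratic" and not out.significant


class TestEonr:
    def test_closed_form_example(self):
        res = compute_eonr(make_fit(40, -0.08), price_ratio=5.6, n_max=268)
        assert res.eonr == pytest.approx((5.6 - 40) / (2 * -0.08))  # 215.0
        assert res.boundary_flag == "interior"
        assert res.yeonr == pytest.approx(make_fit(40, -0.08).predict(res.eonr))

    def test_negative_interior_clips_to_zero(self):
        res = compute_eonr(make_fit(0.0, -0.05))
        assert res.eonr == 0.0 and res.boundary_flag == "clipped_low"

    def test_nonsignificant_maps_to_zero(self):
        fit = FittedResponse("quadratic", 8000, 0, 0, 1.0, 0.0, 1.0, False)
        res = compute_eonr(fit)
        assert res.eonr == 0.0 and res.boundary_flag == "nonsignificant"

    def test_zero_curvature_contracts(self):
        steep = FittedResponse("quadratic", 5000, 20.0, 0.0, 0.0, 1.0, 0.0, True)
        assert compute_eonr(steep, n_max=268).boundary_flag == "clipped_high"
        shallow = FittedResponse("quadratic", 5000, 2.0, 0.0, 0.0, 1.0, 0.0, True)
        assert compute_eonr(shallow).eonr == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        b=st.floats(min_value=10.0, max_value=60.0),
        c=st.floats(min_value=-0.15, max_value=-0.02),
    )
    def test_closed_form_matches_profit_grid(self, b, c):
        fit = make_fit(b, c)
        res = compute_eonr(fit, 5.6, 268.0)
        grid = profit_grid_eonr(fit, 5.6, 268.0, step=0.01)
        assert abs(res.eonr - grid) <= 0.01

    def test_eonr_non_increasing_in_price_ratio(self):
        fit = make_fit(40, -0.08)
        ratios = [0.0, 2.8, 5.6, 11.2, 22.4]
        eonrs = [compute_eonr(fit, r).eonr for r in ratios]
        assert all(b <= a for a, b in zip(eonrs, eonrs[1:]))
        # and the grid oracle agrees that doubling the ratio lowers the optimum
        assert profit_grid_eonr(fit, 11.2) < profit_grid_eonr(fit, 5.6)


class TestEonrFromData:
    def test_known_quadratic_end_to_end(self):
        # b, c chosen so the analytic EONR is 180: (5.6-b)/(2c) = 180
        c = -0.09
        b = 5.6 - 2 * c * 180
        data = NResponseData(RATES, quad_yields(6000, b, c))
        res, fit = eonr_from_data(data)
        assert res.eonr == pytest.approx(180.0, abs=1e-6)
        grid = profit_grid_eonr(fit, 5.6, 268.0, step=0.01)
        assert abs(res.eonr - grid) <= 0.01

    def test_flat_yields_zero_eonr(self):
        res, _ = eonr_from_data(NResponseData(RATES, np.full(5, 10000.0)))
        assert res.eonr == 0.0 and res.boundary_flag == "nonsignificant"

    def test_doubled_price_ratio_lowers_eonr(self):
        data = NResponseData(RATES, quad_yields(6000, 40, -0.08))
        lo, _ = eonr_from_data(data, price_ratio=5.6)
        hi, _ = eonr_from_data(data, price_ratio=11.2)
        assert hi.eonr < lo.eonr

    def test_yeonr_equals_curve_at_eonr(self, small_lib):
        # on simulated data too, not just synthetic algebra
        import copy

        from eonrcast import ManagementConfig, default_initial_soil, run_season

        yields = [
            run_season(
                small_lib[small_lib.years[6]],
                ManagementConfig(n_rate=float(r)),
                copy.deepcopy(default_initial_soil()),
            ).grain_yield
            for r in RATES
        ]
        res, fit = eonr_from_data(NResponseData(RATES, np.array(yields)))
        assert res.yeonr == pytest.approx(float(fit.predict(res.eonr)))
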