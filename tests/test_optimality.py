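"""Optimum-finding, grids, volcano curves and the k2-Km scaling law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzact import (
    AssayCondition,
    GridSpec,
    ThermoLandscape,
    activity,
    activity_grid,
    michaelis_constant,
    optimal_dG1_closed,
    optimize_numeric,
    rate_constants,
    scaling_relation,
    volcano_curve,
)


def _grid_scan_argmax(template, cond, lo=-60.0, hi=20.0, n=100_000):
    """Independent brute-force oracle: dense scan of the rate over dG1."""
    dg1 = np.linspace(lo, hi, n)
    from enzact.optimality import _rate_arrays

    v, _ = _rate_arrays(dg1, np.full_like(dg1, template.dGT), template, cond)
    return dg1[int(np.argmax(v))]


class TestClosedForm:
    @pytest.mark.parametrize("S", [0.1, 1.0, 10.0, 100.0])
    def test_apex_at_km_equal_s_for_symmetric_alphas(self, S, default_template):
        res = optimal_dG1_closed(S, default_template)
        assert res.Km_star == pytest.approx(S, rel=1e-12)
        assert res.method == "closed_form"

    @pytest.mark.parametrize("a2", [0.26, 0.5, 0.74])
    def test_general_complementary_alphas(self, a2):
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=1.0 - a2, alpha2=a2)
        res = optimal_dG1_closed(10.0, tpl)
        assert res.Km_star == pytest.approx(a2 / (1.0 - a2) * 10.0, rel=1e-12)

    def test_half_saturation_at_optimum(self, default_template):
        res = optimal_dG1_closed(0.1, default_template)
        opt = default_template.with_dG1(res.dG1_star)
        k2 = rate_constants(opt).k2
        assert res.v_star == pytest.approx(0.5 * k2 * 0.01, rel=1e-12)

    def test_rejects_non_complementary_alphas(self):
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=0.3, alpha2=0.3)
        with pytest.raises(ValueError, match="optimize_numeric"):
            optimal_dG1_closed(10.0, tpl)

    def test_is_a_local_maximum(self, default_template):
        res = optimal_dG1_closed(10.0, default_template)
        cond = AssayCondition(S=10.0, ET=0.01)
        v0 = activity(default_template.with_dG1(res.dG1_star), cond)
        for d in (-1e-3, 1e-3):
            assert activity(default_template.with_dG1(res.dG1_star + d), cond) < v0


class TestNumericOptimizer:
    @pytest.mark.parametrize("S", [0.1, 1.0, 10.0, 100.0])
    def test_matches_km_equal_s(self, S, default_template):
        res = optimize_numeric(default_template, AssayCondition(S=S, ET=0.01))
        assert abs(np.log10(res.Km_star / S)) < 1e-6
        assert not res.boundary

    def test_agrees_with_closed_form(self):
        for a2 in (0.3, 0.5, 0.74):
            tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=1.0 - a2, alpha2=a2)
            closed = optimal_dG1_closed(10.0, tpl)
            numeric = optimize_numeric(tpl, AssayCondition(S=10.0, ET=0.01))
            assert abs(closed.dG1_star - numeric.dG1_star) < 1e-6

    def test_general_alphas_against_grid_scan(self):
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=0.2, alpha2=0.2)
        cond = AssayCondition(S=10.0, ET=0.01)
        res = optimize_numeric(tpl, cond)
        oracle = _grid_scan_argmax(tpl, cond)
        assert abs(res.dG1_star - oracle) < (80.0 / 100_000) * 1.5

    def test_low_alpha_rule_within_order_of_magnitude(self):
        """With alpha1=alpha2=0.2 the Km=[S] rule stays within 10x of the
        true maximum activity."""
        from enzact import dG1_for_km

        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=0.2, alpha2=0.2)
        cond = AssayCondition(S=10.0, ET=0.01)
        res = optimize_numeric(tpl, cond)
        v_rule = activity(tpl.with_dG1(dG1_for_km(tpl, 10.0)), cond)
        assert v_rule <= res.v_star
        assert res.v_star / v_rule < 10.0

    @given(st.floats(0.1, 0.9), st.floats(-70, -10), st.floats(-1, 2))
    @settings(max_examples=25)
    def test_optimizer_matches_dense_scan(self, a, dgt, log_s):
        tpl = ThermoLandscape(dG1=0.0, dGT=dgt, alpha1=a, alpha2=a)
        cond = AssayCondition(S=10.0**log_s, ET=0.01)
        res = optimize_numeric(tpl, cond)
        oracle = _grid_scan_argmax(tpl, cond, lo=tpl.dGT - 60.0, hi=60.0, n=50_000)
        assert abs(res.dG1_star - oracle) < (120.0 + 60.0) / 50_000 * 2

    def test_boundary_flagged(self, default_template):
        cond = AssayCondition(S=10.0, ET=0.01)
        with pytest.warns(RuntimeWarning, match="bracket"):
            res = optimize_numeric(default_template, cond, bracket=(-60.0, -40.0))
        assert res.boundary


class TestActivityGrid:
    @pytest.mark.parametrize("S", [0.1, 1.0, 10.0, 100.0])
    def test_ridge_is_km_equal_s_contour(self, S, default_template):
        spec = GridSpec(n_dG1=200, n_dGT=50)
        g = activity_grid(spec, AssayCondition(S=S, ET=0.01), default_template)
        cell = np.diff(spec.dG1_values)[0]
        # one dG1 cell corresponds to a factor exp(cell/RT) in Km
        tol = cell / default_template.RT / np.log(10.0)
        interior = (g.ridge_dG1 > spec.dG1_range[0]) & (g.ridge_dG1 < spec.dG1_range[1])
        assert interior.all()
        assert np.all(np.abs(np.log10(g.ridge_Km / S)) <= tol)

    def test_grid_values_equal_pointwise_calls(self, default_template):
        spec = GridSpec(n_dG1=7, n_dGT=5)
        cond = AssayCondition(S=1.0, ET=0.01)
        g = activity_grid(spec, cond, default_template)
        for i, dgt in enumerate(spec.dGT_values):
            for j, dg1 in enumerate(spec.dG1_values):
                ls = ThermoLandscape(dG1=dg1, dGT=dgt)
                assert g.v[i, j] == pytest.approx(activity(ls, cond), rel=1e-12)

    def test_refinement_consistency(self, default_template):
        cond = AssayCondition(S=1.0, ET=0.01)
        coarse = activity_grid(GridSpec(n_dG1=100, n_dGT=20), cond, default_template)
        fine = activity_grid(GridSpec(n_dG1=200, n_dGT=20), cond, default_template)
        coarse_cell = np.diff(coarse.dG1_values)[0]
        assert np.all(np.abs(fine.ridge_dG1 - coarse.ridge_dG1) <= coarse_cell)

    def test_ridge_matches_numeric_optimizer(self, default_template):
        spec = GridSpec(n_dG1=400, n_dGT=5)
        cond = AssayCondition(S=10.0, ET=0.01)
        g = activity_grid(spec, cond, default_template)
        cell = np.diff(spec.dG1_values)[0]
        for i, dgt in enumerate(spec.dGT_values):
            tpl = ThermoLandscape(dG1=0.0, dGT=dgt)
            res = optimize_numeric(tpl, cond)
            assert abs(g.ridge_dG1[i] - res.dG1_star) <= cell

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(dG1_range=(0.0, 0.0))
        with pytest.raises(ValueError):
            GridSpec(n_dG1=1)


class TestVolcano:
    @pytest.mark.parametrize("S", [0.1, 100.0])
    def test_apex_at_substrate_concentration(self, S):
        sweep = np.linspace(-60.0, 20.0, 4001)
        c = volcano_curve(S, -40.0, sweep)
        assert c.single_peaked
        assert abs(np.log10(c.apex_Km / S)) < 0.02  # sweep resolution

    def test_apex_half_saturation(self):
        sweep = np.linspace(-60.0, 20.0, 8001)
        c = volcano_curve(10.0, -40.0, sweep)
        apex_ls = ThermoLandscape(dG1=float(c.dG1[c.apex_index]), dGT=-40.0)
        assert c.apex_v == pytest.approx(0.5 * rate_constants(apex_ls).k2 * 0.01, rel=1e-3)

    def test_apex_invariant_to_dGT_and_k0(self):
        sweep = np.linspace(-70.0, 20.0, 8001)
        apexes = []
        for dgt, k1_0, k2_0 in [(-20.0, 1.0, 1.0), (-40.0, 10.0, 1.0), (-60.0, 1.0, 0.1)]:
            tpl = ThermoLandscape(dG1=0.0, dGT=dgt, k1_0=k1_0, k2_0=k2_0)
            apexes.append(volcano_curve(1.0, dgt, sweep, template=tpl).apex_Km)
        assert np.ptp(apexes) / np.mean(apexes) < 0.01

    def test_sweep_missing_apex_flagged(self):
        with pytest.warns(RuntimeWarning, match="apex"):
            c = volcano_curve(10.0, -40.0, np.linspace(-60.0, -40.0, 100))
        assert not c.apex_contained
        assert len(c.v) == 100


class TestScaling:
    @pytest.mark.parametrize("a2", [0.5, 0.74])
    def test_slope_equals_alpha2(self, a2):
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=1.0 - a2, alpha2=a2)
        res = scaling_relation(tpl, np.linspace(-40.0, 10.0, 51))
        assert res.slope == pytest.approx(a2, abs=1e-9)
        assert res.r_squared > 0.999999
        assert res.K_values is None

    def test_intercept_closed_form(self):
        a2 = 0.5
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0)
        res = scaling_relation(tpl, np.linspace(-40.0, 10.0, 51))
        expected = -a2 * np.log10((1.0 + tpl.K) * tpl.gT) + np.log10(tpl.k2_0)
        assert res.intercept == pytest.approx(expected, abs=1e-9)

    def test_non_complementary_alphas_report_K_per_point(self):
        tpl = ThermoLandscape(dG1=0.0, dGT=-40.0, alpha1=0.3, alpha2=0.4)
        res = scaling_relation(tpl, np.linspace(-40.0, 10.0, 11))
        assert res.K_values is not None and len(res.K_values) == 11
        assert np.ptp(res.K_values) > 0

    def test_short_sweep_rejected(self, default_template):
        with pytest.raises(ValueError, match="at least 2"):
            scaling_relation(default_template, np.array([0.0]))


@given(st.floats(0.15, 0.85), st.floats(0.15, 0.85), st.floats(-60, -10))
@settings(max_examples=20)
def test_single_peak_along_any_sweep(a1, a2, dgt):
    """v vs log Km along dG1 has exactly one local maximum."""
    from enzact.optimality import _rate_arrays

    tpl = ThermoLandscape(dG1=0.0, dGT=dgt, alpha1=a1, alpha2=a2)
    dg1 = np.linspace(dgt - 40.0, 40.0, 2000)
    v, _ = _rate_arrays(dg1, np.full_like(dg1, dgt), tpl, AssayCondition(S=1.0, ET=0.01))
    dv = np.diff(v)
    dv = dv[dv != 0]
    assert int(np.sum(np.diff(np.sign(dv)) != 0)) <= 1
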