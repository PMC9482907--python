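import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from napsri import calibration as cal


class TestMakeAnchors:
    def test_average_of_two_anchor_pairs(self):
        # per homolog, the average policy takes the mean bracketing RT:
        # C4 at (4.00 + 4.20)/2 = 4.10
        anchors = cal.make_anchors(
            [(4, 4.00), (5, 6.00)], [(4, 4.20), (5, 6.20)], policy="average"
        )
        assert anchors.ris == (400.0, 500.0)
        assert anchors.rts == (4.10, 6.10)

    def test_before_policy_is_identity(self):
        anchors = cal.make_anchors([(4, 4.0), (5, 5.0)], policy="before")
        assert anchors.rts == (4.0, 5.0)

    def test_average_of_equal_sets_is_identity(self):
        pairs = [(4, 4.0), (5, 5.0)]
        anchors = cal.make_anchors(pairs, pairs, policy="average")
        assert anchors.rts == (4.0, 5.0)

    def test_average_requires_both_runs(self):
        with pytest.raises(ValueError, match="average"):
            cal.make_anchors([(4, 4.0), (5, 5.0)], None, policy="average")

    def test_mismatched_homolog_sets_listed(self):
        with pytest.raises(ValueError, match="6"):
            cal.make_anchors([(4, 4.0), (5, 5.0)], [(4, 4.1), (6, 6.0)], policy="average")

    def test_coelution_collapse_keeps_highest_homolog(self):
        rts = (0.840, 0.846, 0.851, 1.30, 2.10, 3.10)
        anchors = cal.make_anchors(list(zip(range(1, 7), rts)))
        collapsed = anchors.collapse_coelution()
        # C1-C3 (gaps < 0.01 min) merge into the single RI-300 anchor
        assert collapsed.ris[0] == 300.0
        assert collapsed.rts[0] == pytest.approx(0.851)
        assert len(collapsed.ris) == len(anchors.ris) - 2


class TestFitAndConvert:
    @pytest.mark.parametrize("method", cal.METHODS)
    def test_anchor_reproduction_exact(self, spread_anchors, method):
        model = cal.fit(spread_anchors, method=method)
        for ri, rt in zip(spread_anchors.ris, spread_anchors.rts):
            assert model.rt_to_ri(rt).ri == pytest.approx(ri, abs=1e-9)

    @pytest.mark.parametrize("method", cal.METHODS)
    def test_collinear_anchors_give_the_line(self, collinear_anchors, method):
        model = cal.fit(collinear_anchors, method=method)
        grid = np.linspace(*collinear_anchors.rt_range, 31)
        expected = np.interp(grid, collinear_anchors.rts, collinear_anchors.ris)
        got = np.array([model.rt_to_ri(rt).ri for rt in grid])
        assert np.allclose(got, expected, atol=1e-8)

    def test_linear_bracketing_formula(self, simple_anchors):
        model = cal.fit(simple_anchors, method="linear")
        assert model.rt_to_ri(5.0).ri == pytest.approx(450.0)
        assert model.rt_to_ri(4.0).ri == pytest.approx(400.0)
        # RI = 400 + 100 * (4.5 - 4.0) / (6.0 - 4.0)
        assert model.rt_to_ri(4.5).ri == pytest.approx(425.0)

    def test_linear_monotone_in_rt(self, spread_anchors):
        model = cal.fit(spread_anchors, method="linear")
        grid = np.linspace(*spread_anchors.rt_range, 101)
        ris = [model.rt_to_ri(rt).ri for rt in grid]
        assert np.all(np.diff(ris) > 0)

    def test_flags(self, simple_anchors):
        model = cal.fit(simple_anchors, method="linear")
        inside = model.rt_to_ri(5.0)
        assert not inside.extrapolated and not inside.below_usable
        outside = model.rt_to_ri(7.0)
        assert outside.extrapolated
        low = model.rt_to_ri(2.0)  # extrapolates below RI 300
        assert low.extrapolated and low.below_usable

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            cal.AnchorSet(ris=(400.0,), rts=(4.0,))

    def test_bad_method_rejected(self, simple_anchors):
        with pytest.raises(ValueError):
            cal.fit(simple_anchors, method="quadratic")

    def test_ri_rounding_for_reporting(self, simple_anchors):
        model = cal.fit(simple_anchors, method="linear")
        assert model.rt_to_ri(4.5).ri_rounded == 425
        assert model.rt_to_ri(4.51).ri_rounded == 426


class TestInverse:
    def test_linear_inverse_midpoint(self, simple_anchors):
        model = cal.fit(simple_anchors, method="linear")
        assert model.ri_to_rt(450.0) == pytest.approx(5.0)
        assert model.ri_to_rt(400.0) == pytest.approx(4.0)

    def test_out_of_range_rejected(self, simple_anchors):
        model = cal.fit(simple_anchors, method="linear")
        with pytest.raises(ValueError, match="range"):
            model.ri_to_rt(600.0)

    @pytest.mark.parametrize("method,tol", [("linear", 1e-6), ("cubic", 1e-4), ("akima", 1e-4)])
    def test_round_trip(self, spread_anchors, method, tol):
        model = cal.fit(spread_anchors, method=method)
        rng = np.random.default_rng(0)
        lo, hi = spread_anchors.rt_range
        for rt in rng.uniform(lo, hi, 25):
            ri = model.rt_to_ri(rt).ri
            assert model.ri_to_rt(ri) == pytest.approx(rt, abs=tol)

    def test_non_monotone_cubic_segment_reported(self, pileup_anchors):
        # the cubic spline overshoots past RI 400 in the post-pileup gap,
        # so some indices have multiple preimages
        model = cal.fit(pileup_anchors, method="cubic")
        grid = np.linspace(0.87, 1.30, 200)
        overshoot = max(model._eval(grid))
        assert overshoot > 400.0  # precondition: the overshoot exists
        with pytest.raises(ValueError, match="non-monotone|preimages"):
            model.ri_to_rt((overshoot + 400.0) / 2.0)


class TestAffineInvariance:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=50.0),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_linear_ri_invariant_under_rt_axis_transform(self, a, b, frac):
        """Transforming rt' = a*rt + b for anchors and analyte alike leaves
        the linear RI unchanged -- the core of cross-system normalization."""
        rts = (1.0, 1.4, 2.0, 2.9, 4.1, 5.5, 7.0, 8.6)
        ris = tuple(100.0 * n for n in range(4, 12))
        rt = rts[0] + frac * (rts[-1] - rts[0])
        model = cal.fit(cal.AnchorSet(ris, rts), method="linear")
        transformed = cal.AnchorSet(ris, tuple(a * t + b for t in rts))
        model_t = cal.fit(transformed, method="linear")
        ri0 = model.rt_to_ri(rt).ri
        ri1 = model_t.rt_to_ri(a * rt + b).ri
        assert ri1 == pytest.approx(ri0, rel=1e-9)


class TestCompareAndSerialize:
    def test_grid_at_anchors_equals_anchor_ris(self, spread_anchors):
        tab = cal.compare_methods(spread_anchors, spread_anchors.rts)
        for col in ("ri_linear", "ri_cubic", "ri_akima"):
            assert np.allclose(tab[col], spread_anchors.ris, atol=1e-8)

    def test_cubic_overshoots_more_than_akima_in_early_region(self, pileup_anchors):
        grid = np.linspace(0.84, 5.35, 500)
        tab = cal.compare_methods(pileup_anchors, grid)
        dev_cubic = (tab["ri_cubic"] - tab["ri_linear"]).abs().max()
        dev_akima = (tab["ri_akima"] - tab["ri_linear"]).abs().max()
        assert dev_cubic > dev_akima

    def test_json_round_trip(self, spread_anchors, tmp_path):
        model = cal.fit(spread_anchors, method="akima", usable_ri_min=300)
        path = tmp_path / "cal.json"
        model.to_json(path)
        loaded = cal.CalibrationModel.from_json(path)
        assert loaded.method == "akima"
        assert loaded.anchors == model.anchors
        payload = json.loads(path.read_text())
        assert payload["anchors"][0]["n"] == 4
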