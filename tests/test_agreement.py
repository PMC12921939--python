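"""Agreement statistics: censoring, Deming, Bland-Altman, contingency."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from perisim.agreement import (
    ContingencyCounts,
    bland_altman,
    build_pairs,
    censor_for_regression,
    contingency,
    deming_fit,
    diagnostic_metrics,
    full_report,
)
from perisim.grid import generate_10_2
from perisim.zest import MeasuredField


def tls_oracle(x, y):
    """Orthogonal-regression oracle: profile the perpendicular SSE over the
    slope (intercept solved in closed form per candidate slope)."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def sse(b):
        a = np.mean(y - b * x)
        return np.sum((y - a - b * x) ** 2) / (1 + b * b)

    best = None
    for lo, hi in [(-100, 100)]:
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    b = best.x
    return b, float(np.mean(y - b * x))


def _field(values, subject="s1", eye="OD", device="octopus900"):
    grid = generate_10_2(eye=eye)
    return MeasuredField(grid=grid, sensitivity_db=np.asarray(values, float),
                         n_presentations=np.ones(68, int), device=device,
                         subject_id=subject, eye=eye)


class TestCensoring:
    def test_strict_window(self):
        df = pd.DataFrame({"octopus_db": [5.0, 14.0, 14.1, 20.0, 29.9, 30.0,
                                          31.0]})
        kept = censor_for_regression(df)["octopus_db"].tolist()
        assert kept == [14.1, 20.0, 29.9]

    def test_all_outside_gives_empty(self):
        df = pd.DataFrame({"octopus_db": [5.0, 31.0]})
        assert len(censor_for_regression(df)) == 0

    def test_order_preserving(self):
        df = pd.DataFrame({"octopus_db": [25.0, 15.0, 28.0]})
        assert censor_for_regression(df)["octopus_db"].tolist() == [
            25.0, 15.0, 28.0]


class TestDeming:
    def test_noiseless_line_recovered(self):
        x = np.linspace(0, 10, 20)
        fit = deming_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_axis_swap_reciprocal_slope(self, rng):
        x = rng.normal(10, 3, 40)
        y = 0.8 * x + rng.normal(0, 1, 40)
        assert deming_fit(x, y).slope * deming_fit(y, x).slope == \
            pytest.approx(1.0, abs=1e-9)

    def test_matches_perpendicular_distance_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            x = rng.normal(20, 4, 20)
            y = 0.77 * x - 10 + rng.normal(0, 1.5, 20)
            fit = deming_fit(x, y)
            b, a = tls_oracle(x, y)
            assert fit.slope == pytest.approx(b, abs=1e-3)
            assert fit.intercept == pytest.approx(a, abs=1e-3)

    def test_matches_scipy_odr(self):
        # independent library route for orthogonal regression
        import scipy.odr as odr
        rng = np.random.default_rng(5)
        x = rng.normal(20, 4, 30)
        y = 0.9 * x - 5 + rng.normal(0, 1, 30)
        fit = deming_fit(x, y)
        data = odr.RealData(x, y, sx=1.0, sy=1.0)
        out = odr.ODR(data, odr.unilinear,
                      beta0=[fit.slope, fit.intercept]).run()
        assert fit.slope == pytest.approx(out.beta[0], abs=1e-4)
        assert fit.intercept == pytest.approx(out.beta[1], abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            deming_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            deming_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            deming_fit([1.0, 2.0, 3.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.arange(10.0)
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert ba.loa_high - ba.loa_low == 0.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        ba = bland_altman(x + 14.0, x)
        assert ba.mean_diff == pytest.approx(14.0)
        assert ba.sd_diff == 0.0

    def test_loa_width_identity(self, rng):
        x = rng.normal(20, 3, 50)
        y = x - rng.normal(14, 2, 50)
        ba = bland_altman(x, y)
        assert ba.loa_high - ba.loa_low == pytest.approx(
            2 * 1.96 * ba.sd_diff)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestContingency:
    def test_toy_set_matches_hand_enumeration(self):
        pairs = pd.DataFrame({
            "octopus_db":  [10.0, 25.0, 13.9, 14.0, 20.0,  5.0],
            "hmp_db_raw":  [0.0,   6.0,  2.0,  0.0,  0.0,  0.0],
        })
        c = contingency(pairs)
        # by hand: tp {10/0, 5/0}, tn {25/6}, fn {13.9/2}, fp {14/0, 20/0}
        assert (c.tp, c.tn, c.fn, c.fp) == (2, 1, 1, 2)
        assert c.total == 6

    def test_boundary_14_is_condition_negative(self):
        pairs = pd.DataFrame({"octopus_db": [14.0], "hmp_db_raw": [0.0]})
        c = contingency(pairs)
        assert c.fp == 1 and c.tp == 0

    def test_conservation(self, rng):
        n = 500
        pairs = pd.DataFrame({
            "octopus_db": rng.uniform(0, 33, n),
            "hmp_db_raw": np.round(rng.uniform(0, 2, n)) * rng.uniform(
                0, 16, n)})
        assert contingency(pairs).total == n


class TestDiagnosticMetrics:
    def test_published_style_counts(self):
        sens, spec = diagnostic_metrics(
            ContingencyCounts(tn=1001, fn=191, fp=55, tp=385))
        assert round(sens, 2) == 0.67
        assert round(spec, 2) == 0.95

    def test_perfect_test(self):
        assert diagnostic_metrics(
            ContingencyCounts(tn=10, fn=0, fp=0, tp=10)) == (1.0, 1.0)

    def test_undefined_signaled(self):
        with pytest.raises(ZeroDivisionError):
            diagnostic_metrics(ContingencyCounts(tn=5, fn=0, fp=1, tp=0))
        with pytest.raises(ZeroDivisionError):
            diagnostic_metrics(ContingencyCounts(tn=0, fn=3, fp=0, tp=5))


class TestFullReport:
    def _paired(self, rng):
        """Self-agreeing pair: HMP raw = clamp(octopus - 14, 0, 16)."""
        oct_fields, hmp_fields = [], []
        for i, eye in [(1, "OD"), (1, "OS"), (2, "OD"), (2, "OS")]:
            # stay below the HMP ceiling (octopus 30 dB) so the clamp
            # cannot distort the self-agreement identities
            ov = rng.uniform(0, 30, 68)
            hv = np.clip(ov - 14.0, 0.0, 16.0)
            oct_fields.append(_field(ov, f"s{i}", eye, "octopus900"))
            hmp_fields.append(_field(hv, f"s{i}", eye, "iowa_hmp"))
        return oct_fields, hmp_fields

    def test_self_agreement(self, rng):
        oct_fields, hmp_fields = self._paired(rng)
        rep = full_report(oct_fields, hmp_fields)
        assert rep.n_pairs == 4 * 68
        assert rep.deming.slope == pytest.approx(1.0, abs=1e-9)
        assert rep.deming.intercept == pytest.approx(-14.0, abs=1e-9)
        assert rep.bland_altman.mean_diff == pytest.approx(14.0, abs=1e-9)
        assert rep.diagnostic_sensitivity == 1.0
        assert rep.diagnostic_specificity == 1.0
        assert rep.counts.total == rep.n_pairs

    def test_pairs_table_schema_and_harmonization(self, rng):
        oct_fields, hmp_fields = self._paired(rng)
        pairs = build_pairs(oct_fields, hmp_fields)
        nz = pairs["hmp_db_raw"] > 0
        assert np.all(pairs.loc[nz, "hmp_db_equivalent"]
                      == pairs.loc[nz, "hmp_db_raw"] + 14)
        assert np.all(pairs.loc[~nz, "hmp_db_equivalent"] == 0.0)

    def test_regression_input_fully_censored(self, rng):
        oct_fields, hmp_fields = self._paired(rng)
        pairs = build_pairs(oct_fields, hmp_fields)
        reg = censor_for_regression(pairs)
        assert reg["octopus_db"].min() > 14.0
        assert reg["octopus_db"].max() < 30.0

    def test_unmatched_pairs_rejected(self, rng):
        oct_fields, hmp_fields = self._paired(rng)
        with pytest.raises(ValueError, match="unmatched"):
            full_report(oct_fields[:3], hmp_fields)
        with pytest.raises(ValueError):
            full_report([], [])

    def test_ba_drop_floored_option(self, rng):
        oct_fields, hmp_fields = self._paired(rng)
        rep_keep = full_report(oct_fields, hmp_fields)
        rep_drop = full_report(oct_fields, hmp_fields, ba_drop_floored=True)
        assert rep_drop.n_bland_altman <= rep_keep.n_bland_altman

    def test_report_serializes_to_json(self, rng, tmp_path):
        oct_fields, hmp_fields = self._paired(rng)
        rep = full_report(oct_fields, hmp_fields)
        p = tmp_path / "report.json"
        rep.to_json(p)
        import json
        data = json.loads(p.read_text())
        assert data["deming"]["n"] == rep.deming.n
        assert data["counts"]["tp"] == rep.counts.tp
        assert "diagnostic sensitivity" in rep.summary()
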