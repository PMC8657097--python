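import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from theradose import (
    CU64,
    LU177,
    MonoExpFit,
    NormalizedActivityPoint,
    extrapolate_nuclide,
    fit_monoexp,
    integrate_tiac,
    scale_factor,
    tiac_envelope,
    to_physical_units,
)
from theradose.kinetics import BRANCH_INFINITE, BRANCH_PHYSICAL_TAIL
from theradose.nuclides import Nuclide


def _points(times, values, sds=None, corrected=False, organ="o"):
    sds = sds if sds is not None else [0.0] * len(times)
    return [
        NormalizedActivityPoint(organ, t, v, s, decay_corrected=corrected)
        for t, v, s in zip(times, values, sds)
    ]


def tiac_quadrature(a0, lam_eff, lam_p, t_last):
    """Independent oracle: adaptive quadrature of the piecewise curve."""
    if lam_eff > lam_p:
        val, _ = quad(lambda t: a0 * math.exp(-lam_eff * t), 0, np.inf)
        return val
    head, _ = quad(lambda t: a0 * math.exp(-lam_eff * t), 0, t_last)
    a_last = a0 * math.exp(-lam_eff * t_last)
    tail, _ = quad(lambda t: a_last * math.exp(-lam_p * (t - t_last)), t_last, np.inf)
    return head + tail


class TestToPhysicalUnits:
    def test_reapplies_decay_and_clears_flag(self):
        pts = _points([4.3, 50.2], [0.16463, 0.12928], corrected=True)
        out = to_physical_units(pts, CU64)
        assert out[0].na_mean == pytest.approx(0.13020, rel=1e-3)
        assert out[1].na_mean == pytest.approx(0.0083489, rel=2e-3)
        assert not any(p.decay_corrected for p in out)

    def test_time_zero_unchanged(self):
        pts = _points([0.0], [0.3], corrected=True)
        assert to_physical_units(pts, CU64)[0].na_mean == 0.3

    def test_already_uncorrected_warns_and_noop(self):
        pts = _points([4.3], [0.1], corrected=False)
        with pytest.warns(UserWarning, match="uncorrected"):
            out = to_physical_units(pts, CU64)
        assert out[0].na_mean == 0.1


class TestFitMonoexp:
    def test_noiseless_recovery(self):
        t = [4.3, 26.0, 50.2]
        y = [0.2 * math.exp(-0.05 * x) for x in t]
        fit = fit_monoexp(_points(t, y))
        assert fit.a0 == pytest.approx(0.2, rel=1e-10)
        assert fit.lambda_eff == pytest.approx(0.05, rel=1e-10)

    def test_two_points_exact_interpolation(self):
        fit = fit_monoexp(_points([1.0, 2.0], [0.5, 0.25]))
        assert fit.lambda_eff == pytest.approx(math.log(2), rel=1e-12)
        assert fit.a0 == pytest.approx(1.0, rel=1e-12)

    def test_liver_series(self, liver_uncorrected):
        fit = fit_monoexp(liver_uncorrected)
        assert fit.lambda_eff == pytest.approx(0.0598, abs=2e-4)
        assert fit.a0 == pytest.approx(0.161, abs=1e-3)

    def test_linear_scale_agrees_on_exact_data(self):
        t = [4.3, 26.0, 50.2]
        y = [0.2 * math.exp(-0.05 * x) for x in t]
        fit = fit_monoexp(_points(t, y), scale="linear")
        assert fit.lambda_eff == pytest.approx(0.05, rel=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_monoexp(_points([1.0, 1.0], [0.5, 0.4]))
        with pytest.raises(ValueError, match="positive"):
            fit_monoexp(_points([1.0, 2.0], [0.5, 0.0]))
        with pytest.raises(ValueError, match="uncorrected"):
            fit_monoexp(_points([1.0, 2.0], [0.5, 0.25], corrected=True))


class TestIntegrateTiac:
    def test_fast_clearance_integrates_to_infinity(self):
        tiac, branch = integrate_tiac(MonoExpFit("o", 1.0, 0.1), CU64, 50.2)
        assert tiac == pytest.approx(10.0, rel=1e-12)
        assert branch == BRANCH_INFINITE

    def test_slow_clearance_truncated_with_physical_tail(self):
        nuc = Nuclide("Cu-64", 12.7, 0.121)
        tiac, branch = integrate_tiac(MonoExpFit("o", 1.0, 0.01), nuc, 50.2)
        assert branch == BRANCH_PHYSICAL_TAIL
        assert tiac == pytest.approx(50.56, abs=0.01)
        assert tiac == pytest.approx(tiac_quadrature(1.0, 0.01, nuc.lambda_p, 50.2),
                                     rel=1e-8)

    def test_zero_lambda_eff_limit(self):
        tiac, _ = integrate_tiac(MonoExpFit("o", 2.0, 0.0), CU64, 50.2)
        expected = 2.0 * 50.2 + 2.0 / CU64.lambda_p
        assert tiac == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=150)
    @given(
        a0=st.floats(1e-3, 1.0),
        lam_eff=st.floats(-0.05, 0.5),
        half_life=st.floats(2.0, 200.0),
        t_last=st.floats(10.0, 100.0),
    )
    def test_matches_quadrature_oracle(self, a0, lam_eff, half_life, t_last):
        nuc = Nuclide("X", half_life, 0.1)
        tiac, _ = integrate_tiac(MonoExpFit("o", a0, lam_eff), nuc, t_last)
        assert tiac == pytest.approx(
            tiac_quadrature(a0, lam_eff, nuc.lambda_p, t_last), rel=1e-6
        )

    def test_continuous_at_branch_point(self):
        lam_p = CU64.lambda_p
        eps = 1e-9
        above, _ = integrate_tiac(MonoExpFit("o", 1.0, lam_p + eps), CU64, 50.2)
        below, _ = integrate_tiac(MonoExpFit("o", 1.0, lam_p - eps), CU64, 50.2)
        assert above == pytest.approx(1.0 / lam_p, rel=1e-6)
        assert below == pytest.approx(1.0 / lam_p, rel=1e-6)
        assert above == pytest.approx(below, rel=1e-6)

    def test_strictly_decreasing_in_lambda_eff(self):
        lams = np.linspace(-0.02, 0.3, 40)
        tiacs = [integrate_tiac(MonoExpFit("o", 1.0, l), CU64, 50.2)[0] for l in lams]
        assert all(a > b for a, b in zip(tiacs, tiacs[1:]))


class TestTiacEnvelope:
    def test_zero_sd_collapses_envelope(self):
        t = [4.3, 26.0, 50.2]
        y = [0.2 * math.exp(-0.08 * x) for x in t]
        res = tiac_envelope(_points(t, y), CU64)
        assert res.tiac_low == res.tiac_mean == res.tiac_high

    def test_known_analytic_envelope(self):
        # mean and +/- SD series are themselves exact monoexponentials
        t = np.array([4.3, 26.0, 50.2])
        mk = lambda a0: a0 * np.exp(-0.09 * t)
        sds = mk(0.25) - mk(0.2)
        res = tiac_envelope(_points(t, mk(0.2), sds), CU64)
        assert res.tiac_mean == pytest.approx(0.2 / 0.09, rel=1e-9)
        assert res.tiac_low == pytest.approx(0.15 / 0.09, rel=1e-9)
        assert res.tiac_high == pytest.approx(0.25 / 0.09, rel=1e-9)

    def test_liver_envelope_ordered(self, liver_uncorrected):
        res = tiac_envelope(liver_uncorrected, CU64)
        assert res.tiac_low < res.tiac_mean < res.tiac_high
        assert res.tiac_mean == pytest.approx(2.687, abs=0.01)

    def test_nonpositive_lower_series_degrades_gracefully(self):
        pts = _points([4.3, 26.0], [0.1, 0.05], sds=[0.2, 0.01])
        with pytest.warns(UserWarning, match="envelope bound unavailable"):
            res = tiac_envelope(pts, CU64)
        assert math.isnan(res.tiac_low)
        assert math.isfinite(res.tiac_mean)


class TestExtrapolateNuclide:
    def test_identity_when_same_nuclide(self):
        pts = _points([4.3, 26.0], [0.1, 0.05])
        curve = extrapolate_nuclide(pts, CU64, CU64)
        assert curve.sf_values == (1.0, 1.0)
        assert [p.na_mean for p in curve.points] == [0.1, 0.05]

    def test_scale_factor_value(self):
        assert scale_factor(4.3, CU64, LU177) == pytest.approx(1.2411, abs=2e-4)
        assert scale_factor(0.0, CU64, LU177) == 1.0

    def test_sf_above_one_for_longer_lived_destination(self):
        for t in (1.0, 26.0, 50.2):
            assert scale_factor(t, CU64, LU177) > 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        amplitudes=st.lists(st.floats(1e-4, 0.5), min_size=2, max_size=5),
    )
    def test_round_trip_is_identity(self, amplitudes):
        # physically plausible uncorrected data: amplitude times Cu-64 decay
        times = [4.3 + 10 * i for i in range(len(amplitudes))]
        values = [a * CU64.decay_factor(t) for a, t in zip(amplitudes, times)]
        pts = _points(times, values)
        there = extrapolate_nuclide(pts, CU64, LU177)
        back = extrapolate_nuclide(list(there.points), LU177, CU64)
        for orig, rt in zip(pts, back.points):
            assert rt.na_mean == pytest.approx(orig.na_mean, rel=1e-12)

    def test_rejects_decay_corrected_input(self):
        pts = _points([4.3, 26.0], [0.1, 0.05], corrected=True)
        with pytest.raises(ValueError, match="uncorrected"):
            extrapolate_nuclide(pts, CU64, LU177)

    def test_liver_extrapolated_tiac(self, liver_uncorrected):
        curve = extrapolate_nuclide(liver_uncorrected, CU64, LU177)
        res = tiac_envelope(list(curve.points), LU177)
        assert res.tiac_mean == pytest.approx(16.89, abs=0.01)
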