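"""Forward-model unit tests: exponential-Lorentzian evaluation, the
exchange-parameter mapping and unit plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xecest.zspec_model import (
    AcquisitionParams,
    ExchangeParams,
    Resonance,
    ZSpecModelParams,
    cest_amplitude,
    cest_width,
    evaluate_zspectrum,
    evaluate_zspectrum_linearized,
    hz_to_ppm,
    koff_from_linewidth,
    ppm_to_hz,
    width_high_power_limit,
)

F_OBS = 83.0e6


def single(b=77.9, B=2.206, w=497.0):
    return ZSpecModelParams(A=1.0, resonances=(Resonance.from_width_hz(b, B, w),))


class TestTypes:
    def test_width_roundtrip_is_lossless(self):
        r = Resonance.from_width_hz(77.5, 2.3, 573.0)
        assert r.width_hz == pytest.approx(573.0, abs=0.0)
        assert r.a == pytest.approx(573.0 * math.pi)

    @pytest.mark.parametrize("kwargs", [dict(b_ppm=77.5, B=-0.1, a=100.0),
                                        dict(b_ppm=77.5, B=1.0, a=0.0),
                                        dict(b_ppm=math.nan, B=1.0, a=100.0)])
    def test_invalid_resonance_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Resonance(**kwargs)

    def test_degenerate_positions_rejected(self):
        pair = (Resonance(77.5, 1.0, 100.0), Resonance(77.5, 0.5, 200.0))
        with pytest.raises(ValueError, match="degenerate"):
            ZSpecModelParams(A=1.0, resonances=pair)

    def test_resonances_sorted_downfield_first(self):
        p = ZSpecModelParams(
            A=1.0,
            resonances=(Resonance(58.8, 0.1, 100.0), Resonance(103.3, 0.1, 100.0)),
        )
        assert [r.b_ppm for r in p.resonances] == [103.3, 58.8]

    def test_acquisition_grid_has_91_points(self):
        grid = AcquisitionParams().offsets_hz()
        assert grid.size == 91
        assert grid[0] == -13000.0 and grid[-1] == 5000.0


class TestEvaluate:
    def test_empty_resonance_list_gives_baseline(self):
        p = ZSpecModelParams(A=1.7)
        assert np.allclose(evaluate_zspectrum(p, [0.0, 50.0, 200.0]), 1.7)

    def test_on_resonance_value_is_A_exp_minus_B(self):
        p = single()
        assert evaluate_zspectrum(p, [77.9], F_OBS)[0] == pytest.approx(math.exp(-2.206))

    def test_apo_preset_matches_hand_arithmetic(self, presets):
        # frozen from independent per-term exponent arithmetic (math
        # module only, separate from the vectorized implementation)
        val = evaluate_zspectrum(presets["apo"].params, [77.5], F_OBS)[0]
        assert val == pytest.approx(0.09682725807777032, rel=1e-12)

    def test_baseline_recovered_far_off_resonance(self, presets):
        # 1e4 half-widths away from every resonance
        val = evaluate_zspectrum(presets["apo"].params, [1e6], F_OBS)
        assert abs(val[0] - 1.0) < 1e-6

    def test_permutation_invariance(self, presets, rng):
        res = list(presets["apo"].params.resonances)
        x = np.linspace(40, 250, 50)
        ref = evaluate_zspectrum(presets["apo"].params, x, F_OBS)
        rng.shuffle(res)
        shuffled = ZSpecModelParams(A=1.0, resonances=tuple(res))
        assert np.array_equal(evaluate_zspectrum(shuffled, x, F_OBS), ref)

    def test_nonfinite_offsets_rejected(self):
        with pytest.raises(ValueError):
            evaluate_zspectrum(single(), [math.inf])

    @settings(deadline=None, max_examples=50)
    @given(
        b=st.floats(40, 250),
        B=st.floats(0, 5),
        w=st.floats(10, 5000),
        x=st.floats(-500, 500),
        A=st.floats(0.1, 10),
    )
    def test_bounds_property(self, b, B, w, x, A):
        """0 < S(x) <= A for any valid parameters and finite offset."""
        p = ZSpecModelParams(A=A, resonances=(Resonance.from_width_hz(b, B, w),))
        s = evaluate_zspectrum(p, [x], F_OBS)[0]
        assert 0 < s <= A


class TestLinearized:
    def test_all_zero_amplitudes_give_baseline(self):
        res = tuple(Resonance.from_width_hz(b, 0.0, 300.0) for b in (100.0, 80.0, 60.0))
        p = ZSpecModelParams(A=1.3, resonances=res)
        assert np.allclose(evaluate_zspectrum_linearized(p, [60.0, 90.0], F_OBS), 1.3)

    def test_single_strong_resonance_equals_exact(self):
        p = single()
        x = np.linspace(40, 250, 91)
        exact = evaluate_zspectrum(p, x, F_OBS)
        assert np.allclose(evaluate_zspectrum_linearized(p, x, F_OBS), exact, rtol=0, atol=1e-15)

    def test_apo_taylor_remainder_bound(self, presets, acq):
        """|linearized - exact|/A stays below the quadratic Taylor bound
        2 * max of the non-dominant B^2."""
        p = presets["apo"].params
        x = acq.offsets_ppm()
        weak_max = sorted(r.B for r in p.resonances)[-2]
        dev = np.max(np.abs(
            evaluate_zspectrum_linearized(p, x, F_OBS) - evaluate_zspectrum(p, x, F_OBS)
        ))
        assert dev < 2.0 * weak_max**2

    def test_deviation_shrinks_quadratically(self, presets, acq):
        x = acq.offsets_ppm()
        devs = []
        for scale in (1.0, 0.5, 0.25):
            res = tuple(
                r if r.B > 1 else Resonance(r.b_ppm, r.B * scale, r.a)
                for r in presets["apo"].params.resonances
            )
            p = ZSpecModelParams(A=1.0, resonances=res)
            devs.append(np.max(np.abs(
                evaluate_zspectrum_linearized(p, x, F_OBS) - evaluate_zspectrum(p, x, F_OBS)
            )))
        # quadratic: halving the weak amplitudes quarters the error
        assert devs[1] < 0.3 * devs[0]
        assert devs[2] < 0.3 * devs[1]

    def test_warns_on_large_weak_amplitude(self):
        res = (Resonance.from_width_hz(90.0, 2.0, 300.0),
               Resonance.from_width_hz(60.0, 1.5, 300.0))
        p = ZSpecModelParams(A=1.0, resonances=res)
        with pytest.warns(UserWarning, match="non-strong"):
            evaluate_zspectrum_linearized(p, [75.0], F_OBS)


class TestExchangeMapping:
    acq = AcquisitionParams()

    def test_no_rf_no_saturation(self):
        acq0 = AcquisitionParams(omega1=0.0)
        assert cest_amplitude(ExchangeParams(1.0, 320.0, 0.0), acq0) == 0.0

    def test_no_exchange_no_amplitude(self):
        assert cest_amplitude(ExchangeParams(0.0, 320.0, 10.0), self.acq) == 0.0

    def test_amplitude_hand_arithmetic(self):
        # frozen: 20 * (2*pi*99)^2 / ((2*pi*99)^2 + 320^2)
        B = cest_amplitude(ExchangeParams(1.0, 320.0, 0.0), self.acq)
        assert B == pytest.approx(15.814668031209207, rel=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(t=st.floats(0.1, 50), kon=st.floats(0, 100), c=st.floats(0.1, 10))
    def test_amplitude_linear_in_t_and_kon(self, t, kon, c):
        ex = ExchangeParams(kon, 320.0, 50.0)
        a1 = AcquisitionParams(t_sat=t)
        a2 = AcquisitionParams(t_sat=c * t)
        assert cest_amplitude(ex, a2) == pytest.approx(c * cest_amplitude(ex, a1))
        exc = ExchangeParams(c * kon, 320.0, 50.0)
        assert cest_amplitude(exc, a1) == pytest.approx(c * cest_amplitude(ex, a1))

    def test_width_collapses_to_omega1(self):
        a = cest_width(ExchangeParams(1.0, 0.0, 0.0), self.acq)
        assert a == self.acq.omega1

    def test_width_high_power_agreement(self):
        """With R2 >> k_off << omega1 the full and simplified widths
        agree to better than 1%."""
        ex = ExchangeParams(1.0, 50.0, 1800.0)
        full = cest_width(ex, self.acq)
        lim = width_high_power_limit(ex, self.acq)
        assert abs(full - lim) / full < 0.01

    def test_width_monotone_in_r2_and_omega1(self):
        """Doubling R2 (or omega1) never decreases the width, scanned
        over a parameter lattice."""
        for koff in (10.0, 100.0, 500.0):
            for r2 in (0.0, 50.0, 1000.0):
                for w1 in (100.0, 622.0, 3000.0):
                    acq = AcquisitionParams(omega1=w1)
                    a0 = cest_width(ExchangeParams(1.0, koff, r2), acq)
                    assert cest_width(ExchangeParams(1.0, koff, 2 * r2), acq) >= a0
                    acq2 = AcquisitionParams(omega1=2 * w1)
                    assert cest_width(ExchangeParams(1.0, koff, r2), acq2) >= a0

    def test_width_errors(self):
        with pytest.raises(ValueError):
            cest_width(ExchangeParams(0.0, 0.0, 0.0), AcquisitionParams(omega1=0.0))
        with pytest.raises(ValueError):
            cest_width(ExchangeParams(1.0, 0.0, 100.0), self.acq)

    def test_high_power_limit_trivial_and_warning(self):
        assert width_high_power_limit(ExchangeParams(1.0, 0.0, 0.0), self.acq) == self.acq.omega1
        with pytest.warns(UserWarning, match="comparable"):
            width_high_power_limit(ExchangeParams(1.0, 600.0, 100.0), self.acq)


class TestUnits:
    def test_zero_maps_to_zero(self):
        assert ppm_to_hz(0.0, F_OBS) == 0.0

    def test_definition_and_roundtrip(self):
        assert ppm_to_hz(1.0, F_OBS) == pytest.approx(83.0)
        x = np.linspace(-200, 300, 17)
        assert np.allclose(hz_to_ppm(ppm_to_hz(x, F_OBS), F_OBS), x, rtol=1e-15)

    @pytest.mark.parametrize(
        "fwhm,conv,expected",
        [(320.0, "numeric", 320.0), (24.0, "numeric", 24.0),
         (320.0, "lorentzian", math.pi * 320.0)],
    )
    def test_koff_conventions(self, fwhm, conv, expected):
        assert koff_from_linewidth(fwhm, conv) == pytest.approx(expected)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            koff_from_linewidth(320.0, "radians")
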