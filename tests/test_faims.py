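import numpy as np
import pytest

from imsmetry import (
    AlphaFunction,
    AsymmetricWaveform,
    FaimsCurve,
    FaimsGap,
    GasState,
    classify_ion_type,
    extract_alpha,
    fields_from_voltages,
    forward_curve,
    forward_ec,
    operating_mode,
    reconstruct_absolute_k,
    residence_time,
    waveform_moments,
)
from imsmetry.errors import (
    ClassificationError,
    DomainError,
    ExtractionError,
    WaveformError,
)


class TestFieldsFromVoltages:
    def test_zero_cv(self):
        gap = FaimsGap(width=2e-3)
        (ed, ec), _ = fields_from_voltages(4000.0, 0.0, gap)
        assert ec == 0.0

    def test_dispersion_field_arithmetic(self):
        # DV = 4 kV over g = 2 mm -> E_D = 20 kV/cm = 2e6 V/m
        gap = FaimsGap(width=2e-3)
        (ed, ec), _ = fields_from_voltages(4000.0, -12.0, gap)
        assert ed == pytest.approx(2e6, rel=1e-12)
        assert ec == pytest.approx(-6000.0, rel=1e-12)

    def test_halving_gap_doubles_fields(self):
        a, _ = fields_from_voltages(4000.0, 10.0, FaimsGap(width=2e-3))
        b, _ = fields_from_voltages(4000.0, 10.0, FaimsGap(width=1e-3))
        assert b[0] == pytest.approx(2 * a[0]) and b[1] == pytest.approx(2 * a[1])

    def test_townsend_normalization(self):
        gap = FaimsGap(width=2e-3)
        gas = GasState.pure("N2", temperature=298.0, pressure=101325.0)
        _, (ed_td, ec_td) = fields_from_voltages(4000.0, 0.0, gap, gas=gas)
        n = gas.number_density()
        assert ed_td == pytest.approx((2e6 / n) / 1e-21, rel=1e-12)


class TestWaveform:
    def test_symmetric_square_wave_has_zero_odd_moments(self):
        wf = AsymmetricWaveform(lambda p: np.where(np.mod(p, 1.0) < 0.5, 1.0, -1.0))
        m = wf.moments(7)
        for n in (1, 3, 5, 7):
            assert abs(m[n]) < 1e-9

    def test_bisinusoidal_moments_match_analytic_harmonics(self, bisinusoidal):
        # closed forms for f = (2 sin(th) - cos(2th))/3:
        # <F2> = (a1^2 + a2^2)/2 = 5/18, <F3> = 3 a1^2 a2 / 4 = 1/9
        m = waveform_moments(bisinusoidal, 3)
        assert m[2] == pytest.approx(5.0 / 18.0, abs=1e-8)
        assert m[3] == pytest.approx(1.0 / 9.0, abs=1e-8)

    def test_rectangular_moments_match_closed_form(self):
        wf = AsymmetricWaveform.rectangular(high_low_ratio=2.0)
        quad = wf.moments(5)
        analytic = wf.analytic_moments(5)
        # midpoint sampling of a discontinuous profile: O(1/N) agreement
        for n in range(2, 6):
            assert quad[n] == pytest.approx(analytic[n], abs=5e-4)

    def test_zero_profile_rejected(self):
        with pytest.raises(WaveformError):
            AsymmetricWaveform(lambda p: np.zeros_like(p))

    def test_net_area_waveform_rejected(self):
        with pytest.raises(WaveformError):
            AsymmetricWaveform(lambda p: np.ones_like(p) * 0.5 + np.sin(2 * np.pi * p))

    def test_sampled_profile_round_trip(self, bisinusoidal):
        phase = np.linspace(0, 1, 2049)
        f = np.interp(np.mod(phase, 1.0), (np.arange(4096) + 0.5) / 4096,
                      bisinusoidal.samples, period=1.0)
        wf = AsymmetricWaveform.from_samples(phase, f)
        m1 = waveform_moments(bisinusoidal, 3)
        m2 = waveform_moments(wf, 3)
        assert m2[2] == pytest.approx(m1[2], abs=1e-4)

    def test_sampled_profile_must_cover_period(self):
        with pytest.raises(WaveformError):
            AsymmetricWaveform.from_samples(np.linspace(0, 0.5, 100),
                                            np.sin(np.linspace(0, np.pi, 100)))


class TestForwardEc:
    def test_alpha_unity_gives_zero_compensation(self, bisinusoidal):
        alpha = AlphaFunction(coefficients=())
        assert forward_ec(alpha, bisinusoidal, 80.0) == pytest.approx(0.0, abs=1e-12)

    def test_sign_of_a2_flips_sign_of_ec(self, bisinusoidal):
        # K increasing with E/N (a2 > 0) transmits at negative E_C under the
        # unified convention, and vice versa
        up = forward_ec(AlphaFunction((1e-5,)), bisinusoidal, 60.0)
        dn = forward_ec(AlphaFunction((-1e-5,)), bisinusoidal, 60.0)
        assert up < 0 < dn
        # antisymmetry is exact only in the small-field limit, where the
        # E_C-dependent terms of the transmission condition are negligible
        up_small = forward_ec(AlphaFunction((1e-5,)), bisinusoidal, 10.0)
        dn_small = forward_ec(AlphaFunction((-1e-5,)), bisinusoidal, 10.0)
        assert up_small == pytest.approx(-dn_small, rel=5e-3)

    def test_matches_brute_force_root_scan(self, bisinusoidal):
        """Oracle: dense scan of the net-drift function for the sign change."""
        alpha = AlphaFunction((1e-5,))
        ed = 80.0
        samples = bisinusoidal.samples

        def drift(ec):
            e = ed * samples + ec
            return np.mean((1.0 + 1e-5 * e**2) * e)

        grid = np.linspace(-5.0, 5.0, 200_001)
        vals = np.array([drift(g) for g in grid[::100]])  # coarse bracket
        idx = np.nonzero(np.diff(np.sign(vals)))[0][0]
        fine = np.linspace(grid[::100][idx], grid[::100][idx + 1], 20_001)
        fvals = np.array([drift(g) for g in fine])
        j = np.nonzero(np.diff(np.sign(fvals)))[0][0]
        oracle = 0.5 * (fine[j] + fine[j + 1])
        assert forward_ec(alpha, bisinusoidal, ed) == pytest.approx(oracle, abs=1e-4)

    def test_single_sign_across_dispersion_range(self, bisinusoidal):
        """An a2-only alpha of one sign yields E_C of one sign at every E_D."""
        curve = forward_curve(AlphaFunction((-2e-6,)), bisinusoidal,
                              np.linspace(10, 150, 12))
        assert np.all(curve.e_c > 0)


class TestExtractAlpha:
    def test_generative_round_trip(self, bisinusoidal):
        truth = (-2e-6, 1.2e-11)
        curve = forward_curve(AlphaFunction(truth), bisinusoidal,
                              np.linspace(20, 120, 8))
        alpha = extract_alpha(curve, bisinusoidal, order=4)
        for got, want in zip(alpha.coefficients, truth):
            assert got == pytest.approx(want, rel=1e-3)

    def test_flat_curve_gives_null_coefficients(self, bisinusoidal):
        curve = FaimsCurve(e_d=np.linspace(20, 120, 6), e_c=np.zeros(6),
                           normalized=True)
        alpha = extract_alpha(curve, bisinusoidal, order=4)
        assert np.allclose(alpha.coefficients, 0.0, atol=1e-12)

    def test_underdetermined_rejected(self, bisinusoidal):
        curve = FaimsCurve(e_d=[50.0, 60.0], e_c=[0.1, 0.2], normalized=True)
        with pytest.raises(ExtractionError):
            extract_alpha(curve, bisinusoidal, order=6)

    def test_noisy_recovery_within_bootstrap_interval(self, bisinusoidal):
        from imsmetry.synthetic import make_faims_curve
        truth = (-2e-6, 1.2e-11)
        curve, _ = make_faims_curve(truth, bisinusoidal, np.linspace(20, 120, 12),
                                    seed=5, noise_rel=0.01)
        alpha = extract_alpha(curve, bisinusoidal, order=4)
        # bootstrap the curve points to get a CI for a2
        rng = np.random.default_rng(6)
        boots = []
        for _ in range(200):
            idx = rng.integers(0, len(curve.e_d), len(curve.e_d))
            if len(np.unique(idx)) < 3:
                continue
            sub = FaimsCurve(e_d=curve.e_d[idx], e_c=curve.e_c[idx], normalized=True)
            try:
                boots.append(extract_alpha(sub, bisinusoidal, order=4).coefficients[0])
            except ExtractionError:
                continue
        lo, hi = np.percentile(boots, [0.5, 99.5])
        assert lo <= truth[0] <= hi


class TestClassification:
    ED = np.linspace(20, 120, 8)

    def test_type_c_positive_increasing(self):
        curve = FaimsCurve(e_d=self.ED, e_c=np.linspace(0.1, 2.0, 8), normalized=True)
        letter, desc = classify_ion_type(curve)
        assert letter == "C"
        assert "in N2" in desc and "120" in desc

    def test_type_a_negative_increasing_magnitude(self):
        curve = FaimsCurve(e_d=self.ED, e_c=-np.linspace(0.1, 2.0, 8), normalized=True)
        assert classify_ion_type(curve)[0] == "A"

    def test_type_b_reversal_on_negative_branch(self):
        ec = -np.array([0.1, 0.5, 1.0, 1.4, 1.5, 1.3, 1.0, 0.6])
        curve = FaimsCurve(e_d=self.ED, e_c=ec, normalized=True)
        assert classify_ion_type(curve)[0] == "B"

    def test_type_d_positive_maximum_then_decrease(self):
        ec = np.array([0.1, 0.5, 1.0, 1.4, 1.5, 1.3, 1.0, 0.6])
        curve = FaimsCurve(e_d=self.ED, e_c=ec, normalized=True)
        assert classify_ion_type(curve)[0] == "D"

    def test_type_e_crosses_to_negative(self):
        ec = np.array([0.1, 0.5, 0.8, 0.9, 0.5, -0.5, -2.0, -4.0])
        curve = FaimsCurve(e_d=self.ED, e_c=ec, normalized=True)
        assert classify_ion_type(curve)[0] == "E"

    def test_unsorted_input_warns(self):
        curve = FaimsCurve(e_d=self.ED[::-1], e_c=np.linspace(2.0, 0.1, 8),
                           normalized=True)
        with pytest.warns(UserWarning, match="sorted"):
            assert classify_ion_type(curve)[0] == "C"

    def test_too_few_points(self):
        curve = FaimsCurve(e_d=[10.0, 20.0], e_c=[0.1, 0.2], normalized=True)
        with pytest.raises(ClassificationError):
            classify_ion_type(curve)

    def test_generated_negative_a2_gives_positive_branch_type(self, bisinusoidal):
        curve = forward_curve(AlphaFunction((-2e-6,)), bisinusoidal,
                              np.linspace(20, 120, 8))
        assert classify_ion_type(curve)[0] == "C"


class TestOperatingModes:
    @pytest.mark.parametrize("polarity, deriv, mode", [
        ("+", +1, "P1"), ("+", -1, "P2"), ("-", +1, "N1"), ("-", -1, "N2")])
    def test_modes(self, polarity, deriv, mode):
        assert operating_mode(polarity, deriv) == mode


class TestResidenceTime:
    def test_flow_scaling_and_upper_limit_tag(self):
        gap = FaimsGap(width=5e-4, length=0.02, span=0.01)
        q = 1e-3 / 60.0  # 1 L/min in m^3/s
        t1 = residence_time(gap, q)
        t2 = residence_time(gap, 2 * q)
        assert t1.value == pytest.approx(2 * t2.value, rel=1e-12)
        assert t1.upper_limit
        # oracle: g L s / Q = 0.5mm * 2cm * 1cm / (1 L/min)
        assert t1.value == pytest.approx(5e-4 * 0.02 * 0.01 / q, rel=1e-12)

    def test_zero_flow_rejected(self):
        with pytest.raises(DomainError):
            residence_time(FaimsGap(width=5e-4, length=0.02, span=0.01), 0.0)


class TestAbsoluteReconstruction:
    def test_alpha_unity_constant(self):
        alpha = AlphaFunction((), k0=1.8, u_k0_rel=0.01, k0_source="drift tube")
        k = reconstruct_absolute_k(alpha)
        val, u = k(0.0)
        assert val == pytest.approx(1.8) and u == 0.01
        assert "drift tube" in k.k0_source

    def test_polynomial_arithmetic(self):
        alpha = AlphaFunction((1e-5,), k0=2.0)
        val, _ = reconstruct_absolute_k(alpha)(100.0)
        assert val == pytest.approx(2.0 * (1 + 1e-5 * 1e4), rel=1e-12)

    def test_missing_k0_rejected(self):
        with pytest.raises(DomainError):
            reconstruct_absolute_k(AlphaFunction((1e-5,)))
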