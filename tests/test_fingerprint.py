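"""Chord slopes, band plans, binary/ternary fingerprints, alphabet entropy."""

import math

import numpy as np
import pytest

import fes
from fes.errors import AlignmentError, ExtrapolationError, ValidationError


class TestEndpointSlope:
    @pytest.mark.parametrize("level", [1.0, 1e-6, 42.0])
    def test_power_law_slope_is_minus_gamma_for_any_level(self, power_law, level):
        ps = power_law(1.0, level=level)
        assert fes.endpoint_slope(ps, 1.0, 10.0) == pytest.approx(-1.0, abs=1e-12)

    def test_flat_spectrum_slope_zero(self, power_law):
        ps = power_law(0.0)
        assert fes.endpoint_slope(ps, 1.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_chord_ignores_interior_bump(self):
        ps = fes.PowerSpectrum(
            frequencies=[1.0, 10.0, 100.0], density=[1.0, 5.0, 0.01]
        )
        assert fes.endpoint_slope(ps, 1.0, 100.0) == pytest.approx(-1.0, abs=1e-12)

    def test_bad_ordering_raises(self, power_law):
        with pytest.raises(ValidationError):
            fes.endpoint_slope(power_law(1.0), 10.0, 10.0)

    def test_outside_support_raises(self, power_law):
        ps = power_law(1.0, f_lo=1.0, f_hi=100.0)
        with pytest.raises(ExtrapolationError):
            fes.endpoint_slope(ps, 0.1, 10.0)


class TestMakeBandPlan:
    def test_log_equal_split(self):
        plan = fes.make_band_plan(1.0, 100.0, 2)
        np.testing.assert_allclose(plan.edges, [1.0, 10.0, 100.0], rtol=1e-12)

    def test_single_subband(self):
        plan = fes.make_band_plan(1.0, 100.0, 1)
        np.testing.assert_allclose(plan.edges, [1.0, 100.0], rtol=1e-12)

    def test_constant_edge_ratio(self):
        plan = fes.make_band_plan(2.0, 20.0, 5)
        ratios = plan.edges[1:] / plan.edges[:-1]
        np.testing.assert_allclose(ratios, 10.0 ** (1.0 / 5.0), rtol=1e-12)

    @pytest.mark.parametrize("args", [(10.0, 1.0, 3), (0.0, 10.0, 3), (1.0, 10.0, 0)])
    def test_invalid_inputs_raise(self, args):
        with pytest.raises(ValidationError):
            fes.make_band_plan(*args)


class TestSlopeProfile:
    def test_pure_power_law_all_slopes_equal(self, power_law, plan5):
        prof = fes.slope_profile(power_law(1.7), plan5)
        np.testing.assert_allclose(prof.local_slopes, -1.7, atol=1e-10)
        assert prof.global_slope == pytest.approx(-1.7, abs=1e-10)

    def test_telescoping_on_random_spectra(self, rng, random_spectrum):
        """Mean of local chord slopes equals the global chord slope on
        log-equal plans: interior endpoint values cancel in the sum."""
        for _ in range(25):
            ps = random_spectrum(rng)
            plan = fes.make_band_plan(ps.f_min, ps.f_max, int(rng.integers(1, 9)))
            prof = fes.slope_profile(ps, plan)
            assert prof.local_slopes.mean() == pytest.approx(
                prof.global_slope, abs=1e-9
            )

    def test_single_subband_equals_global(self, rng, random_spectrum):
        ps = random_spectrum(rng)
        plan = fes.make_band_plan(ps.f_min, ps.f_max, 1)
        prof = fes.slope_profile(ps, plan)
        assert prof.local_slopes[0] == pytest.approx(prof.global_slope, abs=1e-12)


def _spectrum_with_local_slopes(plan, slopes, level=1.0):
    """Piecewise power law whose chord slope over sub-band i is slopes[i]."""
    segs = tuple(
        (float(plan.edges[i]), float(plan.edges[i + 1]), -float(slopes[i]))
        for i in range(plan.n_subbands)
    )
    model = fes.SpectrumModel(segments=segs, overall_level=level)
    return fes.model_psd(model, np.geomspace(plan.f_low, plan.f_high, 400))


class TestBinaryFingerprint:
    def test_caption_pattern_below_above(self, plan5):
        """Local slopes (below, above, below, above, above) the global slope
        give bits [-1, +1, -1, +1, +1] — the labelled bits A through E."""
        ps = _spectrum_with_local_slopes(plan5, [-2.0, -0.5, -1.8, -0.9, -0.8])
        assert fes.binary_fingerprint(ps, plan5).bits == (-1, 1, -1, 1, 1)

    def test_pure_power_law_all_plus_one(self, power_law, plan5):
        """Every local slope ties the global; ties go to +1 by convention."""
        assert fes.binary_fingerprint(power_law(1.0), plan5).bits == (1, 1, 1, 1, 1)

    def test_two_exponent_spectrum_matches_hand_arithmetic(self):
        """gamma=1 on [1,10], gamma=2 on [10,100]: locals -1 and -2 straddle
        the global -1.5, so the bits are [+1, -1]."""
        model = fes.SpectrumModel(segments=((1.0, 10.0, 1.0), (10.0, 100.0, 2.0)))
        ps = fes.model_psd(model, np.geomspace(1.0, 100.0, 300))
        plan = fes.make_band_plan(1.0, 100.0, 2)
        assert fes.binary_fingerprint(ps, plan).bits == (1, -1)

    def test_always_contains_a_positive_bit(self, rng, random_spectrum):
        """Telescoping corollary: some local slope is >= the global slope."""
        for _ in range(25):
            ps = random_spectrum(rng)
            plan = fes.make_band_plan(ps.f_min, ps.f_max, int(rng.integers(1, 9)))
            assert 1 in fes.binary_fingerprint(ps, plan).bits

    def test_amplitude_invariance(self, rng, random_spectrum, plan5):
        ps = random_spectrum(rng, f_lo=1.0, f_hi=400.0)
        scaled = fes.PowerSpectrum(ps.frequencies, 1e6 * ps.density)
        assert (
            fes.binary_fingerprint(ps, plan5).bits
            == fes.binary_fingerprint(scaled, plan5).bits
        )


class TestTernaryFingerprint:
    def test_caption_pattern_relative_to_reference(self, plan5):
        """Agent local slopes (greater, less, equal, greater, greater) than the
        reference's give bits [+1, -1, 0, +1, +1] — labelled bits F through J."""
        ref = _spectrum_with_local_slopes(plan5, [-1.0] * 5)
        agent = _spectrum_with_local_slopes(plan5, [-0.6, -1.4, -1.0, -0.6, -0.8])
        fp = fes.ternary_fingerprint(agent, ref, plan5, tie_tolerance=0.05)
        assert fp.bits == (1, -1, 0, 1, 1)
        assert fp.scheme == "ternary"
        assert fp.reference_label

    def test_self_reference_is_all_zeros(self, rng, random_spectrum):
        for _ in range(25):
            ps = random_spectrum(rng)
            plan = fes.make_band_plan(ps.f_min, ps.f_max, int(rng.integers(1, 9)))
            tol = float(rng.uniform(0.0, 0.2))
            fp = fes.ternary_fingerprint(ps, ps, plan, tol)
            assert fp.bits == (0,) * plan.n_subbands

    def test_analytic_slopes_all_plus_one(self, power_law, plan5):
        """1/f agent vs 1/f^2 reference: -1 > -2 in every sub-band."""
        fp = fes.ternary_fingerprint(
            power_law(1.0), power_law(2.0), plan5, tie_tolerance=0.05
        )
        assert fp.bits == (1,) * 5

    def test_antisymmetry(self, rng, random_spectrum):
        for _ in range(10):
            a = random_spectrum(rng)
            b = random_spectrum(rng)
            plan = fes.make_band_plan(1.0, 400.0, 5)
            fab = fes.ternary_fingerprint(a, b, plan, 0.03)
            fba = fes.ternary_fingerprint(b, a, plan, 0.03)
            assert fab.bits == tuple(-x for x in fba.bits)

    def test_amplitude_invariance(self, rng, random_spectrum, plan5):
        a = random_spectrum(rng, f_lo=1.0, f_hi=400.0)
        b = random_spectrum(rng, f_lo=1.0, f_hi=400.0)
        a2 = fes.PowerSpectrum(a.frequencies, 7.3 * a.density)
        b2 = fes.PowerSpectrum(b.frequencies, 1e-4 * b.density)
        assert (
            fes.ternary_fingerprint(a, b, plan5, 0.05).bits
            == fes.ternary_fingerprint(a2, b2, plan5, 0.05).bits
        )

    def test_tolerance_monotonicity(self, rng, random_spectrum, plan5):
        """Raising the tie tolerance can only turn +-1 bits into 0."""
        a = random_spectrum(rng, f_lo=1.0, f_hi=400.0)
        b = random_spectrum(rng, f_lo=1.0, f_hi=400.0)
        tols = [0.0, 0.02, 0.05, 0.1, 0.5, 2.0]
        prev = fes.ternary_fingerprint(a, b, plan5, tols[0]).bits
        for tol in tols[1:]:
            cur = fes.ternary_fingerprint(a, b, plan5, tol).bits
            for p, c in zip(prev, cur):
                assert c == p or c == 0
            prev = cur

    def test_band_coverage_mismatch_raises(self, power_law, plan5):
        narrow_ref = power_law(1.0, f_lo=10.0, f_hi=100.0)
        with pytest.raises(AlignmentError):
            fes.ternary_fingerprint(power_law(1.0), narrow_ref, plan5, 0.05)

    def test_negative_tolerance_rejected(self, power_law, plan5):
        with pytest.raises(ValidationError):
            fes.ternary_fingerprint(power_law(1.0), power_law(2.0), plan5, -0.1)


class TestAlphabetEntropy:
    def test_binary_is_one_bit(self):
        assert fes.alphabet_entropy("binary") == 1.0

    def test_ternary_is_log2_of_three(self):
        h = fes.alphabet_entropy("ternary")
        assert h == pytest.approx(math.log(3) / math.log(2), abs=1e-12)
        assert h / fes.alphabet_entropy("binary") == pytest.approx(1.585, abs=1e-3)

    def test_entropy_increase_meets_fifty_percent(self):
        inc = fes.entropy_increase()
        assert inc == pytest.approx(100.0 * (math.log2(3) - 1.0), abs=1e-12)
        assert inc >= 50.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            fes.alphabet_entropy("quaternary")
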