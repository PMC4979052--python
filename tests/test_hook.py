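"""Langmuir hook decomposition: background, correction, curve, inversion."""

import numpy as np
import pytest

import hookqc as hq
from hookqc.errors import InsufficientDataError, ValidationError
from hookqc.hook import CorrectedChip, _floor_for
from hookqc.sequence import SensitivityProfile

from conftest import make_chip


ZERO_PROFILE = SensitivityProfile(sigma=np.zeros((24, 16)))


class TestOpticalBackground:
    def test_constant_intensities(self):
        chip = make_chip(pm_base=1000.0, with_mm=False)
        chip.pm[:] = 400.0
        assert hq.estimate_optical_background(chip) == pytest.approx(360.0)
        corrected = hq.sequence_correct(chip, ZERO_PROFILE, 360.0)
        np.testing.assert_allclose(corrected.pm, 40.0)

    def test_bounded_by_rule(self):
        chip = make_chip(pm_base=100.0)
        assert hq.estimate_optical_background(chip) <= 90.0 * 1.1

    def test_simulated_estimate_near_true_background(self):
        """Percentile rule lands in [30, 55] for O=50, M=10000 chips; the
        profile-likelihood refinement recovers O to a few units."""
        for seed in range(1, 6):
            chip, _, _ = hq.simulate_chip(hq.SimulationConfig(seed=seed))
            o_rule = hq.estimate_optical_background(chip)
            assert 30.0 <= o_rule <= 55.0
            idx = hq.select_absent_probes(chip)
            o_ref = hq.refine_optical_background(chip, idx, o_rule)
            assert abs(o_ref - 50.0) < 5.0


class TestSequenceCorrect:
    def test_zero_profile_divides_by_one(self):
        chip = make_chip()
        corrected = hq.sequence_correct(chip, ZERO_PROFILE, 10.0)
        np.testing.assert_allclose(corrected.pm, chip.pm - 10.0)

    def test_unit_delta_a_divides_by_ten(self):
        chip = make_chip(n_sets=1, probes_per_set=3, with_mm=False)
        # a constant row scores dA = 1 for every sequence
        sigma = np.zeros((24, 16))
        sigma[0, :] = 1.0
        profile = SensitivityProfile(sigma=sigma)
        corrected = hq.sequence_correct(chip, profile, 0.0)
        np.testing.assert_allclose(corrected.pm, chip.pm / 10.0)

    def test_correction_removes_sequence_variation(self):
        """Noise-free non-specific chip: after fitting and correcting, the
        absent probes' log10 intensities collapse (sd < 0.01)."""
        cfg = hq.SimulationConfig(f_present=0.0, noise_sd_log=0.0, seed=3)
        chip, _, _ = hq.simulate_chip(cfg)
        idx = hq.select_absent_probes(chip)
        o = hq.refine_optical_background(
            chip, idx, hq.estimate_optical_background(chip))
        profile = hq.fit_sensitivity_profile(chip, idx, background=o)
        corrected = hq.sequence_correct(chip, profile, o)
        assert np.log10(corrected.pm).std() < 0.01


class TestHookCurve:
    def test_requires_mm(self):
        chip = make_chip(with_mm=False)
        corrected = hq.sequence_correct(chip, ZERO_PROFILE, 0.0)
        with pytest.raises(ValidationError, match="MM"):
            hq.build_hook_curve(corrected)

    def test_windows_cover_all_sets(self, default_corrected):
        hook = hq.build_hook_curve(default_corrected)
        assert hook.n_windows >= 10
        assert hook.starts[0] == 0
        assert hook.starts[-1] + hook.window == default_corrected.chip.n_sets

    def test_hook_rises_to_its_maximum(self, default_corrected):
        """Smoothed delta is non-decreasing (within noise) from the left
        end up to its maximum — the rising flank of the hook."""
        hook = hq.build_hook_curve(default_corrected)
        top = int(np.argmax(hook.smooth_delta))
        rise = hook.smooth_delta[: top + 1]
        assert (np.diff(rise) > -0.05).all()
        assert hook.smooth_delta[top] > hook.smooth_delta[0] + 0.3


@pytest.fixture(scope="module")
def default_corrected():
    chip, _, _ = hq.simulate_chip(hq.SimulationConfig(seed=6))
    idx = hq.select_absent_probes(chip)
    o = hq.refine_optical_background(
        chip, idx, hq.estimate_optical_background(chip))
    profile = hq.fit_sensitivity_profile(chip, idx, background=o)
    return hq.sequence_correct(chip, profile, o)


class TestChipParams:
    def test_beta_is_neg_log10_n(self):
        params = hq.ChipHybridizationParams(
            optical_o=50.0, saturation_m=10000.0, n_chip=0.01,
            sigma_break=1.0, n_absent_sets=100,
            absent_sets=np.ones(200, dtype=bool))
        assert params.beta == pytest.approx(2.0, abs=1e-12)

    def test_nearly_pure_nonspecific_recovery(self):
        """With almost nothing expressed (but a few saturated sets to anchor
        M), the non-specific level m_ns matches M N/(1+N) and beta is
        recovered within 0.1."""
        cfg = hq.SimulationConfig(f_present=0.05, noise_sd_log=0.0,
                                  s_mean_log=0.5, s_sd_log=0.3, seed=4)
        chip, _, _ = hq.simulate_chip(cfg)
        analysis = hq.analyze_chip(chip)
        assert analysis.metrics.beta == pytest.approx(2.25, abs=0.1)

    def test_pm_only_fallback(self):
        chip, truth, _ = hq.simulate_chip(hq.SimulationConfig(seed=11))
        chip.mm = None
        analysis = hq.analyze_chip(chip)
        assert analysis.hook is None
        assert analysis.metrics.beta == pytest.approx(2.25, abs=0.3)
        assert analysis.metrics.lambda_ == pytest.approx(
            truth.true_lambda, abs=0.15)

    def test_hook_width_tracks_nonspecific_level(self):
        """More non-specific background (smaller beta_true) narrows the
        measuring range: estimated beta is ordered like the truth."""
        estimates = []
        for bt in (1.5, 2.25, 3.0):
            chip, _, _ = hq.simulate_chip(
                hq.SimulationConfig(beta_true=bt, seed=7))
            estimates.append(hq.analyze_chip(chip).metrics.beta)
        assert estimates[0] < estimates[1] < estimates[2]


def synthetic_corrected(y, n_chip, m, probes_per_set=4):
    """CorrectedChip with prescribed corrected PM intensities."""
    chip = make_chip(n_sets=y.size // probes_per_set,
                     probes_per_set=probes_per_set, with_mm=False)
    return CorrectedChip(chip=chip, o=0.0, floor=1e-6, pm=y, mm=None,
                         profile=ZERO_PROFILE), hq.ChipHybridizationParams(
        optical_o=0.0, saturation_m=m, n_chip=n_chip, sigma_break=0.0,
        n_absent_sets=0, absent_sets=np.zeros(y.size // probes_per_set,
                                              dtype=bool))


class TestLangmuirInversion:
    def test_roundtrip_exact_to_1e9(self):
        """Forward-simulate y = M(N+S)/(1+N+S), invert, recover S."""
        rng = np.random.default_rng(0)
        n, m = 0.005, 10000.0
        s_true = np.repeat(10.0 ** rng.uniform(-2, 1, 50), 4)
        y = m * (n + s_true) / (1 + n + s_true)
        corrected, params = synthetic_corrected(y, n, m)
        est = hq.decompose_probesets(corrected, params)
        np.testing.assert_allclose(est.s_set, s_true[::4], rtol=0, atol=1e-9)
        np.testing.assert_allclose(est.r_set, s_true[::4] / n, rtol=1e-9)

    def test_pure_nonspecific_set_gives_zero_s(self):
        n, m = 0.01, 1000.0
        y = np.full(8, m * n / (1 + n))
        corrected, params = synthetic_corrected(y, n, m)
        est = hq.decompose_probesets(corrected, params)
        np.testing.assert_allclose(est.s_set, 0.0, atol=1e-12)
        assert not est.expressed.any()

    def test_below_nonspecific_clipped_to_zero(self):
        n, m = 0.01, 1000.0
        y = np.full(8, 0.1 * m * n / (1 + n))
        corrected, params = synthetic_corrected(y, n, m)
        est = hq.decompose_probesets(corrected, params)
        assert (est.s_set == 0.0).all()

    def test_monotone_in_specific_signal(self):
        """Raising every present set's specific strength (noise-free) raises
        the estimated transcript level and no set's R decreases."""
        results = []
        for s_mean in (-1.0, -0.7):
            chip, _, _ = hq.simulate_chip(hq.SimulationConfig(
                noise_sd_log=0.0, s_mean_log=s_mean, seed=3))
            analysis = hq.analyze_chip(chip)
            results.append((analysis.metrics.lambda_,
                            analysis.estimates.r_set))
        assert results[1][0] > results[0][0]
        assert (results[1][1] - results[0][1] > -1e-9).all()


def test_floor_follows_background():
    assert _floor_for(900.0) == pytest.approx(1.0)
    assert _floor_for(0.0) > 0
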