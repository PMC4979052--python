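"""Langmuir decomposition of probe-set signals ("hook" analysis).

After removing the optical background and the sequence effect, probe
intensities follow a Langmuir isotherm

    I' = M * B / (1 + B),        B = N_p + S_p

with chip-wide saturation M, per-set non-specific strength N_p and specific
strength S_p.  For PM/MM chips, plotting the per-set log-intensity difference
delta = <log10 PM' - log10 MM'> against the per-set mean log intensity
sigma = <0.5 (log10 PM' + log10 MM')> produces the characteristic hook-shaped
curve: flat at the non-specific (absent) end, rising where specific binding
dominates, and bending down again under saturation.  The geometry of this
curve separates absent from expressed probe sets and yields the chip
parameters:

* ``beta = -log10(n_chip)``, the measuring range — the width of the hook,
  estimated here as the (log) distance between saturation and the mean
  non-specific signal;
* ``M``, the saturation intensity;
* per-set ``S_p`` and ``R_p = S_p / N_p``, by exact inversion of the
  Langmuir form.

This module implements a deterministic break-point heuristic in place of a
full nonlinear hook fit; all constants are exposed as keyword arguments.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import InsufficientDataError, ValidationError
from .io import ChipData
from .sequence import SensitivityProfile, indicator_design
from .simulate import _mm_codes


def estimate_optical_background(chip: ChipData) -> float:
    """Optical background O: 90% of the 0.5th percentile of all intensities
    (PM and MM pooled).  The floor used when subtracting O is O / 900
    (i.e. 10^-3 of that percentile)."""
    pooled = chip.pm if not chip.has_mm else np.concatenate([chip.pm, chip.mm])
    return float(0.9 * np.percentile(pooled, 0.5))


def _floor_for(o: float) -> float:
    # 1e-3 x the 0.5th intensity percentile, re-expressed through O = 0.9 p.
    return o / 900.0 if o > 0 else 1e-6


def refine_optical_background(chip: ChipData, probe_indices: np.ndarray,
                              o_initial: float, ridge: float = 1e-6,
                              xatol: float = 0.01) -> float:
    """Refine the optical background by profile likelihood on the NN fit.

    The percentile rule of :func:`estimate_optical_background` overshoots the
    true additive background by the Langmuir non-specific floor.  For the
    absent-probe pool the model is

        log10(PM_i - O) = intercept + dA_i + noise,

    exactly linear in the dinucleotide indicators at the true O.  O is
    therefore estimated by minimizing the profiled negative log-likelihood
    of the transformed linear model,

        n/2 * ln(SSE(O)/n) + sum_i ln(PM_i - O),

    over O in [0, min(PM)); the second term is the log-Jacobian of the log
    transform (without it, the multiplicative noise would drive O toward
    -inf because compression shrinks the residuals).  The indicator normal
    matrix does not depend on O, so the scan costs one Cholesky plus a
    handful of cheap solves.
    """
    probe_indices = np.asarray(probe_indices, dtype=np.intp)
    pm = chip.pm[probe_indices]
    o_max = 0.999 * float(pm.min())
    if o_max <= 0:
        return 0.0
    x, _ = indicator_design(chip.codes[probe_indices])
    normal = (x.T @ x).toarray()
    normal[np.diag_indices_from(normal)] += ridge
    factor = scipy.linalg.cho_factor(normal)
    n = pm.shape[0]

    def negll(o: float) -> float:
        t = pm - o
        y = np.log10(t)
        rhs = x.T @ y
        coef = scipy.linalg.cho_solve(factor, rhs)
        sse = max(float(y @ y - coef @ rhs), 1e-300)
        return 0.5 * n * np.log(sse / n) + float(np.log(t).sum())

    result = scipy.optimize.minimize_scalar(
        negll, bounds=(0.0, o_max), method="bounded",
        options={"xatol": xatol})
    o = float(result.x)
    if not np.isfinite(o) or o < 0:
        return min(o_initial, o_max)
    return o


@dataclasses.dataclass
class CorrectedChip:
    """Optically and sequence-corrected intensities of one chip."""

    chip: ChipData
    o: float
    floor: float
    pm: np.ndarray
    mm: np.ndarray | None
    profile: SensitivityProfile

    @property
    def has_mm(self) -> bool:
        return self.mm is not None


def sequence_correct(chip: ChipData, profile: SensitivityProfile,
                     o: float) -> CorrectedChip:
    """I' = max(I - O, floor) / 10^dA(sequence), PM and MM each with their
    own sequence (MM: middle base complemented)."""
    floor = _floor_for(o)
    da_pm = profile.delta_a_codes(chip.codes)
    pm = np.maximum(chip.pm - o, floor) / 10.0 ** da_pm
    mm = None
    if chip.has_mm:
        da_mm = profile.delta_a_codes(_mm_codes(chip.codes))
        mm = np.maximum(chip.mm - o, floor) / 10.0 ** da_mm
    return CorrectedChip(chip=chip, o=o, floor=floor, pm=pm, mm=mm,
                         profile=profile)


@dataclasses.dataclass
class HookCurve:
    """Per-set hook coordinates, sorted by sigma_set, plus the smoothed
    curve on sliding windows."""

    sigma_set: np.ndarray     # sorted per-set mean log intensity
    delta_set: np.ndarray     # aligned per-set PM-MM log difference
    set_order: np.ndarray     # chip set indices in sigma order
    window: int
    starts: np.ndarray
    smooth_sigma: np.ndarray  # window-center sigma (mean sigma per window)
    smooth_delta: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.starts.shape[0]


def _set_means(values: np.ndarray, set_codes: np.ndarray,
               n_sets: int) -> np.ndarray:
    counts = np.bincount(set_codes, minlength=n_sets)
    return np.bincount(set_codes, weights=values, minlength=n_sets) / counts


def build_hook_curve(corrected: CorrectedChip, min_windows: int = 10
                     ) -> HookCurve:
    """Per-set hook coordinates with sliding-window smoothing.

    Window size is max(50, n_sets/40) sets, step half a window (reduced when
    necessary so at least ``min_windows`` windows exist); a final window is
    appended when needed so every set is covered.
    """
    if not corrected.has_mm:
        raise ValidationError(
            "hook curve requires MM intensities; use the PM-only parameter "
            "estimate instead")
    chip = corrected.chip
    if chip.n_sets < 200:
        raise InsufficientDataError(
            f"hook curve needs >= 200 probe sets, got {chip.n_sets}")
    log_pm = np.log10(corrected.pm)
    log_mm = np.log10(corrected.mm)
    n_sets = chip.n_sets
    sigma = _set_means(0.5 * (log_pm + log_mm), chip.set_codes, n_sets)
    delta = _set_means(log_pm - log_mm, chip.set_codes, n_sets)
    order = np.argsort(sigma, kind="stable")
    sigma_sorted = sigma[order]
    delta_sorted = delta[order]

    window = min(n_sets, max(50, n_sets // 40))
    step = max(1, window // 2)
    if n_sets >= window + (min_windows - 1):
        max_step = max(1, (n_sets - window) // (min_windows - 1))
        step = min(step, max_step)
    starts = np.arange(0, n_sets - window + 1, step)
    if starts.size == 0 or starts[-1] + window < n_sets:
        starts = np.append(starts, n_sets - window)
    csum_s = np.concatenate([[0.0], np.cumsum(sigma_sorted)])
    csum_d = np.concatenate([[0.0], np.cumsum(delta_sorted)])
    smooth_sigma = (csum_s[starts + window] - csum_s[starts]) / window
    smooth_delta = (csum_d[starts + window] - csum_d[starts]) / window
    return HookCurve(sigma_set=sigma_sorted, delta_set=delta_sorted,
                     set_order=order, window=window, starts=starts,
                     smooth_sigma=smooth_sigma, smooth_delta=smooth_delta)


@dataclasses.dataclass
class ChipHybridizationParams:
    """Chip-level Langmuir parameters."""

    optical_o: float
    saturation_m: float
    n_chip: float
    sigma_break: float
    n_absent_sets: int
    absent_sets: np.ndarray  # boolean mask over chip sets

    @property
    def beta(self) -> float:
        """Measuring range, beta = -log10 N (Eq 5 with the chip-wide N)."""
        return float(-np.log10(self.n_chip))

    def __post_init__(self) -> None:
        if self.saturation_m <= 0:
            raise ValidationError("saturation_m must be > 0")
        if not 1e-5 < self.n_chip < 1.0:
            warnings.warn(
                f"n_chip = {self.n_chip:.3g} outside the typical range "
                f"(1e-5, 1)", stacklevel=3)


def _nonspecific_level(corrected: CorrectedChip, absent_sets: np.ndarray,
                       sigma_break: float, m_margin: float
                       ) -> ChipHybridizationParams:
    chip = corrected.chip
    n_absent = int(absent_sets.sum())
    if n_absent == 0:
        raise InsufficientDataError(
            "cannot estimate the non-specific level: no absent probe sets "
            "below the hook break point")
    # M from optically corrected intensities WITHOUT sequence correction:
    # saturated probes carry no sequence modulation, so dividing them by
    # 10^dA would inflate the brightest sets and hence M.
    optical_only = np.maximum(chip.pm - corrected.o, corrected.floor)
    set_mean_pm = _set_means(optical_only, chip.set_codes, chip.n_sets)
    m = m_margin * float(set_mean_pm.max())
    m_ns = float(corrected.pm[absent_sets[chip.set_codes]].mean())
    if m <= m_ns:
        raise AssertionError("saturation estimate below non-specific level")
    n_chip = m_ns / (m - m_ns)
    return ChipHybridizationParams(
        optical_o=corrected.o, saturation_m=m, n_chip=n_chip,
        sigma_break=sigma_break, n_absent_sets=n_absent,
        absent_sets=absent_sets)


def estimate_chip_params(hook: HookCurve, corrected: CorrectedChip,
                         decile: float = 0.10, sd_mult: float = 3.0,
                         delta_floor: float = 0.1, run_length: int = 3,
                         m_margin: float = 1.2) -> ChipHybridizationParams:
    """Chip parameters from the hook geometry.

    The non-specific delta level is taken from the dimmest decile of sets;
    the break point is the first window center whose smoothed delta exceeds
    that level by max(delta_floor, sd_mult x SD) for ``run_length``
    consecutive windows.  Sets left of the break are absent; the saturation
    M is ``m_margin`` times the largest set-mean corrected PM intensity and
    ``n_chip`` follows from the mean non-specific intensity m_ns via the
    Langmuir form n = m_ns / (M - m_ns).
    """
    n_sets = hook.sigma_set.shape[0]
    n_low = max(1, int(decile * n_sets))
    delta_ns = float(hook.delta_set[:n_low].mean())
    s_ns = float(hook.delta_set[:n_low].std())
    threshold = delta_ns + max(delta_floor, sd_mult * s_ns)

    above = hook.smooth_delta > threshold
    sigma_break = np.inf  # never exceeded: every set is absent
    for w in range(hook.n_windows - run_length + 1):
        if above[w: w + run_length].all():
            sigma_break = float(hook.smooth_sigma[w])
            break
    chip = corrected.chip
    set_sigma = np.empty(n_sets)
    set_sigma[hook.set_order] = hook.sigma_set
    absent_sets = set_sigma < sigma_break
    return _nonspecific_level(corrected, absent_sets, sigma_break, m_margin)


def estimate_chip_params_pm_only(corrected: CorrectedChip,
                                 decile: float = 0.10, sd_mult: float = 3.0,
                                 delta_floor: float = 0.1,
                                 m_margin: float = 1.2
                                 ) -> ChipHybridizationParams:
    """PM-only fallback (no MM, hence no hook curve; lower fidelity).

    Absent sets are those whose set-mean log10 corrected PM intensity lies
    below the dimmest decile's mean plus max(delta_floor, sd_mult x SD).
    """
    chip = corrected.chip
    if chip.n_sets < 200:
        raise InsufficientDataError(
            f"parameter estimation needs >= 200 probe sets, got {chip.n_sets}")
    set_log = _set_means(np.log10(corrected.pm), chip.set_codes, chip.n_sets)
    ordered = np.sort(set_log)
    n_low = max(1, int(decile * chip.n_sets))
    mu_low = float(ordered[:n_low].mean())
    sd_low = float(ordered[:n_low].std())
    sigma_break = mu_low + max(delta_floor, sd_mult * sd_low)
    absent_sets = set_log < sigma_break
    return _nonspecific_level(corrected, absent_sets, sigma_break, m_margin)


@dataclasses.dataclass
class ProbeSetEstimates:
    """Per-set Langmuir decomposition of one chip (vectorized container).

    ``s_set``, ``n_set``, ``r_set`` and ``expressed`` are parallel arrays over
    the chip's probe sets (in first-appearance order); ``probe_s`` holds the
    per-probe specific strengths used by the degradation analysis, aligned
    with the chip's probe order.
    """

    probeset_ids: np.ndarray
    s_set: np.ndarray
    n_set: np.ndarray
    r_set: np.ndarray
    expressed: np.ndarray
    probe_s: np.ndarray
    probe_set_codes: np.ndarray
    probe_x: np.ndarray
    r_expressed_threshold: float

    @property
    def n_sets(self) -> int:
        return self.s_set.shape[0]

    @property
    def n_expressed(self) -> int:
        return int(self.expressed.sum())


def decompose_probesets(corrected: CorrectedChip,
                        params: ChipHybridizationParams,
                        r_expressed: float = 0.5,
                        probe_saturation_frac: float = 0.995
                        ) -> ProbeSetEstimates:
    """Invert the Langmuir form per probe set (and per probe).

    With y the mean linear corrected PM intensity of a set,
    ``s = (y (1 + n) - M n) / (M - y)`` recovers the specific strength
    exactly in the noise-free case; negative values (sets below the
    non-specific level) are clipped to zero.  Intensities are clipped at
    ``probe_saturation_frac * M`` before inversion: sequence-corrected
    values of saturated probes can exceed the saturation estimate (their
    observed intensity is no longer sequence-modulated), which would flip
    the inversion's denominator.
    """
    chip = corrected.chip
    m = params.saturation_m
    n = params.n_chip
    y_set = _set_means(corrected.pm, chip.set_codes, chip.n_sets)
    y_set = np.minimum(y_set, probe_saturation_frac * m)
    s_set = (y_set * (1.0 + n) - m * n) / (m - y_set)
    s_set = np.maximum(s_set, 0.0)
    r_set = s_set / n
    y_probe = np.minimum(corrected.pm, probe_saturation_frac * m)
    probe_s = (y_probe * (1.0 + n) - m * n) / (m - y_probe)
    return ProbeSetEstimates(
        probeset_ids=chip.set_ids,
        s_set=s_set,
        n_set=np.full(chip.n_sets, n),
        r_set=r_set,
        expressed=r_set > r_expressed,
        probe_s=probe_s,
        probe_set_codes=chip.set_codes,
        probe_x=chip.normalized_position,
        r_expressed_threshold=r_expressed,
    )
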