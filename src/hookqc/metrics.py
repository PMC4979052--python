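"""Per-sample quality metrics and threshold flags.

Five probe-level metrics summarize one hybridized sample:

* ``d_index`` — RNA degradation surrogate.  Within each expressed probe set,
  the per-probe specific strengths decay toward the 5' end when the RNA was
  degraded; the pooled decadic-log decay slope gamma per unit normalized
  position yields d = 10^(-gamma), clipped to <= 1.  d = 1 means no decay;
  d < 0.45 corresponds to RIN < 7 by the established convention.
* ``lambda_`` — specific transcript level: mean log10(R + 1) over expressed
  sets (R = S/N > 0.5); proxies the amount of specific RNA hybridized.
* ``beta`` — measuring range, -log10 of the chip non-specific strength.
* ``log_kdiff`` — maximum sensitivity amplitude of the fitted NN profile.
* ``d_ggg`` — guanine-run bias: mean log10 intensity excess of probes
  starting with GGG over probes containing TTT anywhere (computed on
  optically corrected but NOT sequence-corrected intensities, since sequence
  correction would absorb the very effect being measured).

Samples are flagged against conservative thresholds; an undefined metric
never raises a flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.stats

from .errors import HookQCError
from .hook import (CorrectedChip, ChipHybridizationParams, HookCurve,
                   ProbeSetEstimates, build_hook_curve, decompose_probesets,
                   estimate_chip_params, estimate_chip_params_pm_only,
                   estimate_optical_background, refine_optical_background,
                   sequence_correct, _floor_for)
from .io import ChipData, require_minimum_sets
from .sequence import (ExtremalResult, SensitivityProfile,
                       extremal_sequences, fit_sensitivity_profile,
                       select_absent_probes)

FLAG_LOW_RNA_QUALITY = "LOW_RNA_QUALITY"
FLAG_LOW_SPECIFIC_LEVEL = "LOW_SPECIFIC_LEVEL"
FLAG_LOW_MEASURING_RANGE = "LOW_MEASURING_RANGE"
FLAG_LOW_SEQUENCE_EFFECT = "LOW_SEQUENCE_EFFECT"
FLAG_HIGH_GGG_EFFECT = "HIGH_GGG_EFFECT"

ALL_FLAGS = (FLAG_LOW_RNA_QUALITY, FLAG_LOW_SPECIFIC_LEVEL,
             FLAG_LOW_MEASURING_RANGE, FLAG_LOW_SEQUENCE_EFFECT,
             FLAG_HIGH_GGG_EFFECT)

#: metric column (QC report naming) backing each flag
FLAG_METRIC = {
    FLAG_LOW_RNA_QUALITY: "d_index",
    FLAG_LOW_SPECIFIC_LEVEL: "lambda",
    FLAG_LOW_MEASURING_RANGE: "beta",
    FLAG_LOW_SEQUENCE_EFFECT: "log_kdiff",
    FLAG_HIGH_GGG_EFFECT: "d_ggg",
}


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Flagging thresholds.

    Defaults are the conservative cut-offs established for HG-U133-class
    arrays: d >= 0.45 (the RIN-7 equivalent), lambda >= 0.95, beta >= 1.8,
    log(K_diff) >= 3 and dI(GGG)1 <= 0.25.
    """

    d_min: float = 0.45
    lambda_min: float = 0.95
    beta_min: float = 1.8
    log_kdiff_min: float = 3.0
    d_ggg_max: float = 0.25
    r_expressed: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise HookQCError(f"threshold {f.name} must be positive")


@dataclasses.dataclass(frozen=True)
class QualityMetrics:
    """Per-sample metric values and flags; None marks an undefined metric."""

    sample_id: str
    d_index: float | None
    lambda_: float | None
    beta: float | None
    log_kdiff: float | None
    d_ggg: float | None
    n_expressed: int | None
    decay_slope_gamma: float | None
    flags: tuple[str, ...]


def specific_transcript_level(estimates: ProbeSetEstimates,
                              r_expressed: float = 0.5) -> float | None:
    """lambda = <log10(R + 1)> over sets with R > r_expressed (Eq 4);
    None when no set qualifies."""
    r = estimates.r_set
    mask = r > r_expressed
    if not mask.any():
        return None
    return float(np.mean(np.log10(r[mask] + 1.0)))


def degradation_index(estimates: ProbeSetEstimates, min_sets: int = 50,
                      min_probes: int = 4
                      ) -> tuple[float, float] | None:
    """(d_index, decay_slope_gamma) from the pooled within-set decay of the
    per-probe specific strengths, or None when fewer than ``min_sets``
    expressed sets with >= ``min_probes`` probes are available.

    For every expressed set, each probe contributes log10(s_i / <s>_set)
    paired with its normalized position x_i (0 at the 3' end); probes whose
    inverted s_i is non-positive carry no usable specific signal and are
    dropped.  gamma is minus the pooled OLS slope, d = min(1, 10^-gamma).
    """
    set_sizes = np.bincount(estimates.probe_set_codes,
                            minlength=estimates.n_sets)
    usable_sets = estimates.expressed & (set_sizes >= min_probes)
    if int(usable_sets.sum()) < min_sets:
        return None
    in_set = usable_sets[estimates.probe_set_codes]
    positive = estimates.probe_s > 0
    use = in_set & positive
    s = estimates.probe_s[use]
    codes = estimates.probe_set_codes[use]
    x = estimates.probe_x[use]
    counts = np.bincount(codes, minlength=estimates.n_sets)
    mean_s = np.bincount(codes, weights=s, minlength=estimates.n_sets)
    with np.errstate(invalid="ignore"):
        mean_s = mean_s / counts
    ratio = np.log10(s / mean_s[codes])
    fit = scipy.stats.linregress(x, ratio)
    gamma = -float(fit.slope)
    d_index = min(1.0, 10.0 ** (-gamma))
    return d_index, gamma


def ggg_effect(chip: ChipData, o: float, min_group: int = 50) -> float | None:
    """dI(GGG)1 = <log10 I'>_{GGG start} - <log10 I'>_{TTT anywhere} on
    optically corrected PM intensities (Eq 6); None when either group has
    fewer than ``min_group`` probes."""
    codes = chip.codes
    ggg = (codes[:, :3] == 2).all(axis=1)
    ttt = np.zeros(chip.n_probes, dtype=bool)
    for k in range(codes.shape[1] - 2):
        ttt |= (codes[:, k: k + 3] == 3).all(axis=1)
    ttt &= ~ggg
    if int(ggg.sum()) < min_group or int(ttt.sum()) < min_group:
        return None
    floor = _floor_for(o)
    log_i = np.log10(np.maximum(chip.pm - o, floor))
    return float(log_i[ggg].mean() - log_i[ttt].mean())


def assign_flags(d_index: float | None, lambda_: float | None,
                 beta: float | None, log_kdiff: float | None,
                 d_ggg: float | None,
                 thresholds: ThresholdConfig) -> tuple[str, ...]:
    """Pure threshold function; undefined (None) metrics never flag."""
    flags = []
    if d_index is not None and d_index < thresholds.d_min:
        flags.append(FLAG_LOW_RNA_QUALITY)
    if lambda_ is not None and lambda_ < thresholds.lambda_min:
        flags.append(FLAG_LOW_SPECIFIC_LEVEL)
    if beta is not None and beta < thresholds.beta_min:
        flags.append(FLAG_LOW_MEASURING_RANGE)
    if log_kdiff is not None and log_kdiff < thresholds.log_kdiff_min:
        flags.append(FLAG_LOW_SEQUENCE_EFFECT)
    if d_ggg is not None and d_ggg > thresholds.d_ggg_max:
        flags.append(FLAG_HIGH_GGG_EFFECT)
    return tuple(flags)


@dataclasses.dataclass
class ChipAnalysis:
    """Full per-sample analysis: the metrics plus every intermediate."""

    metrics: QualityMetrics
    profile: SensitivityProfile
    extremal: ExtremalResult
    optical_o: float
    params: ChipHybridizationParams
    estimates: ProbeSetEstimates
    hook: HookCurve | None


def analyze_chip(chip: ChipData, thresholds: ThresholdConfig | None = None,
                 absent_quantile: float = 0.30, min_deg_sets: int = 50,
                 min_ggg_group: int = 50) -> ChipAnalysis:
    """Run the full per-sample pipeline.

    Optical background (percentile rule, then sequence-model refinement) ->
    absent-probe selection -> NN profile fit -> extremal sequences ->
    sequence correction -> hook curve (or the PM-only fallback) -> chip
    parameters -> Langmuir decomposition -> metrics -> flags.
    """
    thresholds = thresholds or ThresholdConfig()
    require_minimum_sets(chip)
    try:
        o_initial = estimate_optical_background(chip)
        idx = select_absent_probes(chip, absent_quantile)
        o = refine_optical_background(chip, idx, o_initial)
        profile = fit_sensitivity_profile(chip, idx, background=o)
        ext = extremal_sequences(profile)
        corrected = sequence_correct(chip, profile, o)
        if chip.has_mm:
            hook = build_hook_curve(corrected)
            params = estimate_chip_params(hook, corrected)
        else:
            hook = None
            params = estimate_chip_params_pm_only(corrected)
        estimates = decompose_probesets(corrected, params,
                                        thresholds.r_expressed)
    except HookQCError as exc:
        raise type(exc)(f"sample {chip.sample_id!r}: {exc}") from exc

    lambda_ = specific_transcript_level(estimates, thresholds.r_expressed)
    deg = degradation_index(estimates, min_sets=min_deg_sets)
    d_index, gamma = deg if deg is not None else (None, None)
    d_ggg = ggg_effect(chip, o, min_group=min_ggg_group)
    beta = params.beta
    log_kdiff = ext.log_kdiff
    metrics = QualityMetrics(
        sample_id=chip.sample_id,
        d_index=d_index,
        lambda_=lambda_,
        beta=beta,
        log_kdiff=log_kdiff,
        d_ggg=d_ggg,
        n_expressed=estimates.n_expressed,
        decay_slope_gamma=gamma,
        flags=assign_flags(d_index, lambda_, beta, log_kdiff, d_ggg,
                           thresholds),
    )
    return ChipAnalysis(metrics=metrics, profile=profile, extremal=ext,
                        optical_o=o, params=params, estimates=estimates,
                        hook=hook)


def compute_qc(chip: ChipData, thresholds: ThresholdConfig | None = None,
               **kwargs) -> QualityMetrics:
    """Per-sample quality metrics (thin wrapper over :func:`analyze_chip`)."""
    return analyze_chip(chip, thresholds, **kwargs).metrics
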