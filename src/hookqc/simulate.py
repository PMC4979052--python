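"""Synthetic Langmuir chip simulator.

Generates probe-level chip data with a fully known ground truth, emulating the
hybridization physics of 3'-expression arrays:

* Each probe set p carries a non-specific binding strength ``N_p = 10**(-beta_true)``
  and, with probability ``f_present``, a specific strength ``S_p = 10**s`` with
  ``s ~ Normal(s_mean_log, s_sd_log)`` (decadic logs throughout).
* RNA degradation attenuates only the specific mode, by ``10**(-gamma_decay * x)``
  where x in [0, 1] is the probe's normalized distance from the 3' end.
* The probe sequence modulates binding through the positional NN profile
  (``10**dA``), and probes starting with a guanine triplet get an extra factor
  ``10**delta_ggg_true`` (G-quadruplex affinity bias, applied pre-saturation).
* Observed PM intensity follows a Langmuir isotherm with saturation M, additive
  optical background O and multiplicative log-normal noise:

      PM = O + M * B / (1 + B) * 10**eps,   eps ~ Normal(0, noise_sd_log)

* MM probes use the PM sequence with the middle base (position 13)
  complemented; their binding strength re-uses the set strengths with reduced
  specific (default 0.2x) and slightly reduced non-specific (0.8x)
  cross-hybridization factors.

Everything is seeded and bit-reproducible: identical configs give identical
chips.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Any, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .io import ChipData, SampleMetadata, decode_sequences, PROBE_LENGTH
from .sequence import (SensitivityProfile, N_POSITIONS,
                       canonicalize_profile, extremal_sequences)

_G = 2  # base code of guanine
_MAX_SEED = 2**31 - 1


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters of one simulated hybridization.

    Defaults are the package's reference study conditions: a mid-size chip
    (2000 sets x 11 probes) with 30% expressed transcripts, non-specific
    level beta = 2.25 (the typical measuring range of a good hybridization),
    log-normal specific abundances centered at S = 0.1, 5% multiplicative
    intensity noise and a moderate sequence effect; degradation and guanine
    bias are off unless switched on.
    """

    n_sets: int = 2000
    probes_per_set: int = 11
    f_present: float = 0.3
    beta_true: float = 2.25
    s_mean_log: float = -1.0
    s_sd_log: float = 0.7
    gamma_decay: float = 0.0
    delta_ggg_true: float = 0.0
    sensitivity_amplitude: float = 0.15
    saturation_m: float = 10000.0
    optical_o: float = 50.0
    noise_sd_log: float = 0.05
    mm_specific_factor: float = 0.2
    mm_nonspecific_factor: float = 0.8
    ggg_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_sets < 200:
            raise ValidationError(f"n_sets must be >= 200, got {self.n_sets}")
        if self.probes_per_set < 3:
            raise ValidationError(
                f"probes_per_set must be >= 3, got {self.probes_per_set}")
        if not 0.0 <= self.f_present < 1.0:
            raise ValidationError(f"f_present must be in [0, 1), got {self.f_present}")
        for name in ("gamma_decay", "delta_ggg_true", "sensitivity_amplitude",
                     "noise_sd_log", "optical_o"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.saturation_m <= 0:
            raise ValidationError("saturation_m must be > 0")
        if self.saturation_m <= self.optical_o:
            raise ValidationError("saturation_m must exceed optical_o")
        for name in ("mm_specific_factor", "mm_nonspecific_factor",
                     "ggg_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")

    def replace(self, **overrides: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


@dataclasses.dataclass
class ChipLayout:
    """Array geometry shared by all samples of a cohort: ids, probe order and
    sequences; intensities are not part of the layout."""

    probe_id: np.ndarray
    probeset_id: np.ndarray
    probe_index: np.ndarray
    codes: np.ndarray  # (n_probes, 25) uint8
    n_sets: int
    probes_per_set: int
    seed: int

    @property
    def n_probes(self) -> int:
        return self.codes.shape[0]

    @property
    def set_codes(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_sets), self.probes_per_set)

    @property
    def normalized_position(self) -> np.ndarray:
        x = (np.arange(self.probes_per_set) /
             max(self.probes_per_set - 1, 1))
        return np.tile(x, self.n_sets)

    @property
    def ggg_start(self) -> np.ndarray:
        """Probes whose positions 1-3 are GGG (forced or by chance)."""
        return (self.codes[:, :3] == _G).all(axis=1)


@dataclasses.dataclass
class GroundTruth:
    """Latent variables of one simulated sample, for recovery tests."""

    present: np.ndarray
    s_set: np.ndarray       # per-set specific strength (0 for absent sets)
    n_set: np.ndarray       # per-set non-specific strength
    delta_a: np.ndarray     # per-probe sequence effect (PM)
    profile: SensitivityProfile
    gamma_decay: float
    delta_ggg_true: float

    @property
    def true_beta(self) -> float:
        """beta = -<log10 N_p> over all sets (Eq 5 applied to the ledger)."""
        return float(-np.mean(np.log10(self.n_set)))

    @property
    def r_set(self) -> np.ndarray:
        return self.s_set / self.n_set

    @property
    def true_lambda(self) -> float | None:
        """lambda = <log10(R+1)> over sets with R > 0.5 (Eq 4 on the
        ledger), or None when no set qualifies."""
        r = self.r_set
        mask = r > 0.5
        if not mask.any():
            return None
        return float(np.mean(np.log10(r[mask] + 1.0)))


def generate_layout(n_sets: int, probes_per_set: int, seed: int,
                    ggg_fraction: float = 0.02) -> ChipLayout:
    """I.i.d. uniform 25-mer probe sequences with a forced fraction of
    GGG-start probes so the guanine-effect groups are populated."""
    if n_sets < 200:
        raise ValidationError(f"n_sets must be >= 200, got {n_sets}")
    if probes_per_set < 3:
        raise ValidationError(
            f"probes_per_set must be >= 3, got {probes_per_set}")
    rng = np.random.default_rng(seed)
    n = n_sets * probes_per_set
    codes = rng.integers(0, 4, size=(n, PROBE_LENGTH), dtype=np.uint8)
    n_force = int(np.ceil(ggg_fraction * n))
    if n_force:
        forced = rng.choice(n, size=n_force, replace=False)
        codes[forced, :3] = _G
    set_num = np.repeat(np.arange(n_sets), probes_per_set)
    idx = np.tile(np.arange(1, probes_per_set + 1), n_sets)
    probeset_id = np.array([f"ps{i:06d}" for i in range(n_sets)],
                           dtype=object)[set_num]
    probe_id = np.array([f"{s}_{j}" for s, j in zip(probeset_id, idx)],
                        dtype=object)
    return ChipLayout(probe_id=probe_id, probeset_id=probeset_id,
                      probe_index=idx.astype(np.int64), codes=codes,
                      n_sets=n_sets, probes_per_set=probes_per_set, seed=seed)


#: log(K_diff) produced per unit of ``sensitivity_amplitude``; amplitude
#: 0.15 gives a typical good hybridization (K_diff ~ 4.5 decades) and 0.10
#: sits exactly at the conservative flagging threshold of 3.
KDIFF_PER_AMPLITUDE = 30.0


def generate_sensitivity_profile(amplitude: float, seed: int,
                                 n_positions: int = N_POSITIONS,
                                 smooth_window: int = 5) -> SensitivityProfile:
    """Random smooth positional NN profile of a prescribed overall strength.

    Shape: coefficients are drawn i.i.d. normal per (position,
    dinucleotide), smoothed along positions, centered per position (zero-sum
    gauge), normalized to a common per-position amplitude, and shaped by a
    Hann (sin^2) envelope that vanishes toward the probe ends — mirroring
    the attenuated positional sensitivity observed near duplex ends, where
    base pairings contribute little binding energy.  In addition each
    dinucleotide's coefficients sum to zero along positions (no dinucleotide
    carries a net whole-probe intensity bias; composition effects belong to
    the intercept), enforced by subtracting an envelope-shaped correction
    that preserves both the per-position zero sums and the end attenuation.

    Scale: the profile is normalized so that its maximum sensitivity
    amplitude log(K_diff) — which is exactly linear in the overall scale —
    equals ``KDIFF_PER_AMPLITUDE * amplitude``.  Hence max |sigma| scales
    exactly linearly with ``amplitude``, and amplitude 0 gives the zero
    profile.
    """
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_positions, 16))
    smooth = uniform_filter1d(raw, size=smooth_window, axis=0, mode="nearest")
    smooth -= smooth.mean(axis=1, keepdims=True)
    smooth /= np.abs(smooth).max(axis=1, keepdims=True)
    envelope = np.sin(np.pi * (np.arange(n_positions) + 0.5) / n_positions) ** 2
    smooth *= envelope[:, None]
    # zero the positional sum of every dinucleotide: subtract c_d * envelope
    # with c_d = colsum_d / sum(envelope); sum_d c_d = 0 because the rows are
    # centered, so the per-position zero sums survive.
    c = smooth.sum(axis=0) / envelope.sum()
    smooth -= envelope[:, None] * c[None, :]
    # project onto the canonical gauge so ground-truth profiles live in the
    # same representative the fit recovers (observable scores unchanged)
    smooth, _ = canonicalize_profile(smooth)
    if amplitude == 0:
        return SensitivityProfile(sigma=np.zeros_like(smooth),
                                  intercept=0.0, n_probes_fit=0)
    shape_kdiff = extremal_sequences(
        SensitivityProfile(sigma=smooth)).log_kdiff
    sigma = smooth * (KDIFF_PER_AMPLITUDE * amplitude / shape_kdiff)
    return SensitivityProfile(sigma=sigma, intercept=0.0, n_probes_fit=0)


def _mm_codes(codes: np.ndarray) -> np.ndarray:
    """MM sequence: PM with the middle base (position 13) complemented."""
    mm = codes.copy()
    mm[:, 12] = 3 - mm[:, 12]
    return mm


def simulate_sample(layout: ChipLayout, profile: SensitivityProfile,
                    config: SimulationConfig,
                    expression: tuple[np.ndarray, np.ndarray] | None = None,
                    biological_sd_log: float = 0.0
                    ) -> tuple[ChipData, GroundTruth]:
    """Draw one hybridized sample from the generative law (module docstring).

    Random draws, in fixed order: per-set present flags, per-set log specific
    strengths, (optional per-set biological jitter,) per-probe PM noise,
    per-probe MM noise.

    ``expression`` optionally supplies shared cohort biology as a
    ``(present, s_log)`` pair that replaces the sample's own draws (the
    internal draws still happen, keeping the random stream aligned);
    ``biological_sd_log`` then adds per-sample normal jitter to the shared
    log specific strengths, emulating biological replicate variation.
    """
    config.validate()
    if layout.probes_per_set != config.probes_per_set or \
            layout.n_sets != config.n_sets:
        raise ValidationError(
            "layout geometry does not match the simulation config")
    rng = np.random.default_rng(config.seed)
    n_sets = layout.n_sets
    present = rng.random(n_sets) < config.f_present
    s_log = rng.normal(config.s_mean_log, config.s_sd_log, n_sets)
    if expression is not None:
        present, s_log = expression
        present = np.asarray(present, dtype=bool).copy()
        s_log = np.asarray(s_log, dtype=float)
        if biological_sd_log > 0:
            s_log = s_log + rng.normal(0.0, biological_sd_log, n_sets)
    s_set = np.where(present, 10.0 ** s_log, 0.0)
    n_set = np.full(n_sets, 10.0 ** (-config.beta_true))

    set_codes = layout.set_codes
    x = layout.normalized_position
    delta_a = profile.delta_a_codes(layout.codes)
    ggg = layout.ggg_start
    g_factor = np.where(ggg, 10.0 ** config.delta_ggg_true, 1.0)

    decay = 10.0 ** (-config.gamma_decay * x)
    b_pm = ((n_set[set_codes] + s_set[set_codes] * decay)
            * 10.0 ** delta_a * g_factor)
    eps_pm = rng.normal(0.0, config.noise_sd_log, layout.n_probes) \
        if config.noise_sd_log > 0 else np.zeros(layout.n_probes)
    pm = (config.optical_o
          + config.saturation_m * b_pm / (1.0 + b_pm) * 10.0 ** eps_pm)

    mm_codes = _mm_codes(layout.codes)
    delta_a_mm = profile.delta_a_codes(mm_codes)
    b_mm = ((n_set[set_codes] * config.mm_nonspecific_factor
             + s_set[set_codes] * config.mm_specific_factor * decay)
            * 10.0 ** delta_a_mm * g_factor)
    eps_mm = rng.normal(0.0, config.noise_sd_log, layout.n_probes) \
        if config.noise_sd_log > 0 else np.zeros(layout.n_probes)
    mm = (config.optical_o
          + config.saturation_m * b_mm / (1.0 + b_mm) * 10.0 ** eps_mm)

    chip = ChipData(
        sample_id=f"sim{config.seed:010d}",
        probe_id=layout.probe_id.copy(),
        probeset_id=layout.probeset_id.copy(),
        probe_index=layout.probe_index.copy(),
        sequence=decode_sequences(layout.codes),
        pm=pm,
        mm=mm,
    )
    truth = GroundTruth(present=present, s_set=s_set, n_set=n_set,
                        delta_a=delta_a, profile=profile,
                        gamma_decay=config.gamma_decay,
                        delta_ggg_true=config.delta_ggg_true)
    return chip, truth


def simulate_chip(config: SimulationConfig, layout_seed: int | None = None,
                  ) -> tuple[ChipData, GroundTruth, ChipLayout]:
    """Convenience wrapper: layout + profile + one sample in a single call.

    ``layout_seed`` (default: ``config.seed``) seeds the layout and the true
    sensitivity profile; ``config.seed`` seeds the sample-level draws.
    """
    if layout_seed is None:
        layout_seed = config.seed
    layout = generate_layout(config.n_sets, config.probes_per_set,
                             layout_seed, config.ggg_fraction)
    profile = generate_sensitivity_profile(config.sensitivity_amplitude,
                                           layout_seed)
    chip, truth = simulate_sample(layout, profile, config)
    return chip, truth, layout


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BatchSpec:
    """One batch of a simulated cohort: a label, a size and the generative
    parameters it overrides relative to the cohort base config."""

    batch_id: str
    n_samples: int
    overrides: dict[str, Any] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class CohortConfig:
    """A multi-batch cohort sharing one layout, one true sensitivity profile
    and (by default) one underlying transcriptome.

    ``shared_expression`` draws the present flags and base log specific
    strengths once for the whole cohort, with per-sample normal jitter of
    ``biological_sd_log`` dex on the specific strengths — replicate-like
    samples, as in a study cohort.  Without it every sample draws an
    independent transcriptome and the expression space has no common
    structure for technical artifacts to confound."""

    base: SimulationConfig
    batches: Sequence[BatchSpec]
    layout_seed: int = 0
    shared_expression: bool = True
    biological_sd_log: float = 0.15

    def validate(self) -> None:
        self.base.validate()
        if len(self.batches) < 2:
            raise ValidationError(
                "cohorts need >= 2 batches for batch analysis")
        ids = [b.batch_id for b in self.batches]
        if len(set(ids)) != len(ids):
            raise ValidationError("batch ids must be unique")
        for b in self.batches:
            if b.n_samples < 1:
                raise ValidationError(
                    f"batch {b.batch_id!r} must have >= 1 sample")
            bad = set(b.overrides) & {"n_sets", "probes_per_set", "seed"}
            if bad:
                raise ValidationError(
                    f"batch {b.batch_id!r} overrides {sorted(bad)}; layout "
                    f"geometry and seeds are cohort-level")
            unknown = set(b.overrides) - {
                f.name for f in dataclasses.fields(SimulationConfig)}
            if unknown:
                raise ValidationError(
                    f"batch {b.batch_id!r}: unknown override(s) "
                    f"{sorted(unknown)}")


def simulate_cohort(cohort: CohortConfig,
                    ) -> tuple[list[ChipData], list[SampleMetadata],
                               list[GroundTruth]]:
    """Simulate a multi-batch cohort on a shared layout and true profile.

    Every batch applies its config overrides (e.g. a different degradation
    strength); metadata carries the batch id as experiment id and a distinct
    scan month per batch, so downstream batch labels separate the batches.
    """
    cohort.validate()
    layout = generate_layout(cohort.base.n_sets, cohort.base.probes_per_set,
                             cohort.layout_seed, cohort.base.ggg_fraction)
    profile = generate_sensitivity_profile(
        cohort.base.sensitivity_amplitude, cohort.layout_seed)
    master = np.random.default_rng(cohort.layout_seed)
    expression = None
    if cohort.shared_expression:
        present = master.random(cohort.base.n_sets) < cohort.base.f_present
        s_log = master.normal(cohort.base.s_mean_log, cohort.base.s_sd_log,
                              cohort.base.n_sets)
        expression = (present, s_log)
    chips: list[ChipData] = []
    metadata: list[SampleMetadata] = []
    truths: list[GroundTruth] = []
    for b_idx, batch in enumerate(cohort.batches):
        year = 2004 + b_idx // 12
        month = 1 + b_idx % 12
        scan_date = _dt.date(year, month, 15)
        for j in range(batch.n_samples):
            seed = int(master.integers(0, _MAX_SEED))
            config = cohort.base.replace(seed=seed, **batch.overrides)
            if config.sensitivity_amplitude != cohort.base.sensitivity_amplitude:
                sample_profile = generate_sensitivity_profile(
                    config.sensitivity_amplitude, cohort.layout_seed)
            else:
                sample_profile = profile
            chip, truth = simulate_sample(
                layout, sample_profile, config, expression=expression,
                biological_sd_log=cohort.biological_sd_log)
            chip.sample_id = f"{batch.batch_id}_s{j:03d}"
            chips.append(chip)
            metadata.append(SampleMetadata(
                sample_id=chip.sample_id,
                experiment_id=batch.batch_id,
                scan_date=scan_date,
            ))
            truths.append(truth)
    return chips, metadata, truths
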