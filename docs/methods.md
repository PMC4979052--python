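# Methods

## Model

A probe's fluorescence intensity is modeled as a Langmuir isotherm on top of
an additive optical background:

    I = O + M · B/(1 + B) · 10^ε,    B = (N + S·10^(−γx)) · 10^(δA) · G

- `O` — optical background (scanner offset plus stray light), intensity units.
- `M` — saturation intensity: the signal of a probe whose binding sites are
  fully occupied.
- `N` — non-specific binding strength of the probe set (dimensionless, on the
  Langmuir scale where B = 1 is half-saturation). `β = −log₁₀ N` is the
  measuring range: the number of decades between the non-specific floor and
  saturation available for specific signal.
- `S` — specific binding strength; `R = S/N` is the signal-to-noise ratio of
  the probe set, and `λ = ⟨log₁₀(R+1)⟩` over expressed sets (R > 0.5) is the
  chip's specific transcript level. The `+1` keeps the average stable as
  R → 0 and makes λ a smooth function of abundance.
- `γ` — degradation decay in decades of specific signal per unit normalized
  probe position `x ∈ [0, 1]`; x = 0 at the 3'-proximal probe of a set, 1 at
  the 5'-most. 3'-IVT labelling starts at the 3' end, so degraded RNA loses
  signal with increasing x. Only the specific mode decays: non-specific
  binding comes from the bulk of fragments and is position-blind.
- `δA(ξ) = Σ_k σ_k(ξ^{k,k+1})` — positional nearest-neighbor sequence effect
  of the 25-mer ξ; σ is a 24 × 16 matrix of decadic-log sensitivities.
- `G` — guanine-run factor: probes beginning with GGG can form G-quadruplex
  structures with enhanced affinity; the simulator multiplies their binding
  strength by `10^(δ_GGG)` *before* saturation, so the observed intensity
  effect attenuates near saturation.
- `ε` — multiplicative log-normal noise (per-probe, independent).

MM probes reuse the PM sequence with position 13 complemented; their binding
strength uses the same set-level N and S scaled by cross-hybridization
factors (defaults 0.8 and 0.2). These conventional values reflect that a
central mismatch suppresses specific duplexes strongly but non-specific
binding barely.

## Estimation pipeline (per sample)

1. **Optical background.** A coarse percentile rule (O₀ = 0.9 × the 0.5th
   intensity percentile) is refined by profile likelihood: for the
   absent-probe pool, `log₁₀(PM − O)` is exactly linear in the dinucleotide
   indicators at the true O, so O is chosen to minimize
   `n/2·ln(SSE(O)/n) + Σ ln(PM − O)` — the second term is the log-Jacobian
   of the log transform, without which the multiplicative noise drives O to
   −∞. The indicator normal matrix does not depend on O, so the 1-D search
   costs one Cholesky factorization plus cheap solves. On simulated chips
   the refined O is unbiased to about one intensity unit, whereas the
   percentile rule overshoots by the Langmuir non-specific floor.
2. **Absent probes.** All probes of the dimmest 30% of probe sets (by
   set-mean log intensity). One pass, no iteration with the decomposition,
   for determinism. The rule requires ≥ 10 probes per free parameter
   (≥ 3850), hence chips of ≥ ~1170 sets at 11 probes/set.
3. **Sensitivity profile.** Ridge-stabilized (1e-6) least squares of
   `log₁₀(PM − O)` on 384 position × dinucleotide indicators plus intercept.
   The chain model is identifiable only up to per-position constants and
   *telescoping* shifts (add f(first base) at position k, subtract f(second
   base) at position k−1 — invisible to every consistent base chain), a
   ~95-dimensional gauge space. Fitted and generated profiles are both
   projected onto the canonical (minimum-norm) representative, which makes
   raw coefficients comparable across chips; all observable scores are
   gauge-invariant anyway.
4. **Extremal sequences.** `log K_diff = δA_max − δA_min` is computed exactly
   over all 4²⁵ sequences by dynamic programming over the base at each
   position (O(L·16)); ties break toward the alphabetically smallest base.
   The optimum is generally *not* a homopolymer, so enumeration of candidate
   homopolymers would underestimate the effect.
5. **Sequence correction.** `I' = max(I − O, O/900) / 10^(δA)`, PM and MM
   each with their own sequence.
6. **Hook curve and chip parameters.** Per-set Δ = ⟨log PM′ − log MM′⟩ vs
   Σ = ⟨½(log PM′ + log MM′)⟩, smoothed on sliding windows of
   max(50, n/40) sets with half-window steps (the step shrinks if needed so
   at least 10 windows exist). The non-specific Δ level is taken from the
   dimmest decile; the break point is the first window whose smoothed Δ
   exceeds that level by max(0.1, 3 SD) for 3 consecutive windows. Sets left
   of the break are absent. M = 1.2 × the largest set-mean intensity on
   *optically corrected but not sequence-corrected* values — saturated
   probes are no longer sequence-modulated, and dividing them by 10^δA would
   inflate M. `n = m_ns/(M − m_ns)` from the mean absent-set intensity, and
   β = −log₁₀ n. M estimation needs at least a few near-saturated sets; on
   a chip with nothing expressed the M rule degenerates (a warning fires).
   PM-only chips use a documented lower-fidelity fallback (absent sets from
   the log-intensity distribution's lowest decile + 3 SD rule).
7. **Langmuir inversion.** `S = (y(1+n) − Mn)/(M − y)` per set and per
   probe, exact without noise; negative values clip to 0 and intensities
   clip at 0.995 M before inversion (sequence-corrected values of saturated
   probes can exceed the M estimate and would flip the denominator).
8. **Degradation index.** Pooled OLS of `log₁₀(s_i/⟨s⟩_set)` on x over
   expressed sets with ≥ 4 probes (≥ 50 sets required, else undefined);
   probes with non-positive inverted s carry no usable signal and are
   dropped. `d = min(1, 10^(−γ̂))`. This is an operational surrogate for the
   established degradation index whose exact algorithm is not public; it
   preserves the scale anchors d = 1 (no decay) and d ≈ 0.45 at γ ≈ 0.35.
9. **Guanine effect.** Mean `log₁₀(I − O)` of GGG-start probes minus probes
   containing TTT anywhere (disjoint groups; ≥ 50 probes each). Computed on
   optically corrected but **not** sequence-corrected intensities — the
   fitted profile would partly absorb the very effect being measured.
10. **Flags.** d < 0.45, λ < 0.95, β < 1.8, log K_diff < 3, δI(GGG)₁ > 0.25;
    an undefined metric never flags. All thresholds are overridable.

## Batch impact

Batch labels combine experiment id with the hybridization month
(`E1·2004-03`), the standard surrogate when no richer metadata exists.
Covariation of a metric with batches is the adjusted R² of a one-way
fixed-effects OLS fit (statsmodels); "generalized R²" variants reduce to
this for a single categorical factor. A constant metric is reported as
R² = 0. Impact on expression is the Pearson correlation of the metric with
each of the first five principal components (features centered across
samples; each component's loading vector is oriented so its
largest-magnitude entry is positive, making signs reproducible). Undefined
metric values are pairwise-deleted. Prevalence tables report the flagged
fraction per stratum of the metadata's qc label, with undefined metrics
tallied separately.

## The simulator and what it does (not) emulate

Defaults (`SimulationConfig`): 2000 sets × 11 probes, f_present = 0.3,
β = 2.25, log₁₀ S ~ N(−1, 0.7), M = 10⁴, O = 50, noise 0.05 dex,
sensitivity amplitude 0.15, 2% forced GGG-start probes. These reproduce the
intensity regime of a good HG-U133-class hybridization: non-specific floor
~56 units above background, ~30% present calls, λ ≈ 1.2–1.4, β ≈ 2.25,
log K_diff ≈ 4.5.

Generated sensitivity profiles are smoothed along positions, carry a Hann
(sin²) positional envelope — real profiles show attenuated sensitivity near
the duplex ends, and the envelope also keeps the fixed GGG-start positions
from leaking into δI(GGG)₁ — have zero per-position sums (the fit's gauge),
near-zero per-dinucleotide positional sums (no dinucleotide carries a net
whole-probe bias, keeping the TTT baseline sequence-neutral), and are scaled
so the profile's own log K_diff equals 30 × amplitude exactly (log K_diff is
linear in the scale). Hence amplitude 0.10 sits exactly at the flagging
threshold and 0.15 is a typical good chip.

Cohorts share one layout, one true profile and (by default) one underlying
transcriptome with 0.15 dex per-sample biological jitter — replicate-like
samples, as in a real study group. Without shared biology the expression
space has no common structure for technical artifacts to confound, and
batch effects cannot imprint on principal components by construction.

Not modeled: spatial surface artifacts, washing/target-depletion kinetics,
bulk dimerization at very high RNA mass (the "up-down" saturation of λ),
scanner saturation, and per-set variation of the non-specific level
(sequence correction removes most of it; the chip-wide N is what β averages
anyway). Passing recovery tests on this generator therefore demonstrates
the estimators' correctness under Langmuir physics with sequence and
degradation structure — not robustness to spatial defects or exotic
protocol failures.

## Numerical choices and degenerate inputs

- Decadic logarithms throughout ("orders of magnitude" scale).
- Probe tables are plain TSV with 17-significant-digit intensities; a
  write/read roundtrip is bit-exact (numeric parsing goes through numpy's
  correctly-rounded parser).
- Chips need ≥ 200 sets with ≥ 3 probes for any chip-level estimation;
  smaller inputs are refused with explicit messages, and validation errors
  name the offending row or column.
- A sample that fails inside the CLI `qc` run yields an all-NA report row
  and a warning instead of aborting the cohort (large-cohort practice).
- Recovery bounds quoted in the tests are asserted on means over 10
  seed-swept replicates; per-seed spreads are wider (e.g. d at γ = 0 can
  reach 0.966 on one seed purely through estimation noise at 5% intensity
  noise).
- The test and acceptance suites use 2000-set chips for single-sample
  recovery and 1200-set chips (the smallest geometry keeping the
  absent-probe pool identifiable) with 2 × 20-sample cohorts for the batch
  analyses.

## Known limitations

- β carries a small positive bias (~+0.05) from the 1.2 margin in the M
  rule interacting with the break-point selection; it is well inside the
  ±0.15 recovery band and constant across the conditions studied.
- The degradation surrogate's d ↔ RIN correspondence (0.45 ↔ RIN 7) is
  inherited as a convention; it cannot be validated without wet-lab RIN
  measurements.
- δI(GGG)₁ measured on real chips mixes the quadruplex effect with whatever
  residual sequence preference the NN profile assigns to the fixed GGG-start
  positions; on simulated chips this leakage is kept below ~0.02 by the
  generator's envelope, but on real data the metric should be read as the
  combined effect.
- PM-only β/λ estimates are lower fidelity than the hook-based ones (no
  Δ-based break point); tests hold them to looser tolerances.
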