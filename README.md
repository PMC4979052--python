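# hookqc

Hybridization-model based quality control for 3'-expression microarrays
(GeneChip-type arrays with PM/MM probe pairs), plus diagnostics for
quality-driven batch effects.

## The problem

Large microarray compendia mix samples hybridized in different labs, months
and protocols. Variation in RNA quality and RNA quantity does not merely
lower per-sample data quality — it covaries with those technical batches and
imprints itself on the leading axes of the expression space, where it can
masquerade as biology. `hookqc` computes per-sample, probe-level metrics that
are *specific* to the underlying physical artifact (unlike generic quality
scores), flags affected samples, and quantifies how strongly each metric
covaries with batches and with the principal components of an expression
matrix.

It is aimed at anyone curating or re-analyzing probe-level expression-array
cohorts, and at method developers who need a fully specified synthetic chip
generator with known ground truth.

## The model

Probe intensities follow a Langmuir surface-hybridization isotherm. For probe
*i* of probe set *p*:

    I_i = O + M · B_i / (1 + B_i),        B_i = (N_p + S_p) · 10^{δA(ξ_i)}

with optical background *O*, saturation intensity *M*, non-specific binding
strength *N_p*, specific strength *S_p*, and a sequence effect δA given by a
positional nearest-neighbor model over the 25-mer probe sequence ξ:

    δA(ξ) = Σ_{k=1..24} σ_k(ξ^{k,k+1})        (24 positions × 16 dinucleotides)

σ is fitted by least squares from the dimmest ("absent") probe sets, which
carry only non-specific signal. From this machinery the package derives five
per-sample metrics:

| metric | definition | artifact | flag threshold |
|---|---|---|---|
| d | 10^(−γ̂), γ̂ the pooled 3'→5' decay slope of per-probe specific signal | RNA degradation | d < 0.45 (≈ RIN 7) |
| λ | ⟨log₁₀(R+1)⟩ over sets with R = S/N > 0.5 | low specific RNA amount | λ < 0.95 |
| β | −log₁₀ N, the measuring range (hook-curve width) | high non-specific background | β < 1.8 |
| log K_diff | δA_max − δA_min over all 4²⁵ sequences (exact DP) | weak sequence response | log K_diff < 3 |
| δI(GGG)₁ | mean log₁₀ intensity excess of GGG-start probes over TTT-containing probes | G-quadruplex bias | δI > 0.25 |

For PM/MM chips the specific/non-specific decomposition uses the hook
construction: per-set Δ = ⟨log PM′ − log MM′⟩ against Σ = ⟨½(log PM′ + log
MM′)⟩ traces a hook-shaped curve whose flat left branch locates the absent
sets and whose width is β. Batch impact is assessed with a one-way
fixed-effects fit (adjusted R² of metric vs. batch = experiment id ×
hybridization month) and Pearson correlations with the first five principal
components of an expression matrix.

No real chip data is required: `hookqc.simulate` generates probe tables from
the same Langmuir law with configurable degradation, guanine bias, sequence
effect, saturation, background, noise and batch structure, and reports the
full latent ground truth.

## Worked example

```python
import hookqc as hq

config = hq.SimulationConfig(seed=11, gamma_decay=0.6)   # degraded RNA
chip, truth, _ = hq.simulate_chip(config)
metrics = hq.compute_qc(chip)
```

Running `python examples/02_quality_metrics.py` prints, for the intact and
the degraded version of the same sample:

```
--- intact RNA (true decay gamma = 0.0) ---
  d index      = 1.000   (1 = no decay; < 0.45 ~ RIN < 7; truth 10^-gamma = 1.000)
  lambda       = 1.337   (true 1.366)
  beta         = 2.317   (true 2.250)
  log K_diff   = 4.457
  flags        = none
--- degraded RNA (true decay gamma = 0.6) ---
  d index      = 0.257   (truth 10^-gamma = 0.251)
  lambda       = 1.130   (true 1.366)
  flags        = ['LOW_RNA_QUALITY']
```

The pipeline, working only from intensities, recovers the planted decay
(d ≈ 0.26 vs. truth 0.25), sees the apparent specific level drop with
degradation, and flags the sample. `examples/04_batch_confounding.py` builds
a two-batch cohort whose batch B is degraded and prints the confounding
signature (adjusted R² of d vs. batch ≈ 1.0, r(d, PC1) ≈ 0.97): quality
variation has become the dominant axis of the expression space.

A thin CLI wraps the same pipeline for shell use:

```bash
hookqc simulate --config cohort.txt --seed 5 --out sim/
hookqc qc --in 'sim/*.probes.tsv' --out qc/
hookqc batch --qc qc/qc_report.tsv --metadata sim/metadata.tsv --out impact/
```

## Layout

- `src/hookqc/io.py` — probe tables, metadata, expression matrices, QC
  reports (all plain TSV)
- `src/hookqc/simulate.py` — the Langmuir chip and cohort simulator
- `src/hookqc/sequence.py` — positional NN sensitivity model and exact
  extremal-sequence DP
- `src/hookqc/hook.py` — optical background, sequence correction, hook
  curve, Langmuir decomposition
- `src/hookqc/metrics.py` — the five metrics, thresholds and flags
- `src/hookqc/batch.py` — batch labels, PCA scores, correlations, adjusted
  R², prevalence tables
- `src/hookqc/cli.py` — the `hookqc` command
- `docs/methods.md` — model, estimation procedures, parameter choices and
  limitations
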