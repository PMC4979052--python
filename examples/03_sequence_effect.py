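"""Fit the positional NN sequence model and compute its extremal sequences.

The sensitivity profile sigma (24 positions x 16 dinucleotides) is fitted
from the dimmest 30% of probe sets — probes carrying only non-specific
signal — and the exact dynamic program finds the brightest and dimmest
possible 25-mers under that profile.  Their score difference, log(K_diff),
is the total strength of the chip's sequence effect in decades of intensity.
"""

import hookqc as hq

chip, truth, _ = hq.simulate_chip(hq.SimulationConfig(seed=4))

o = hq.refine_optical_background(
    chip, hq.select_absent_probes(chip), hq.estimate_optical_background(chip))
profile = hq.fit_sensitivity_profile(
    chip, hq.select_absent_probes(chip), background=o)
result = hq.extremal_sequences(profile)

true_result = hq.extremal_sequences(truth.profile)
print(f"fitted on {profile.n_probes_fit} absent probes "
      f"(background O = {o:.1f})")
print(f"brightest sequence: {result.max_sequence}  dA = "
      f"{result.delta_a_max:+.2f}")
print(f"dimmest sequence:   {result.min_sequence}  dA = "
      f"{result.delta_a_min:+.2f}")
print(f"log K_diff = {result.log_kdiff:.2f}   "
      f"(truth {true_result.log_kdiff:.2f}; threshold 3.0)")
# Two hypothetical probes against the same transcript could differ by
# ~10^4.5 in intensity purely through their sequence; values below ~3
# indicate an atypically weak (suspicious) sequence response.
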