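"""The Wiener diffusion primitives: density, choice probability, simulation.

A two-choice decision is a noisy evidence accumulation between boundaries
0 (error) and a (correct).  This script evaluates the first-passage density,
compares the closed-form choice probability with simulated accuracy, and
shows how error responses carry a longer non-decision time.
"""

import numpy as np

from diffstab import DDMParameters, choice_probability, simulate_trials, wfpt_density

# a typical IAT-like parameter set: strong drift, moderate caution
params = DDMParameters(
    drift=2.0, boundary_separation=2.0,
    ndt_correct=0.43, ndt_error=0.73,  # errors include response correction
)

p_correct = choice_probability(params, "upper")
print(f"closed-form P(correct)            : {p_correct:.4f}")

rng = np.random.default_rng(0)
rt, correct = simulate_trials(params, 50_000, rng)
print(f"simulated accuracy (50k trials)   : {correct.mean():.4f}")
print(f"mean correct RT                   : {rt[correct].mean():.3f} s")
print(f"mean error RT                     : {rt[~correct].mean():.3f} s")
print("errors are slower: their non-decision time absorbs the correction.")

t = np.array([0.3, 0.5, 1.0, 2.0])
dens = wfpt_density(t, "upper", DDMParameters(2.0, 2.0))
print("upper-boundary density at t =", t, ":", np.round(dens, 4))
print("(1/s units; integrates over t to the choice probability above)")
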