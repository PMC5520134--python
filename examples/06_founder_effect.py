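"""Founder-effect F_ST: analytic expectation vs forward simulation.

A single-generation bottleneck of N diploid founders is expected to leave
F_ST ≈ 1 - (1 - 1/(2N))^t between source and daughter, plus 1/(2S) per
finite sample of S diploids.  The forward Wright-Fisher generator
reproduces that expectation.
"""

import numpy as np

from fallowpop import founder_fst_expectation

rng = np.random.default_rng(6)
for n_founders in (7, 20, 100):
    exp_full = founder_fst_expectation(n_founders, 1)
    exp_drift = founder_fst_expectation(n_founders, 1, None)
    # forward cross-check: binomial founder draw + binomial sampling
    reps, S = 30_000, 150
    p = rng.uniform(0.2, 0.8, reps)
    pd = rng.binomial(2 * n_founders, p) / (2 * n_founders)
    x = rng.binomial(2 * S, p) / (2 * S)
    y = rng.binomial(2 * S, pd) / (2 * S)
    z = (x + y) / 2
    ok = (z > 0) & (z < 1)
    sim = float((((x - y) ** 2) / (z - x * y))[ok].mean())
    print(f"N={n_founders:4d}: drift-only {exp_drift:.4f}, with sampling "
          f"{exp_full:.4f}, forward simulation {sim:.4f}")

print("\nAt N=7 the expectation is ~0.078 — of the order observed between "
      "recently founded ungulate herds; repeated or prolonged bottlenecks "
      "push F_ST far higher.")
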