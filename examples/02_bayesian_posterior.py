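"""Bayesian estimation of the Hurst index by Metropolis-Hastings.

Runs the posterior sampler on one simulated path under three priors:
uniform on the matching half-space, a beta-type prior on the same
half-space, and a Beta(3, 3) prior on the full interval (0, 1).
"""

import numpy as np

import hurstlab as hl
from hurstlab import MHConfig, PriorSpec

H_TRUE = 0.45
path = hl.simulate_fbm(H_TRUE, 256, np.random.default_rng(7))

priors = [
    PriorSpec("uniform_short"),
    PriorSpec("beta_short", a=3.0, b=3.0),
    PriorSpec("beta_full", a=3.0, b=3.0),
]
for prior in priors:
    sd = 0.25 if prior.family.endswith("full") else 0.125
    cfg = MHConfig(n_keep=2000, burn_in=500, proposal_sd=sd, seed=11)
    post = hl.run_posterior(path, prior, cfg, N=100)
    s = post.summary()
    print(
        f"{prior.family:14s}  mean={s['H_hat']:.4f}  sd={s['posterior_sd']:.4f}  "
        f"95% CI=({s['q2.5']:.4f}, {s['q97.5']:.4f})  "
        f"accept={s['acceptance_rate']:.2f}"
    )
print(f"true H = {H_TRUE}")
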