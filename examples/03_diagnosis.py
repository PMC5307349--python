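"""Screen a sample path for membership in the fBm class.

The five-step screen checks increment stationarity (KPSS), increment
normality (Jarque-Bera), an ergodicity functional, monotonicity of
p-variations across dyadic levels, and the growth rate of the number of
distinct visited sites.  It is applied to a genuine fBm path and to a
continuous-time random walk with heavy-tailed waiting times, which
shares the self-similarity exponent but not the fBm law.  The screen has
a nominal family-wise false-rejection rate of about 5%, so a genuine fBm
path occasionally fails one step.
"""

import numpy as np

import hurstlab as hl

m = 512

fbm = hl.simulate_fbm(0.3, m, np.random.default_rng(0))
H0 = hl.incremental_ml(fbm, hl.ParameterSpace.SHORT).H_hat
rep = hl.diagnose(fbm, H0)
print(f"fBm path (H=0.3):   verdict = {rep.verdict}")

ctrw = hl.simulate_ctrw_fixture(0.7, m, seed=2)
H0 = float(np.clip(hl.discrete_variations_baseline(ctrw), 0.05, 0.95))
rep = hl.diagnose(ctrw, H0)
print(f"CTRW path (a=0.7):  verdict = {rep.verdict}")
d = rep.to_dict()
print("  steps:", {k: (d[k]["passed"] if d[k] else None)
                   for k in ("kpss", "jarque_bera", "ergodicity",
                             "p_variation", "filling_ratio")})
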