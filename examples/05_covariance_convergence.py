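"""Convergence of the series approximation to the exact fBm covariance.

The covariance of fBm is approximated by a finite sum of N
Ornstein-Uhlenbeck-type terms plus a high-frequency band.  This script
prints the sup-norm error on a 20-point grid as N grows, for one H in
each regime.
"""

import numpy as np

import hurstlab as hl

t = np.linspace(0.05, 1.0, 20)
tt, ss = t[:, None], t[None, :]

print(f"{'N':>5} " + "".join(f"  H={H:<4}" for H in (0.1, 0.3, 0.7, 0.9)))
for N in (10, 25, 50, 100, 200):
    errs = []
    for H in (0.1, 0.3, 0.7, 0.9):
        cfg = hl.DecompositionConfig(H=H, N=N)
        err = np.max(np.abs(hl.approx_cov(tt, ss, cfg) - hl.exact_cov(tt, ss, H)))
        errs.append(err)
    print(f"{N:>5} " + "".join(f"  {e:.1e}" for e in errs))
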