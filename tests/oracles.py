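"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's solver code paths: the capillary
oxygen-exchange ODE is integrated by fixed-step forward Euler on the raw
saturation variable, and the oxygen dissociation curve is inverted by
bisection on the closed form.
"""

import numpy as np


def euler_oef(dc, cbf, hb, p50, h=2.8, phi=1.34, inlet=0.95, pm=0.0,
              n_steps=100_000):
    """Fixed-step Euler solution of the capillary oxygen-loss ODE.

    Accepts scalars or equal-length arrays of (dc, cbf); returns the
    oxygen extraction fraction(s).
    """
    dc = np.atleast_1d(np.asarray(dc, dtype=float))
    cbf = np.atleast_1d(np.asarray(cbf, dtype=float))
    gamma = dc * p50 / (cbf * phi * hb)
    u = np.full(gamma.shape, float(inlet))
    dx = 1.0 / n_steps
    floor = 1e-12
    for _ in range(n_steps):
        ue = np.clip(u, floor, 1.0 - 1e-12)
        u = u - dx * gamma * ((ue / (1.0 - ue)) ** (1.0 / h) - pm / p50)
        u = np.maximum(u, floor)
    oef = (inlet - u) / inlet
    return oef if oef.size > 1 else float(oef[0])


def severinghaus_p_for_s(target_s, lo=1e-6, hi=5000.0, n_iter=200):
    """Bisection inverse of S = (23400/(P^3 + 150 P) + 1)^-1."""
    def s_of(p):
        return 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if s_of(mid) < target_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
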