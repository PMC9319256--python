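"""Independent brute-force oracles shared by test modules.

These deliberately avoid the analytic paths they check: equilibria are
solved by 1-D bisection on the mass-action equation instead of the closed
quadratic form.
"""

import numpy as np
from scipy.optimize import bisect

from bindlab import itc


def make_exp(heats=None, n_inj=20, dv=2.0, cell=10.0, syringe=100.0, v0=200.0):
    if heats is None:
        heats = np.zeros(n_inj)
    return itc.ITCExperiment(cell, syringe, v0, np.full(len(heats), dv), np.asarray(heats))


def bisection_bound(kd, s, n):
    """Solve (S - x)(N - x) = Kd x for the complex concentration x."""
    if s == 0 or n == 0:
        return 0.0
    return bisect(lambda x: (s - x) * (n - x) - kd * x, 0.0, min(s, n), xtol=1e-15)


def brute_force_heats(ka, dh, n, q_bg, exp):
    """Per-injection heats with the displacement bookkeeping done stepwise and
    each equilibrium solved by bisection."""
    kd = 1e6 / ka
    v0 = exp.cell_volume
    m, l = exp.cell_conc, 0.0
    pl_prev, heats = 0.0, []
    for dv in exp.injection_volumes:
        f = 1.0 - dv / v0
        m *= f
        l = l * f + exp.syringe_conc * dv / v0
        pl = bisection_bound(kd, l, n * m)
        heats.append(dh * v0 * (pl - pl_prev * f) * 1e-3 + q_bg)
        pl_prev = pl
    return np.array(heats)
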