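"""Mean-effect sensitivity curves through an emulator.

Computes ybar(theta_i) = (1/N) sum_j Y(lambda_j, theta_i) for every
parameter of the 8-dimensional ionic-parameter space against an analytic
stand-in emulator, reusing one Latin-hypercube lambda sample across all
curves.  With the package's trained partitioned emulator the call is the
same, plus `output="dominant_frequency"` (or any biomarker).
"""

import numpy as np

from rotoremu import ParameterSpace, base_lambda_sample, mean_effect

space = ParameterSpace.multi_param()
lo, hi = np.asarray(space.low), np.asarray(space.high)


def emulator_stub(X):
    """Analytic response: depends on g_fi strongly, tau_w_minus mildly."""
    U = (np.asarray(X) - lo) / (hi - lo)
    return 4.0 + 3.0 * np.sin(2.5 * U[:, 0]) + 0.5 * U[:, 7]


N = 20_000
lam = base_lambda_sample(space, N, seed=0)
total = 0
for i, name in enumerate(space.names):
    curve = mean_effect(emulator_stub, space, i, n_grid=100, N=N, seed=0,
                        base_sample=lam)
    total += curve.n_evaluations
    swing = np.nanmax(curve.effect) - np.nanmin(curve.effect)
    print(f"{name:<14} mean-effect swing: {swing:.3f}")
print(f"\nemulator evaluations performed: {total:,}")
print()
print("The swing of each curve measures that parameter's main effect on")
print("the output while all others vary over their full ranges: g_fi")
print("dominates here by construction, tau_w_minus contributes ~0.5, and")
print("the remaining curves are flat to Monte-Carlo noise.")
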