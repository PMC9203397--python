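"""Independent brute-force oracles used by the test suite.

Kept free of any call into the code paths they check.
"""

import numpy as np


def pinball(residual, tau):
    r = np.asarray(residual, dtype=float)
    return np.where(r >= 0, r * tau, r * (tau - 1.0))


def brute_force_quantile_min(x, y, tau):
    """Minimum pinball loss over all lines through two data points.

    An optimal solution of the quantile-regression LP interpolates two
    data points, so enumerating all C(n, 2) candidate lines (plus the
    horizontal lines through each single point, harmless extras) yields
    the global optimum for small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = np.inf
    n = x.size
    for i in range(n):
        # horizontal line through point i
        best = min(best, float(np.sum(pinball(y - y[i], tau))))
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            intercept = y[i] - slope * x[i]
            loss = float(np.sum(pinball(y - (intercept + slope * x), tau)))
            best = min(best, loss)
    return best
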