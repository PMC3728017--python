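"""Independent oracles used by the test suite.

The fixed-point oracle never calls the package's root finder: for n = 1 the
x-nullcline condition beta1 + b * (x/(x+ka)) * R - x = 0 (R constant in x)
reduces to the quadratic x^2 - (beta1 - ka + b*R) x - beta1*ka = 0, whose
unique positive root is closed-form.  Scanning the y-nullcline residual along
that curve and bisecting sign changes enumerates all fixed points.
"""

import numpy as np
from scipy.optimize import brentq


def x_nullcline(y, p):
    """Unique x >= 0 with dx/dt = 0 at the given y (requires n == 1)."""
    R = p.k_cross_x / (np.asarray(y, dtype=float) + p.k_cross_x)
    B = p.beta1 - p.k_auto_x + p.b * R
    return 0.5 * (B + np.sqrt(B ** 2 + 4.0 * p.beta1 * p.k_auto_x))


def _y_residual(y, p):
    x = x_nullcline(y, p)
    return (p.beta2 + p.b * (y / (y + p.k_auto_y))
            * (p.k_cross_y / (x + p.k_cross_y)) - y)


def nullcline_roots(p, n_scan=2000):
    """All fixed points (x, y) of the n=1 motif via 1-D nullcline scanning."""
    assert p.n == 1.0 and p.beta1 > 0
    hi = max(p.beta1, p.beta2) + p.b + 0.5
    ys = np.concatenate([[0.0], np.geomspace(1e-9, hi, n_scan)])
    res = _y_residual(ys, p)
    roots = []
    for i in range(len(ys) - 1):
        if res[i] == 0.0:
            roots.append(ys[i])
        elif res[i] * res[i + 1] < 0:
            roots.append(brentq(lambda v: _y_residual(v, p), ys[i], ys[i + 1],
                                xtol=1e-14))
    if res[-1] == 0.0:
        roots.append(ys[-1])
    pts = sorted((float(x_nullcline(y, p)), float(y)) for y in roots)
    out = []
    for r in pts:
        if not any(np.hypot(r[0] - q[0], r[1] - q[1]) < 1e-6 * (1 + np.hypot(*q))
                   for q in out):
            out.append(r)
    return out


def mi_2x2(n00, n01, n10, n11):
    """Plug-in mutual information in bits from a 2x2 contingency table."""
    tab = np.array([[n00, n01], [n10, n11]], dtype=float)
    tab /= tab.sum()
    pa, pb = tab.sum(axis=1), tab.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if tab[i, j] > 0:
                mi += tab[i, j] * np.log2(tab[i, j] / (pa[i] * pb[j]))
    return mi
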