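"""Independent numeric oracles used by the test suite.

These deliberately avoid the closed-form expressions they are checking.
"""

import math

import numpy as np


def golden_section_slope(points, bracket=(-1e3, 1e3), tol=1e-6):
    """Minimize SSE(m) = sum (y - m x)^2 numerically.

    Golden-section search narrows the bracket to ``tol``; because the
    objective is exactly quadratic in m, a final parabola-vertex step from
    three sampled values then pins the minimizer to ~1e-12 without using
    the closed-form slope expression.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)

    def sse(m):
        return math.fsum((yi - m * xi) ** 2 for xi, yi in zip(x, y))

    phi = (math.sqrt(5) - 1) / 2
    a, b = bracket
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = sse(c), sse(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = sse(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = sse(d)
    m0 = (a + b) / 2
    h = max(tol, 1e-6)
    f_minus, f0, f_plus = sse(m0 - h), sse(m0), sse(m0 + h)
    denom = f_plus - 2 * f0 + f_minus
    if denom == 0.0:  # flat objective (all x ~ 0 in the bracket)
        return m0
    return m0 - 0.5 * h * (f_plus - f_minus) / denom
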