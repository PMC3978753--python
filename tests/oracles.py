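"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written from first principles (explicit sum formulas, density
integration) without reusing any code path from the package or the same
scipy.stats routines it calls.
"""

import math

from scipy.integrate import quad


def pearson_brute_force(x, y):
    """Pearson r and two-tailed p from explicit sums and t-density quadrature."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    nu = n - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = abs(r) * math.sqrt(nu / (1.0 - r * r))

    def t_pdf(u):
        c = math.gamma((nu + 1) / 2.0) / (math.sqrt(nu * math.pi)
                                          * math.gamma(nu / 2.0))
        return c * (1.0 + u * u / nu) ** (-(nu + 1) / 2.0)

    tail, _ = quad(t_pdf, t, math.inf)
    return r, 2.0 * tail
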