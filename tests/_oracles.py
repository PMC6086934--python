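"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln


def posterior_tail_by_quadrature(k, n, a=1.5, b=2.0, f=0.2):
    """Numerically integrate the Beta(a+k, b+n−k) density above f, with a
    log-scaled integrand so large shape parameters stay in range.  Serves
    as the independent check of the closed-form posterior tail."""
    aa, bb = a + k, b + n - k
    lognorm = betaln(aa, bb)

    def dens(t):
        return np.exp((aa - 1) * np.log(t) + (bb - 1) * np.log1p(-t) - lognorm)

    mode = (aa - 1) / (aa + bb - 2) if aa + bb > 2 else 0.5
    points = [p for p in (f, mode) if 0 < p < 1]
    val, _ = quad(dens, f, 1, points=[p for p in points if p > f], limit=200)
    return val
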