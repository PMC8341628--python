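"""Independent brute-force oracle for elliptic Fourier coefficients.

Integrates the Fourier projection integrals of the piecewise-linear
outline directly, edge by edge, with fixed-order Gauss-Legendre
quadrature (exact to machine precision for these smooth integrands at
polygon edge lengths far below the wavelength). Shares no code with
the closed-form implementation it checks.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss


def oracle_efd(poly: np.ndarray, n_harmonics: int, order: int = 12) -> np.ndarray:
    """(n_harmonics, 4) array of (a_n, b_n, c_n, d_n) by numeric integration.

    Edges are subdivided until every quadrature panel is short against
    the shortest harmonic wavelength, keeping fixed-order quadrature at
    machine accuracy.
    """
    closed = np.vstack([poly, poly[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt, starts = d[keep], dt[keep], closed[:-1][keep]
    t0 = np.concatenate([[0.0], np.cumsum(dt)])
    T = t0[-1]
    max_panel = T / (8.0 * n_harmonics)
    xg, wg = leggauss(order)
    res = np.zeros((n_harmonics, 4))
    for i in range(len(dt)):
        n_sub = max(1, int(np.ceil(dt[i] / max_panel)))
        for j in range(n_sub):
            lo = t0[i] + dt[i] * j / n_sub
            h = dt[i] / n_sub
            s = lo + (xg + 1.0) / 2.0 * h
            w = wg * h / 2.0
            frac = (s - t0[i]) / dt[i]
            x = starts[i, 0] + d[i, 0] * frac
            y = starts[i, 1] + d[i, 1] * frac
            for n in range(1, n_harmonics + 1):
                cn = np.cos(2 * np.pi * n * s / T)
                sn = np.sin(2 * np.pi * n * s / T)
                res[n - 1, 0] += (2.0 / T) * np.sum(w * x * cn)
                res[n - 1, 1] += (2.0 / T) * np.sum(w * x * sn)
                res[n - 1, 2] += (2.0 / T) * np.sum(w * y * cn)
                res[n - 1, 3] += (2.0 / T) * np.sum(w * y * sn)
    return res
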