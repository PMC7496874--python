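"""Clenshaw-Curtis spectral quadrature on Chebyshev-Lobatto nodes.

Static N-point operators used by the life-history integrator: values of a
smooth function at the nodes map linearly to Chebyshev coefficients (for
convergence monitoring) and to cumulative integrals along the panel.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import chebyshev as C

N = 40

# increasing nodes on [-1, 1]
_j = np.arange(N)
_theta = np.pi * _j / (N - 1)
NODES = -np.cos(_theta)

# values (at increasing nodes) -> Chebyshev coefficients, via the DCT-I
# with the half-weight ('double prime') convention on first/last terms
_dct = np.cos(np.outer(np.arange(N), _theta))  # [k, j] = cos(k theta_j)
_w = np.full(N, 2.0 / (N - 1))
_w[0] = _w[-1] = 1.0 / (N - 1)
# f(cos theta_j) corresponds to decreasing node order; flip to increasing
VAL2COEF = (_dct * _w)[:, ::-1].copy()
VAL2COEF[0] *= 0.5
VAL2COEF[-1] *= 0.5

# cumulative integral operator: (CUMINT @ values)[j] = int_{-1}^{x_j} f
CUMINT = np.empty((N, N))
for _k in range(N):
    _e = np.zeros(N)
    _e[_k] = 1.0
    _c = VAL2COEF @ _e
    _ci = C.chebint(_c, lbnd=-1.0)
    CUMINT[:, _k] = C.chebval(NODES, _ci)
del _k, _e, _c, _ci


def coef_tail(values: np.ndarray) -> float:
    """Relative size of the trailing Chebyshev coefficients.

    Small values certify spectral convergence of the interpolant (and
    hence of the quadrature) on the panel.
    """
    c = VAL2COEF @ values
    scale = np.max(np.abs(c))
    if scale == 0.0 or not np.isfinite(scale):
        return 0.0 if scale == 0.0 else np.inf
    return float(np.max(np.abs(c[-3:])) / scale)
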