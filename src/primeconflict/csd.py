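"""Spherical-spline surface Laplacian (current source density).

Scalp potentials are interpolated with spherical splines and the surface
Laplacian of the interpolant is evaluated at the electrodes.  The spline
basis functions are Legendre series

    g(x) = (1 / 4pi) * sum_n  (2n + 1) / (n (n + 1))^m      * P_n(x)
    h(x) = (1 / 4pi) * sum_n  (2n + 1) / (n (n + 1))^(m-1)  * P_n(x)

with x the cosine of the inter-electrode angle, ``m`` the spline stiffness
and the sum truncated at ``n_legendre`` terms.  Spline coefficients are
obtained from the regularized system (G + lambda I) c + d 1 = v subject to
sum(c) = 0; the CSD at electrode i is sum_j c_j h(cos theta_ij) / r^2.

Because the transform is linear, it is precomputed once per montage as an
n x n matrix and applied to every sample.  Adding a constant to all channels
leaves the output unchanged (reference freedom), and a spatially constant
topography maps to zero.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

__all__ = ["spline_gh", "csd_transform_matrix"]


def _legendre_series(x, weights):
    coeffs = np.zeros(len(weights) + 1)
    coeffs[1:] = weights
    return legendre.legval(x, coeffs)


def spline_gh(cosang, m=4, n_legendre=50):
    """Evaluate the g and h spline kernels at an array of angle cosines."""
    n = np.arange(1, n_legendre + 1, dtype=float)
    base = (2.0 * n + 1.0) / (4.0 * np.pi)
    g = _legendre_series(cosang, base / (n * (n + 1.0)) ** m)
    h = _legendre_series(cosang, base / (n * (n + 1.0)) ** (m - 1))
    return g, h


def csd_transform_matrix(positions, m=4, lam=1e-5, n_legendre=50, head_radius=1.0):
    """Linear map ``P`` with ``csd = P @ potentials`` for one montage.

    Parameters
    ----------
    positions : ndarray (n, 3)
        Unit-sphere electrode positions.
    m : int
        Spline stiffness (4 is the common scalp-EEG choice).
    lam : float
        Ridge regularization added to the diagonal of G.
    n_legendre : int
        Number of Legendre terms in the kernel series.
    head_radius : float
        Sphere radius; output scales as 1 / head_radius**2.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 8:
        raise ValueError("CSD needs at least 8 electrodes")
    cos = np.clip(positions @ positions.T, -1.0, 1.0)
    if np.any(cos[~np.eye(n, dtype=bool)] > 1.0 - 1e-12):
        raise ValueError("duplicate electrode positions in montage")
    G, H = spline_gh(cos, m=m, n_legendre=n_legendre)
    Greg = G + lam * np.eye(n)
    # augmented system enforcing sum(c) = 0 with offset d
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = Greg
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # solve A [c; d] = [v; 0] for v = each basis vector -> coefficient map
    rhs = np.zeros((n + 1, n))
    rhs[:n, :] = np.eye(n)
    C = np.linalg.solve(A, rhs)[:n, :]   # (n coeffs) x (n inputs)
    return (H @ C) / float(head_radius) ** 2
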