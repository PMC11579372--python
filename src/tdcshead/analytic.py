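"""Series solution for current injection in a layered conducting sphere.

Classic axisymmetric reference problem: a point current source +I at the
north pole of the outer surface and a sink -I at the south pole of an
N-layer concentric sphere with piecewise-constant conductivity.  In each
layer the potential is a Legendre series

    phi_k(r, theta) = sum_l [ a_kl r^l + b_kl r^-(l+1) ] P_l(cos theta)

with only odd l contributing (antipodal antisymmetry).  Coefficients follow
from continuity of phi and of sigma dphi/dr at the interfaces, regularity at
the origin, and the Neumann condition at the outer surface, whose polar
delta loads expand as j_l = I (2l+1) / (2 pi R^2) for odd l.

The per-layer basis is scaled by the layer's own bounding radii so powers
stay O(1) at any truncation order.  This module shares no code with the FEM
solver and serves as its independent accuracy reference.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre


def layered_sphere_potential(
    r_mm,
    cos_theta,
    outer_radii_mm,
    conductivities,
    current_a: float,
    lmax: int = 200,
) -> np.ndarray:
    """Potential (V) at points (r, theta) for point electrodes at the poles.

    Parameters
    ----------
    r_mm, cos_theta : broadcastable arrays of sample coordinates
    outer_radii_mm : ascending outer radius per layer (innermost first)
    conductivities : S/m per layer, same order
    current_a : injected current in amperes
    lmax : series truncation (odd terms up to lmax); convergence is
        geometric in r/R for interior points
    """
    radii = np.asarray(outer_radii_mm, dtype=float) * 1e-3
    if not np.all(np.diff(radii) > 0):
        raise ValueError("outer radii must be strictly increasing (innermost first)")
    sig = np.asarray(conductivities, dtype=float)
    if len(sig) != len(radii) or np.any(sig <= 0):
        raise ValueError("need one positive conductivity per layer")
    r = np.asarray(r_mm, dtype=float) * 1e-3
    ct = np.asarray(cos_theta, dtype=float)
    if np.any(r > radii[-1] * (1 + 1e-9)):
        raise ValueError("sample radius outside the sphere")
    n_lay = len(radii)
    big_r = radii[-1]

    layer_of = np.minimum(np.searchsorted(radii, np.atleast_1d(r)), n_lay - 1)
    out = np.zeros(np.broadcast(r, ct).shape, dtype=float)
    flat_r = np.atleast_1d(np.broadcast_to(r, out.shape)).ravel()
    flat_ct = np.atleast_1d(np.broadcast_to(ct, out.shape)).ravel()
    flat_lay = np.minimum(np.searchsorted(radii, flat_r), n_lay - 1)
    acc = np.zeros(flat_r.shape)

    def a_idx(k):
        return k

    def b_idx(k):
        return n_lay + k - 1

    n_unk = 2 * n_lay - 1
    for l in range(1, lmax + 1, 2):
        mat = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)
        row = 0
        for k in range(n_lay - 1):
            rk = radii[k]
            # basis in layer k: a_k (r/radii[k])^l + b_k (radii[k-1]/r)^(l+1)
            mat[row, a_idx(k)] = 1.0
            if k >= 1:
                mat[row, b_idx(k)] = (radii[k - 1] / rk) ** (l + 1)
            mat[row, a_idx(k + 1)] = -((rk / radii[k + 1]) ** l)
            mat[row, b_idx(k + 1)] = -1.0
            row += 1
            sk, sk1 = sig[k], sig[k + 1]
            mat[row, a_idx(k)] = sk * l / rk
            if k >= 1:
                mat[row, b_idx(k)] = -sk * (l + 1) / rk * (radii[k - 1] / rk) ** (l + 1)
            mat[row, a_idx(k + 1)] = -sk1 * l / rk * (rk / radii[k + 1]) ** l
            mat[row, b_idx(k + 1)] = sk1 * (l + 1) / rk
            row += 1
        s_out = sig[-1]
        mat[row, a_idx(n_lay - 1)] = s_out * l / big_r
        if n_lay >= 2:
            mat[row, b_idx(n_lay - 1)] = (
                -s_out * (l + 1) / big_r * (radii[-2] / big_r) ** (l + 1)
            )
        rhs[row] = current_a * (2 * l + 1) / (2.0 * np.pi * big_r**2)
        coef = np.linalg.solve(mat, rhs)

        pl = eval_legendre(l, flat_ct)
        radial = np.zeros_like(flat_r)
        for k in range(n_lay):
            m = flat_lay == k
            if not m.any():
                continue
            term = coef[a_idx(k)] * (flat_r[m] / radii[k]) ** l
            if k >= 1:
                term = term + coef[b_idx(k)] * (
                    radii[k - 1] / np.maximum(flat_r[m], 1e-300)
                ) ** (l + 1)
            radial[m] = term
        acc += radial * pl
    out.ravel()[:] = acc
    return out if out.shape else float(acc[0])
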