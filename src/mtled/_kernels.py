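"""Compiled inner loops of the explicit solver.

Everything here operates on the padded arrays of a ShapeTable
(``conn``/``counts``/``grad``) plus flat per-cell data.  Units follow the rest
of the package: coordinates and displacements in mm, gradients in 1/mm,
volumes in mm^3, stresses in Pa.  Nodal forces therefore come out in
Pa*mm^2 = 1e-6 N; the caller applies the conversion.

The Ogden second Piola-Kirchhoff stress is assembled spectrally from the
analytic eigendecomposition of C = F^T F (trigonometric eigenvalue formula,
eigenprojectors with explicit repeated-eigenvalue branches).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TWO_PI_3 = 2.0 * math.pi / 3.0


@njit(cache=True)
def _eigvals_sym3(c00, c11, c22, c01, c02, c12):
    """Eigenvalues of a symmetric 3x3 matrix, descending."""
    p1 = c01 * c01 + c02 * c02 + c12 * c12
    q = (c00 + c11 + c22) / 3.0
    if p1 == 0.0:
        e1 = max(c00, max(c11, c22))
        e3 = min(c00, min(c11, c22))
        e2 = c00 + c11 + c22 - e1 - e3
        return e1, e2, e3
    p2 = ((c00 - q) ** 2 + (c11 - q) ** 2 + (c22 - q) ** 2 + 2.0 * p1) / 6.0
    p = math.sqrt(p2)
    b00 = (c00 - q) / p
    b11 = (c11 - q) / p
    b22 = (c22 - q) / p
    b01 = c01 / p
    b02 = c02 / p
    b12 = c12 / p
    detb = (b00 * (b11 * b22 - b12 * b12)
            - b01 * (b01 * b22 - b12 * b02)
            + b02 * (b01 * b12 - b11 * b02))
    r = detb / 2.0
    if r > 1.0:
        r = 1.0
    elif r < -1.0:
        r = -1.0
    phi = math.acos(r) / 3.0
    e1 = q + 2.0 * p * math.cos(phi)
    e3 = q + 2.0 * p * math.cos(phi + _TWO_PI_3)
    e2 = 3.0 * q - e1 - e3
    return e1, e2, e3


@njit(cache=True)
def _ogden_principal(e1, e2, e3, J, a, mu, D):
    """Principal 2nd PK stresses S_i = l_i^{-1} dW/dl_i and energy density W."""
    l1 = math.sqrt(e1 if e1 > 1e-30 else 1e-30)
    l2 = math.sqrt(e2 if e2 > 1e-30 else 1e-30)
    l3 = math.sqrt(e3 if e3 > 1e-30 else 1e-30)
    Jm = J ** (-a / 3.0)
    la1 = l1 ** a
    la2 = l2 ** a
    la3 = l3 ** a
    sla = la1 + la2 + la3
    pvol = (2.0 / D) * (J - 1.0) * J
    s1 = (2.0 * mu / a) * Jm * (la1 - sla / 3.0) / e1 + pvol / e1
    s2 = (2.0 * mu / a) * Jm * (la2 - sla / 3.0) / e2 + pvol / e2
    s3 = (2.0 * mu / a) * Jm * (la3 - sla / 3.0) / e3 + pvol / e3
    W = (2.0 * mu / (a * a)) * (Jm * sla - 3.0) + (1.0 / D) * (J - 1.0) ** 2
    return s1, s2, s3, W


@njit(cache=True)
def internal_forces_kernel(conn, counts, grads, vols, mat_id, mats, u, f_out):
    """Accumulate nodal internal forces by one-point quadrature per cell.

    ``f_out`` (n_nodes, 3) is zeroed here.  Returns (total strain energy in
    Pa*mm^3, index of the first inverted cell or -1).
    """
    f_out[:] = 0.0
    n_cells = conn.shape[0]
    energy = 0.0
    bad = -1
    for c in range(n_cells):
        k = counts[c]
        h00 = 0.0; h01 = 0.0; h02 = 0.0
        h10 = 0.0; h11 = 0.0; h12 = 0.0
        h20 = 0.0; h21 = 0.0; h22 = 0.0
        for j in range(k):
            n = conn[c, j]
            gx = grads[c, j, 0]; gy = grads[c, j, 1]; gz = grads[c, j, 2]
            ux = u[n, 0]; uy = u[n, 1]; uz = u[n, 2]
            h00 += ux * gx; h01 += ux * gy; h02 += ux * gz
            h10 += uy * gx; h11 += uy * gy; h12 += uy * gz
            h20 += uz * gx; h21 += uz * gy; h22 += uz * gz
        f00 = 1.0 + h00; f01 = h01; f02 = h02
        f10 = h10; f11 = 1.0 + h11; f12 = h12
        f20 = h20; f21 = h21; f22 = 1.0 + h22
        J = (f00 * (f11 * f22 - f12 * f21)
             - f01 * (f10 * f22 - f12 * f20)
             + f02 * (f10 * f21 - f11 * f20))
        if J <= 0.0:
            bad = c
            return energy, bad
        # C = F^T F
        c00 = f00 * f00 + f10 * f10 + f20 * f20
        c11 = f01 * f01 + f11 * f11 + f21 * f21
        c22 = f02 * f02 + f12 * f12 + f22 * f22
        c01 = f00 * f01 + f10 * f11 + f20 * f21
        c02 = f00 * f02 + f10 * f12 + f20 * f22
        c12 = f01 * f02 + f11 * f12 + f21 * f22
        e1, e2, e3 = _eigvals_sym3(c00, c11, c22, c01, c02, c12)
        m = mat_id[c]
        a = mats[m, 0]; mu = mats[m, 1]; D = mats[m, 2]
        s1, s2, s3, W = _ogden_principal(e1, e2, e3, J, a, mu, D)
        energy += W * vols[c]
        # spectral recomposition S = sum s_i P_i with eigenprojectors of C
        tol = 1e-8 * (abs(e1) + 1.0)
        if e1 - e3 <= tol:
            sm = (s1 + s2 + s3) / 3.0
            S00 = sm; S11 = sm; S22 = sm; S01 = 0.0; S02 = 0.0; S12 = 0.0
        else:
            if e1 - e2 <= tol:
                # P3 distinct: P3 = (C-e1)(C-e2)/((e3-e1)(e3-e2))
                d = (e3 - e1) * (e3 - e2)
                p00, p11, p22, p01, p02, p12 = _shifted_product(
                    c00, c11, c22, c01, c02, c12, e1, e2, d)
                s_pair = 0.5 * (s1 + s2)
                S00 = s_pair + (s3 - s_pair) * p00
                S11 = s_pair + (s3 - s_pair) * p11
                S22 = s_pair + (s3 - s_pair) * p22
                S01 = (s3 - s_pair) * p01
                S02 = (s3 - s_pair) * p02
                S12 = (s3 - s_pair) * p12
            elif e2 - e3 <= tol:
                d = (e1 - e2) * (e1 - e3)
                p00, p11, p22, p01, p02, p12 = _shifted_product(
                    c00, c11, c22, c01, c02, c12, e2, e3, d)
                s_pair = 0.5 * (s2 + s3)
                S00 = s_pair + (s1 - s_pair) * p00
                S11 = s_pair + (s1 - s_pair) * p11
                S22 = s_pair + (s1 - s_pair) * p22
                S01 = (s1 - s_pair) * p01
                S02 = (s1 - s_pair) * p02
                S12 = (s1 - s_pair) * p12
            else:
                d1 = (e1 - e2) * (e1 - e3)
                q100, q111, q122, q101, q102, q112 = _shifted_product(
                    c00, c11, c22, c01, c02, c12, e2, e3, d1)
                d2 = (e2 - e1) * (e2 - e3)
                q200, q211, q222, q201, q202, q212 = _shifted_product(
                    c00, c11, c22, c01, c02, c12, e1, e3, d2)
                # P3 = I - P1 - P2
                S00 = s1 * q100 + s2 * q200 + s3 * (1.0 - q100 - q200)
                S11 = s1 * q111 + s2 * q211 + s3 * (1.0 - q111 - q211)
                S22 = s1 * q122 + s2 * q222 + s3 * (1.0 - q122 - q222)
                S01 = s1 * q101 + s2 * q201 + s3 * (-q101 - q201)
                S02 = s1 * q102 + s2 * q202 + s3 * (-q102 - q202)
                S12 = s1 * q112 + s2 * q212 + s3 * (-q112 - q212)
        # first Piola-Kirchhoff P = F S
        P00 = f00 * S00 + f01 * S01 + f02 * S02
        P01 = f00 * S01 + f01 * S11 + f02 * S12
        P02 = f00 * S02 + f01 * S12 + f02 * S22
        P10 = f10 * S00 + f11 * S01 + f12 * S02
        P11 = f10 * S01 + f11 * S11 + f12 * S12
        P12 = f10 * S02 + f11 * S12 + f12 * S22
        P20 = f20 * S00 + f21 * S01 + f22 * S02
        P21 = f20 * S01 + f21 * S11 + f22 * S12
        P22 = f20 * S02 + f21 * S12 + f22 * S22
        V = vols[c]
        for j in range(k):
            n = conn[c, j]
            gx = grads[c, j, 0]; gy = grads[c, j, 1]; gz = grads[c, j, 2]
            f_out[n, 0] += V * (P00 * gx + P01 * gy + P02 * gz)
            f_out[n, 1] += V * (P10 * gx + P11 * gy + P12 * gz)
            f_out[n, 2] += V * (P20 * gx + P21 * gy + P22 * gz)
    return energy, bad


@njit(cache=True)
def _shifted_product(c00, c11, c22, c01, c02, c12, ea, eb, denom):
    """((C - ea I)(C - eb I)) / denom for symmetric C, returned as 6 components."""
    a00 = c00 - ea; a11 = c11 - ea; a22 = c22 - ea
    b00 = c00 - eb; b11 = c11 - eb; b22 = c22 - eb
    p00 = (a00 * b00 + c01 * c01 + c02 * c02) / denom
    p11 = (c01 * c01 + a11 * b11 + c12 * c12) / denom
    p22 = (c02 * c02 + c12 * c12 + a22 * b22) / denom
    p01 = (a00 * c01 + c01 * b11 + c02 * c12) / denom
    p02 = (a00 * c02 + c01 * c12 + c02 * b22) / denom
    p12 = (c01 * c02 + a11 * c12 + c12 * b22) / denom
    return p00, p11, p22, p01, p02, p12


@njit(cache=True)
def max_green_strain_kernel(cell_ids, conn, counts, grads, u):
    """Max principal Green strain over a subset of cells: max eig of (C-I)/2."""
    best = -1e30
    for idx in range(cell_ids.shape[0]):
        c = cell_ids[idx]
        k = counts[c]
        h00 = 0.0; h01 = 0.0; h02 = 0.0
        h10 = 0.0; h11 = 0.0; h12 = 0.0
        h20 = 0.0; h21 = 0.0; h22 = 0.0
        for j in range(k):
            n = conn[c, j]
            gx = grads[c, j, 0]; gy = grads[c, j, 1]; gz = grads[c, j, 2]
            h00 += u[n, 0] * gx; h01 += u[n, 0] * gy; h02 += u[n, 0] * gz
            h10 += u[n, 1] * gx; h11 += u[n, 1] * gy; h12 += u[n, 1] * gz
            h20 += u[n, 2] * gx; h21 += u[n, 2] * gy; h22 += u[n, 2] * gz
        f00 = 1.0 + h00; f01 = h01; f02 = h02
        f10 = h10; f11 = 1.0 + h11; f12 = h12
        f20 = h20; f21 = h21; f22 = 1.0 + h22
        c00 = f00 * f00 + f10 * f10 + f20 * f20
        c11 = f01 * f01 + f11 * f11 + f21 * f21
        c22 = f02 * f02 + f12 * f12 + f22 * f22
        c01 = f00 * f01 + f10 * f11 + f20 * f21
        c02 = f00 * f02 + f10 * f12 + f20 * f22
        c12 = f01 * f02 + f11 * f12 + f21 * f22
        e1, _, _ = _eigvals_sym3(c00, c11, c22, c01, c02, c12)
        g = 0.5 * (e1 - 1.0)
        if g > best:
            best = g
    return best
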