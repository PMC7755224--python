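"""Hyperelastic constitutive models in principal stretches.

The one-term Ogden strain-energy density

    W = (2 mu / a^2) * (J^(-a/3) * (l1^a + l2^a + l3^a) - 3) + (1/D) * (J - 1)^2

with principal stretches l_i, J = det F = l1 l2 l3, shear modulus mu (Pa),
exponent a and volumetric compliance D (1/Pa).  The neo-Hookean model is the
a = 2 special case.  Near-incompressibility is enforced by the (J-1)^2
penalty alone; the implied bulk modulus is K = 2/D (the second derivative of
the volumetric term at J = 1), which together with mu fixes Poisson's ratio.

Stress evaluation goes through the spectral decomposition of C = F^T F:
the principal second Piola-Kirchhoff stresses are S_i = l_i^{-1} dW/dl_i and
S = sum_i S_i n_i n_i^T on the principal directions of C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams", "PointKinematics", "InvertedCellError",
    "neo_hookean", "strain_energy", "second_pk_stress",
    "bulk_modulus", "poisson_ratio", "max_principal_green_strain",
]


class InvertedCellError(FloatingPointError):
    """det F <= 0: the material locally inverted."""


@dataclass(frozen=True)
class MaterialParams:
    """Ogden triple (a, mu, D); ``name`` is free-form metadata."""

    a: float
    mu: float
    D: float
    name: str = ""

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"shear modulus must be positive, got {self.mu}")
        if self.D <= 0:
            raise ValueError(f"volumetric compliance must be positive, got {self.D}")
        if self.a == 0:
            raise ValueError("Ogden exponent a must be nonzero")

    def scaled(self, s: float) -> "MaterialParams":
        """Stiffness-scaled copy: mu -> s*mu, D -> D/s (same Poisson ratio)."""
        return MaterialParams(a=self.a, mu=s * self.mu, D=self.D / s,
                              name=self.name)


def neo_hookean(mu: float, poisson: float = 0.49, name: str = "") -> MaterialParams:
    """Neo-Hookean material (Ogden with a = 2) at a given Poisson ratio."""
    K = 2.0 * mu * (1.0 + poisson) / (3.0 * (1.0 - 2.0 * poisson))
    return MaterialParams(a=2.0, mu=mu, D=2.0 / K, name=name)


@dataclass
class PointKinematics:
    """Deformation gradient and derived spectral quantities at a material point."""

    F: np.ndarray
    J: float = field(init=False)
    stretches: np.ndarray = field(init=False)     # principal stretches, descending
    directions: np.ndarray = field(init=False)    # columns: principal directions of C

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise InvertedCellError(f"det F = {self.J:.3e} <= 0")
        C = self.F.T @ self.F
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        self.stretches = np.sqrt(np.clip(evals[order], 0.0, None))
        self.directions = evecs[:, order]


def strain_energy(kin: PointKinematics, mat: MaterialParams) -> float:
    """Strain-energy density W (Pa)."""
    l = kin.stretches
    J = kin.J
    a = mat.a
    iso = (2.0 * mat.mu / a**2) * (J ** (-a / 3.0) * np.sum(l**a) - 3.0)
    vol = (1.0 / mat.D) * (J - 1.0) ** 2
    return float(iso + vol)


def _principal_second_pk(l: np.ndarray, J: float, mat: MaterialParams) -> np.ndarray:
    """S_i = l_i^{-1} dW/dl_i for the Ogden energy."""
    a = mat.a
    la = l**a
    iso = (2.0 * mat.mu / a) * J ** (-a / 3.0) * (la - la.sum() / 3.0) / l**2
    vol = (2.0 / mat.D) * (J - 1.0) * J / l**2
    return iso + vol


def second_pk_stress(kin: PointKinematics, mat: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress tensor S (Pa, symmetric 3x3)."""
    s = _principal_second_pk(kin.stretches, kin.J, mat)
    N = kin.directions
    return (N * s) @ N.T


def bulk_modulus(mat: MaterialParams) -> float:
    """K = 2/D (Pa), from the curvature of the volumetric penalty at J = 1."""
    return 2.0 / mat.D


def poisson_ratio(mat: MaterialParams) -> float:
    """nu from (K, mu); approaches 0.5 as mu/K -> 0."""
    K = bulk_modulus(mat)
    return (3.0 * K - 2.0 * mat.mu) / (6.0 * K + 2.0 * mat.mu)


def max_principal_green_strain(kin: PointKinematics) -> float:
    """Largest eigenvalue of E = (F^T F - I)/2 = (l_max^2 - 1)/2."""
    return float((kin.stretches[0] ** 2 - 1.0) / 2.0)
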