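"""Isotropic Lee-Sacks hyperelasticity for valve leaflet tissue.

Strain energy (kPa):

    Psi = c0/2 (I1b - 3) + c1/2 (exp(c2 (I1b - 3)^2) - 1) + k/2 (J - 1)^2

with the isochoric first invariant I1b = J^(-2/3) tr(C) by default, so
the reference state is exactly stress-free; the full invariant
I1 = tr(C) is available behind the ``isochoric`` switch. The neo-Hookean
constant c0 is the small-strain shear modulus; c1, c2 control the
exponential collagen-recruitment stiffening; k is the bulk modulus
enforcing near-incompressibility.

Second Piola-Kirchhoff stress S = 2 dPsi/dC and the tangent dS/dC are
analytic. The tangent scale factor TF multiplies only the
exponential-term block of the tangent (a stabilization device for the
implicit solver); TF = 1 gives the exact Newton tangent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationState",
    "strain_energy",
    "pk2_stress",
    "material_tangent",
    "membrane_energy",
    "membrane_pk2",
    "membrane_resultant",
]


@dataclass(frozen=True)
class MaterialParams:
    """Lee-Sacks constants. Defaults are the adult-valve literature set."""

    c0: float = 67.0      # kPa, neo-Hookean shear modulus
    c1: float = 13.0      # kPa, exponential magnitude
    c2: float = 35.0      # -, exponential rate
    k: float = 5000.0     # kPa, bulk modulus
    TF: float = 1.0       # tangent scale factor in (0, 1]
    isochoric: bool = True

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1, c2 must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0 < self.TF <= 1:
            raise ValueError("TF must lie in (0, 1]")


@dataclass
class DeformationState:
    """Kinematic quantities derived from a deformation gradient F."""

    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise ValueError(f"det F = {self.J:.3g} <= 0")
        self.C = self.F.T @ self.F
        self.I1 = float(np.trace(self.C))
        self.I1_bar = self.J ** (-2 / 3) * self.I1


def _psi_iso_derivs(i1b: float, p: MaterialParams):
    """(psi, dpsi/dI1b, d2psi/dI1b2) of the isochoric energy, with the
    exponential parts of the derivatives returned separately for TF."""
    x = i1b - 3.0
    e = np.exp(p.c2 * x * x)
    psi = 0.5 * p.c0 * x + 0.5 * p.c1 * (e - 1.0)
    d_nh = 0.5 * p.c0
    d_exp = p.c1 * p.c2 * x * e
    dd_exp = p.c1 * p.c2 * e * (1.0 + 2.0 * p.c2 * x * x)
    return psi, d_nh, d_exp, dd_exp


def strain_energy(state: DeformationState, p: MaterialParams) -> float:
    """Total strain-energy density (kPa); zero at the reference state."""
    i1b = state.I1_bar if p.isochoric else state.I1
    psi, *_ = _psi_iso_derivs(i1b, p)
    return float(psi + 0.5 * p.k * (state.J - 1.0) ** 2)


def pk2_stress(state: DeformationState, p: MaterialParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC (kPa, symmetric 3x3)."""
    C, J = state.C, state.J
    Cinv = np.linalg.inv(C)
    if p.isochoric:
        a = J ** (-2 / 3)
        G = a * (np.eye(3) - (state.I1 / 3.0) * Cinv)
        i1b = state.I1_bar
    else:
        G = np.eye(3)
        i1b = state.I1
    _, d_nh, d_exp, _ = _psi_iso_derivs(i1b, p)
    S_iso = 2.0 * (d_nh + d_exp) * G
    S_vol = p.k * (J * J - J) * Cinv
    return S_iso + S_vol


def material_tangent(state: DeformationState, p: MaterialParams) -> np.ndarray:
    """Fourth-order tangent dS/dC (3x3x3x3, kPa), exact for TF = 1.

    TF scales only the exponential-term contributions; the residual
    (stress) itself is never scaled.
    """
    C, J, I1 = state.C, state.J, state.I1
    Cinv = np.linalg.inv(C)
    # D_ijkl = 1/2 (Cinv_ik Cinv_jl + Cinv_il Cinv_jk) = -dCinv/dC
    D = 0.5 * (np.einsum("ik,jl->ijkl", Cinv, Cinv)
               + np.einsum("il,jk->ijkl", Cinv, Cinv))
    ident = np.eye(3)

    if p.isochoric:
        a = J ** (-2 / 3)
        G = a * (ident - (I1 / 3.0) * Cinv)
        i1b = state.I1_bar
        # dG_ij/dC_kl
        dG = (-(a / 3.0) * np.einsum("ij,kl->ijkl", ident, Cinv)
              - (1.0 / 3.0) * np.einsum("kl,ij->ijkl", G, Cinv)
              + (a * I1 / 3.0) * D)
    else:
        G = ident
        i1b = I1
        dG = np.zeros((3, 3, 3, 3))
    _, d_nh, d_exp, dd_exp = _psi_iso_derivs(i1b, p)
    psi1_t = d_nh + p.TF * d_exp
    psi2_t = p.TF * dd_exp
    tang = (2.0 * psi2_t * np.einsum("ij,kl->ijkl", G, G)
            + 2.0 * psi1_t * dG)
    # volumetric: S_vol = k (J^2 - J) Cinv; dJ/dC = (J/2) Cinv
    tang += (p.k * (2.0 * J - 1.0) * (J / 2.0)
             * np.einsum("kl,ij->ijkl", Cinv, Cinv)
             - p.k * (J * J - J) * D)
    return tang


# --- plane-stress membrane reduction ---------------------------------


def _embed_f2d(F2d: np.ndarray) -> DeformationState:
    F2d = np.asarray(F2d, dtype=float)
    det = float(np.linalg.det(F2d))
    if det <= 0:
        raise ValueError(f"det F2d = {det:.3g} <= 0")
    F3 = np.zeros((3, 3))
    F3[:2, :2] = F2d
    F3[2, 2] = 1.0 / det  # local incompressibility lambda3 = 1/det(F2d)
    return DeformationState(F3)


def membrane_energy(F2d: np.ndarray, p: MaterialParams) -> float:
    """Condensed membrane energy density (kPa) at lambda3 = 1/det F2d."""
    return strain_energy(_embed_f2d(F2d), p)


def membrane_pk2(F2d: np.ndarray, p: MaterialParams) -> np.ndarray:
    """Effective in-plane PK2 stress 2 dPsi_m/dC2d (kPa, 2x2).

    The out-of-plane stretch follows det(C2d) through incompressibility,
    so the S33 term is condensed into the in-plane stress.
    """
    state = _embed_f2d(F2d)
    S3 = pk2_stress(state, p)
    C2d = state.C[:2, :2]
    lam3sq = state.C[2, 2]
    return S3[:2, :2] - S3[2, 2] * lam3sq * np.linalg.inv(C2d)


def membrane_resultant(F2d: np.ndarray, thickness: float,
                       p: MaterialParams) -> np.ndarray:
    """Membrane stress resultant N = thickness * S_eff (kPa mm, 2x2)."""
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    return thickness * membrane_pk2(F2d, p)


# --- vectorized membrane kernels used by the FE assembly --------------


def membrane_pk2_batch(C2d: np.ndarray, p: MaterialParams) -> np.ndarray:
    """Effective in-plane PK2 for a batch of 2x2 right Cauchy-Green
    tensors (n, 2, 2) -> (n, 2, 2). Same condensation as membrane_pk2
    but written with closed-form 2x2 algebra for speed."""
    C2d = np.asarray(C2d, dtype=float)
    detC = C2d[:, 0, 0] * C2d[:, 1, 1] - C2d[:, 0, 1] * C2d[:, 1, 0]
    if np.any(detC <= 0):
        bad = np.where(detC <= 0)[0]
        raise ValueError(f"inverted membrane state(s): elements "
                         f"{bad[:10].tolist()}")
    lam3sq = 1.0 / detC
    trC2 = C2d[:, 0, 0] + C2d[:, 1, 1]
    I1 = trC2 + lam3sq          # J = 1 by construction
    i1b = I1
    x = i1b - 3.0
    # exponent capped to keep trial states finite during line searches;
    # the cap only binds far outside the physiological strain range
    e = np.exp(np.minimum(p.c2 * x * x, 50.0))
    dpsi = 0.5 * p.c0 + p.c1 * p.c2 * x * e
    # S3 = 2 dpsi * (I - I1/3 Cinv) with J=1, plus zero volumetric term
    inv = np.empty_like(C2d)
    inv[:, 0, 0] = C2d[:, 1, 1]
    inv[:, 1, 1] = C2d[:, 0, 0]
    inv[:, 0, 1] = -C2d[:, 0, 1]
    inv[:, 1, 0] = -C2d[:, 1, 0]
    inv /= detC[:, None, None]
    eye = np.broadcast_to(np.eye(2), C2d.shape)
    # with J = 1 the isochoric and full invariants coincide and the
    # volumetric term vanishes; Cinv3's 33 entry is 1/lam3sq
    S_in = 2.0 * dpsi[:, None, None] * (eye - (I1 / 3.0)[:, None, None] * inv)
    S33 = 2.0 * dpsi * (1.0 - (I1 / 3.0) / lam3sq)
    return S_in - (S33 * lam3sq)[:, None, None] * inv


def membrane_energy_batch(C2d: np.ndarray, p: MaterialParams) -> np.ndarray:
    C2d = np.asarray(C2d, dtype=float)
    detC = C2d[:, 0, 0] * C2d[:, 1, 1] - C2d[:, 0, 1] * C2d[:, 1, 0]
    lam3sq = 1.0 / detC
    I1 = C2d[:, 0, 0] + C2d[:, 1, 1] + lam3sq
    x = I1 - 3.0
    return 0.5 * p.c0 * x + 0.5 * p.c1 * (
        np.exp(np.minimum(p.c2 * x * x, 50.0)) - 1.0)
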