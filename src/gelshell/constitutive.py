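"""Hyperelastic energies, tension/compression split, and stresses.

Two constitutive models are provided:

* a compressible neo-Hookean hydrogel with a principal-stretch
  tension/compression split, where only the tensile part is degraded by the
  damage field through g(p) = (1 - K) p^2 + K;
* a one-term Ogden model (deviatoric principal stretches plus a quadratic
  volumetric term) for soft-tissue substrates.

All stresses are first Piola-Kirchhoff, assembled in the principal frame
through the SVD of F: for an isotropic energy W(lambda_1..3),
dW/dF = U diag(dW/dlambda_i) V^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvertedElementError


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HydrogelMaterial:
    """Split neo-Hookean hydrogel: shear modulus mu, Lame-type constant chi,
    residual factor k_res (keeps a sliver of tensile stiffness at p = 0)."""

    mu: float
    chi: float
    k_res: float = 1e-4

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.chi < 0:
            raise ValueError("chi must be nonnegative")
        if not 0 < self.k_res < 1:
            raise ValueError("k_res must lie in (0, 1)")


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden solid: shear modulus mu_og, bulk modulus k_og,
    exponent alpha (may be negative, must be nonzero)."""

    mu_og: float
    k_og: float
    alpha: float

    def __post_init__(self):
        if self.mu_og <= 0:
            raise ValueError("mu_og must be positive")
        if self.k_og <= 0:
            raise ValueError("k_og must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")


@dataclass
class StretchState:
    """Principal-stretch decomposition of a deformation gradient."""

    F: np.ndarray
    lambdas: np.ndarray  # sorted descending
    J: float
    I1: float


def stretch_state(F: np.ndarray, element: int | None = None) -> StretchState:
    """SVD-based principal stretches; raises on det F <= 0."""
    F = np.asarray(F, dtype=np.float64)
    J = float(np.linalg.det(F))
    if J <= 0:
        where = f" (element {element})" if element is not None else ""
        raise InvertedElementError(f"det F = {J:.3e} <= 0{where}", element)
    lambdas = np.linalg.svd(F, compute_uv=False)
    return StretchState(F=F, lambdas=lambdas, J=J, I1=float((lambdas**2).sum()))


# ---------------------------------------------------------------------------
# split neo-Hookean (vectorized over leading axes)
# ---------------------------------------------------------------------------


def neo_hookean_G(lambdas, J, mu, chi):
    """G(lambda, J) = mu/2 * sum(l^2 - 1 - 2 ln l) + chi/2 (J - 1)^2."""
    lambdas = np.asarray(lambdas, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    iso = 0.5 * mu * np.sum(lambdas**2 - 1.0 - 2.0 * np.log(lambdas), axis=-1)
    return iso + 0.5 * chi * (J - 1.0) ** 2


def split_energy_principal(lambdas, J, mu, chi):
    """(W+, W-) from principal stretches; vectorized over leading axes.

    W+ uses lambda_i+ = max(lambda_i, 1), J+ = max(J, 1); W- uses the
    mirrored clamps.  A stretch (or J) exactly 1 contributes to neither.
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    lp = np.maximum(lambdas, 1.0)
    lm = np.minimum(lambdas, 1.0)
    wp = neo_hookean_G(lp, np.maximum(J, 1.0), mu, chi)
    wm = neo_hookean_G(lm, np.minimum(J, 1.0), mu, chi)
    return wp, wm


def dsplit_dlambda(lambdas, J, mu, chi):
    """Derivatives (dW+/dl_i, dW-/dl_i) of the split energies.

    The volumetric term is chained through J = prod(l_i):
    d/dl_i [chi/2 (J - 1)^2] = chi (J - 1) J / l_i on the active branch.
    Both branches vanish at l_i = 1 / J = 1, so the split is C1 there.
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    iso = mu * (lambdas - 1.0 / lambdas)
    tension = lambdas > 1.0
    dp = np.where(tension, iso, 0.0)
    dm = np.where(~tension, iso, 0.0)
    Jcol = J[..., None]
    vol = (chi * (Jcol - 1.0) * Jcol) / lambdas
    dp = dp + np.where(Jcol > 1.0, vol, 0.0)
    dm = dm + np.where(Jcol < 1.0, vol, 0.0)
    return dp, dm


def degradation(p, k_res):
    """g(p) = (1 - K) p^2 + K; g(1) = 1 (intact), g(0) = K (residual)."""
    return (1.0 - k_res) * np.asarray(p) ** 2 + k_res


def split_energy(state: StretchState, mat: HydrogelMaterial):
    """(W+, W-) for a single stretch state."""
    return split_energy_principal(state.lambdas, state.J, mat.mu, mat.chi)


def degraded_energy(w_plus, w_minus, p, mat: HydrogelMaterial):
    """W = g(p) W+ + W-.  Only the tensile part is degraded."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("phase value p must lie in [0, 1]")
    return degradation(p, mat.k_res) * w_plus + w_minus


def pk1_hydrogel(F, p, mat: HydrogelMaterial, element=None) -> np.ndarray:
    """First Piola-Kirchhoff stress of the degraded split model."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError("phase value p must lie in [0, 1]")
    F = np.asarray(F, dtype=np.float64)
    J = np.linalg.det(F)
    if J <= 0:
        raise InvertedElementError(f"det F = {J:.3e} <= 0", element)
    U, s, Vt = np.linalg.svd(F)
    dp, dm = dsplit_dlambda(s, J, mat.mu, mat.chi)
    g = degradation(p, mat.k_res) * dp + dm
    return (U * g) @ Vt


# ---------------------------------------------------------------------------
# Ogden
# ---------------------------------------------------------------------------


def ogden_energy_principal(lambdas, J, mat: OgdenMaterial):
    """W = 2 mu/alpha^2 (sum lbar_i^alpha - 3) + K/2 (J - 1)^2."""
    lambdas = np.asarray(lambdas, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    lbar = lambdas * J[..., None] ** (-1.0 / 3.0)
    dev = (2.0 * mat.mu_og / mat.alpha**2) * (
        np.sum(lbar**mat.alpha, axis=-1) - 3.0
    )
    return dev + 0.5 * mat.k_og * (J - 1.0) ** 2


def dogden_dlambda(lambdas, J, mat: OgdenMaterial):
    """dW/dlambda_i for the Ogden model.

    With lbar_j = J^(-1/3) lambda_j:
    dW_dev/dl_i = (2 mu / alpha) (1/l_i) [lbar_i^alpha - mean(lbar^alpha)].
    """
    lambdas = np.asarray(lambdas, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    lbar_a = (lambdas * J[..., None] ** (-1.0 / 3.0)) ** mat.alpha
    mean_a = np.mean(lbar_a, axis=-1)[..., None]
    dev = (2.0 * mat.mu_og / mat.alpha) * (lbar_a - mean_a) / lambdas
    vol = mat.k_og * (J[..., None] - 1.0) * J[..., None] / lambdas
    return dev + vol


def ogden_energy(F, mat: OgdenMaterial) -> float:
    s = stretch_state(F)
    return float(ogden_energy_principal(s.lambdas, np.float64(s.J), mat))


def ogden_pk1(F, mat: OgdenMaterial, element=None) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    J = np.linalg.det(F)
    if J <= 0:
        raise InvertedElementError(f"det F = {J:.3e} <= 0", element)
    U, s, Vt = np.linalg.svd(F)
    g = dogden_dlambda(s, np.float64(J), mat)
    return (U * g) @ Vt


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def cauchy_effective(P, F) -> float:
    """Von Mises equivalent of the Cauchy stress sigma = J^-1 P F^T."""
    P = np.asarray(P, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    J = np.linalg.det(F)
    sigma = (P @ F.T) / J
    dev = sigma - np.trace(sigma) / 3.0 * np.eye(3)
    return float(np.sqrt(1.5 * np.sum(dev * dev)))
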