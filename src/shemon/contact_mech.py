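"""Conformal-contact mechanics of a thin-film electrode laminate on skin.

A skin-mounted electrode laminate makes gapless (conformal) contact when the
elastomer's work of adhesion exceeds the energy cost of bending the laminate
into the skin's sinusoidal roughness profile plus deforming the skin.  For a
laminate of effective bending stiffness EI (per unit width) on skin of
modulus ``E_skin`` with roughness wavelength ``lambda_rough`` and amplitude
``h_rough``, the film sags into the valleys by the equilibrium amplitude

    h = E_skin * h_rough / (16 pi^3 EI / lambda^3 + E_skin)

and conformal contact requires (strict inequality)

    gamma_elastomer > 1/(1 - alpha) * [ pi^4 EI h^2 / lambda^4
        + (pi E_skin (h_rough - h) / (16 lambda)) * (1 + pi^2 h^2 / (4 lambda^2)) ]

where ``alpha`` is the areal fraction of the stiff PI/Au mesh (the fraction
of interface that cannot adhere directly).  The right-hand side is the
critical work of adhesion ``gamma_crit``.

The module also fits the work of adhesion from rolling-cylinder peel data
(y-intercept of effective peel energy versus speed) and integrates
peel-force curves into total peel energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LaminateStack",
    "SkinModel",
    "ContactResult",
    "effective_bending_stiffness",
    "sag_amplitude",
    "critical_adhesion",
    "classify_elastomers",
    "work_of_adhesion_intercept",
    "peel_energy",
    "critical_boundary_curve",
]


@dataclass
class LaminateStack:
    """Layer stack (bottom to top) of (name, thickness m, modulus Pa) plus
    the areal fraction ``alpha`` of PI and Au in the mesh."""

    layers: list[tuple[str, float, float]]
    alpha: float = 0.0

    def __post_init__(self):
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        for name, t, E in self.layers:
            if t <= 0:
                raise ValueError(f"layer {name!r} has non-positive thickness")
            if E <= 0:
                raise ValueError(f"layer {name!r} has non-positive modulus")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")


@dataclass
class SkinModel:
    """Skin as an elastic half-space with sinusoidal roughness."""

    E_skin: float = 130e3          # Pa; literature value for epidermis
    lambda_rough: float = 140e-6   # m; roughness wavelength
    h_rough: float = 50e-6         # m; roughness amplitude

    def __post_init__(self):
        if self.E_skin <= 0 or self.lambda_rough <= 0 or self.h_rough < 0:
            raise ValueError("E_skin, lambda_rough must be > 0; h_rough >= 0")


@dataclass
class ContactResult:
    gamma_crit: float          # J m^-2
    h: float                   # m, equilibrium sagging amplitude
    conformal: bool | None = None
    margin: float | None = None  # gamma_elastomer - gamma_crit


def effective_bending_stiffness(stack: LaminateStack) -> float:
    """Composite-beam bending stiffness per unit width, N m.

    Transformed-section method about the stack's modulus-weighted neutral
    axis: EI = sum_i E_i (t_i^3/12 + t_i (y_i - y_bar)^2) with y_i the layer
    midheights and y_bar = sum E_i t_i y_i / sum E_i t_i.
    """
    t = np.array([layer[1] for layer in stack.layers], dtype=float)
    E = np.array([layer[2] for layer in stack.layers], dtype=float)
    tops = np.cumsum(t)
    mid = tops - t / 2.0
    ybar = float(np.sum(E * t * mid) / np.sum(E * t))
    return float(np.sum(E * (t ** 3 / 12.0 + t * (mid - ybar) ** 2)))


def sag_amplitude(EI: float, skin: SkinModel) -> float:
    """Equilibrium sag of the film into the roughness valleys.

    Monotone decreasing in EI, bounded by [0, h_rough]: a perfectly floppy
    film (EI = 0) follows the skin completely (h = h_rough); an infinitely
    stiff one bridges the valleys (h -> 0).
    """
    if EI < 0:
        raise ValueError("EI must be non-negative")
    lam = skin.lambda_rough
    return skin.E_skin * skin.h_rough / (16.0 * np.pi ** 3 * EI / lam ** 3
                                         + skin.E_skin)


def critical_adhesion(stack: LaminateStack, skin: SkinModel) -> ContactResult:
    """Critical work of adhesion for conformal contact (J m^-2)."""
    EI = effective_bending_stiffness(stack)
    h = sag_amplitude(EI, skin)
    lam = skin.lambda_rough
    bending = np.pi ** 4 * EI * h ** 2 / lam ** 4
    skin_el = (np.pi * skin.E_skin * (skin.h_rough - h) / (16.0 * lam)) \
        * (1.0 + np.pi ** 2 * h ** 2 / (4.0 * lam ** 2))
    gamma_crit = (bending + skin_el) / (1.0 - stack.alpha)
    return ContactResult(gamma_crit=float(gamma_crit), h=float(h))


def classify_elastomers(candidates, stack: LaminateStack, skin: SkinModel,
                        elastomer_thickness: float | None = None):
    """Label elastomer candidates conformal / non-conformal.

    ``candidates`` is a list of (name, E Pa, gamma J m^-2); a candidate with
    gamma None is skipped with a warning.  Each candidate's substrate layer
    replaces the stack's elastomer layer modulus (the topmost layer, or the
    layer named like an elastomer) so the margin reflects that material.
    Returns a list of dicts sorted as given, each with ``margin`` =
    gamma - gamma_crit and ``conformal`` (strict inequality: a candidate
    exactly at the boundary is non-conformal).
    """
    out = []
    for name, E, gamma in candidates:
        if gamma is None:
            warnings.warn(f"candidate {name!r} skipped: no work of adhesion")
            continue
        layers = [(nm, (elastomer_thickness if _is_elastomer(nm) and
                        elastomer_thickness else t),
                   (E if _is_elastomer(nm) else Ei))
                  for nm, t, Ei in stack.layers]
        res = critical_adhesion(LaminateStack(layers, alpha=stack.alpha), skin)
        margin = gamma - res.gamma_crit
        out.append(dict(name=name, E=E, gamma=gamma,
                        gamma_crit=res.gamma_crit, h=res.h,
                        margin=margin, conformal=margin > 0))
    return out


def _is_elastomer(name: str) -> bool:
    return name.lower() in ("elastomer", "pdms", "ecoflex", "solaris",
                            "substrate")


def critical_boundary_curve(stack: LaminateStack, skin: SkinModel,
                            E_grid: np.ndarray,
                            elastomer_thickness: float | None = None):
    """gamma_crit as a function of elastomer modulus over ``E_grid``.

    Reproduces the shape of the critical-contact boundary separating
    conformal from non-conformal (modulus, adhesion) pairs.
    """
    rows = classify_elastomers([(f"elastomer", float(E), 0.0) for E in E_grid],
                               stack, skin, elastomer_thickness)
    return np.array([r["gamma_crit"] for r in rows])


# ---------------------------------------------------------------------------
# Work-of-adhesion intercept fit and peel-energy integration
# ---------------------------------------------------------------------------

def work_of_adhesion_intercept(points, degree: int = 1):
    """Work of adhesion from rolling-cylinder data.

    ``points``: (speed, delta_gamma) pairs.  Fits delta_gamma as a
    polynomial in speed (default linear) by least squares and returns
    ``(gamma_0, se)``: the y-intercept and its standard error (0 for an
    exact fit or a saturated system).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (speed, delta_gamma) points")
    v, g = pts[:, 0], pts[:, 1]
    if np.ptp(v) == 0:
        raise ValueError("all speeds identical; intercept is unconstrained")
    V = np.vander(v, degree + 1, increasing=True)
    coef, res, rank, _ = np.linalg.lstsq(V, g, rcond=None)
    dof = len(v) - (degree + 1)
    if dof > 0:
        resid = g - V @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(V.T @ V)
        se = float(np.sqrt(cov[0, 0]))
    else:
        se = 0.0
    return float(coef[0]), se


def peel_energy(curve) -> float:
    """Total energy (J) to peel a device: trapezoidal integral of force over
    displacement.  Displacement must be strictly increasing."""
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least two (displacement, force) points")
    d, f = arr[:, 0], arr[:, 1]
    if np.any(np.diff(d) <= 0):
        raise ValueError("displacement must be strictly increasing")
    return float(np.trapezoid(f, d))
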