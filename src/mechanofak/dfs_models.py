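"""Single-barrier free-energy-landscape models for dynamic force spectroscopy.

A one-dimensional reaction coordinate crosses a single activation barrier of
height ``deltaG`` (in units of the thermal energy) located ``x_b`` nanometres
from the bound minimum, with effective diffusivity ``D``.  Two classical
landscape shapes are supported:

* ``cusp`` -- harmonic well truncated by an absorbing cusp at the barrier,
* ``linear-cubic`` -- smooth cubic polynomial with matched well/barrier
  curvatures.

Under a force ``F`` the barrier is lowered; the escape rate follows the
one-parameter family

.. math::

    k(F) = k_0\,(1 - \nu F x_b/\Delta G)^{1/\nu - 1}
           \exp\{\beta\Delta G\,[1 - (1 - \nu F x_b/\Delta G)^{1/\nu}]\},

with :math:`\nu = 1/2` (cusp) or :math:`\nu = 2/3` (linear-cubic), and
:math:`k_0` the zero-force Kramers rate built from ``D`` and the curvatures
implied by ``(deltaG, x_b)``.  The Bell model is the :math:`\nu \to 1`
(phenomenological) limit :math:`k(F) = k_0 e^{\beta F x_b}`.

Constant-velocity pulling through a harmonic transducer loads the bond at a
rate :math:`\dot F = \text{stiffness\_factor}\cdot\kappa_s v`, and the
rupture-force statistics follow the quasi-adiabatic first-passage
construction

.. math::

    p(F) = \frac{k(F)}{\dot F}\exp\Big(-\frac{1}{\dot F}\int_0^F k(F')\,dF'\Big).

The barrier vanishes at :math:`F_c = \Delta G/(\nu x_b)`; force grids stop
1% below it, and the probability of surviving past the grid is reported as a
*survival deficit* rather than silently renormalised away.  Means and
standard deviations are therefore conditional on rupture within the
admissible (sub-critical) force range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

__all__ = [
    "KB_PN_NM_PER_K",
    "KJ_PER_MOL_NM2_TO_PN_PER_NM",
    "LandscapeParams",
    "PullingProtocol",
    "ModelKind",
    "LandscapeShape",
    "RuptureForceDensity",
    "stiffness_from_kjmol",
    "thermal_energy",
    "intrinsic_rate",
    "barrier_vanishing_force",
    "force_dependent_rate",
    "default_force_grid",
    "rupture_force_distribution",
    "mean_rupture_force",
]

# Boltzmann constant in pN nm / K (1 pN nm = 1e-21 J).
KB_PN_NM_PER_K = 1.380649e-23 / 1e-21

# 1 kJ mol^-1 nm^-2 in pN/nm:  1e3 J / N_A / 1e-21 J per pN nm.
KJ_PER_MOL_NM2_TO_PN_PER_NM = 1e3 / 6.02214076e23 / 1e-21


class ValidationError(ValueError):
    """Raised when model parameters violate their physical domain."""


class OutOfRegimeError(ValueError):
    """Raised when a force at/beyond the barrier-vanishing point is requested."""


def thermal_energy(temperature: float) -> float:
    """k_B*T in pN nm for a temperature in kelvin."""
    if not np.isfinite(temperature) or temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature!r}")
    return KB_PN_NM_PER_K * temperature


def stiffness_from_kjmol(kappa: float) -> float:
    """Convert a spring stiffness from kJ mol^-1 nm^-2 to pN/nm.

    The conversion constant is 1.66054 pN nm per kJ/mol (CODATA N_A).
    """
    if kappa < 0 or not np.isfinite(kappa):
        raise ValidationError(f"stiffness must be non-negative, got {kappa!r}")
    return kappa * KJ_PER_MOL_NM2_TO_PN_PER_NM


class ModelKind(str, Enum):
    """Which rupture-force theory evaluates the landscape."""

    BELL = "bell"
    HS = "hs"
    BSK = "bsk"


class LandscapeShape(str, Enum):
    """Barrier shape of the one-dimensional free-energy profile."""

    CUSP = "cusp"
    LINEAR_CUBIC = "linear-cubic"


#: nu exponent of the Dudko-Hummer-Szabo rate family per shape.
_NU = {LandscapeShape.CUSP: 0.5, LandscapeShape.LINEAR_CUBIC: 2.0 / 3.0}

#: Default shape per model kind.  The Hummer-Szabo branch defaults to the
#: smooth linear-cubic profile; the BSK branch is the harmonic-well/cusp
#: landscape by construction; Bell inherits the default shape's k0.
_DEFAULT_SHAPE = {
    ModelKind.BELL: LandscapeShape.LINEAR_CUBIC,
    ModelKind.HS: LandscapeShape.LINEAR_CUBIC,
    ModelKind.BSK: LandscapeShape.CUSP,
}


@dataclass(frozen=True)
class LandscapeParams:
    """Single-barrier landscape parameters.

    Parameters
    ----------
    deltaG : float
        Activation free energy in units of k_B*T.
    x_b : float
        Distance from the bound minimum to the barrier, nm.
    D : float
        Effective diffusivity along the reaction coordinate, nm^2/s.
    temperature : float, default 300
        Temperature in K; the thermal energy k_B*T is computed internally
        in pN nm (4.142 pN nm at 300 K).
    """

    deltaG: float
    x_b: float
    D: float
    temperature: float = 300.0

    def __post_init__(self) -> None:
        for name in ("deltaG", "x_b", "D", "temperature"):
            try:
                v = float(getattr(self, name))
            except (TypeError, ValueError):
                raise ValidationError(f"{name} must be a number, got "
                                      f"{getattr(self, name)!r}") from None
            object.__setattr__(self, name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in pN nm."""
        return thermal_energy(self.temperature)

    @property
    def deltaG_energy(self) -> float:
        """Activation free energy in pN nm."""
        return self.deltaG * self.kT

    def to_dict(self) -> dict:
        return {
            "deltaG_kT": self.deltaG,
            "xb_nm": self.x_b,
            "D_nm2_per_s": self.D,
            "temperature_K": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeParams":
        return cls(
            deltaG=d["deltaG_kT"],
            x_b=d["xb_nm"],
            D=d["D_nm2_per_s"],
            temperature=d.get("temperature_K", 300.0),
        )


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-velocity harmonic-transducer pulling protocol.

    Parameters
    ----------
    kappa_s : float
        Transducer spring stiffness in pN/nm.
    velocity : float
        Pulling velocity in nm/ns.
    stiffness_factor : float, default 1.0
        Dimensionless effective-compliance multiplier in (0, 1]; series
        compliance of the pulled construct reduces the effective loading
        rate below kappa_s * v.
    """

    kappa_s: float
    velocity: float
    stiffness_factor: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.kappa_s) or self.kappa_s <= 0:
            raise ValidationError(f"kappa_s must be positive, got {self.kappa_s!r}")
        if not np.isfinite(self.velocity) or self.velocity < 0:
            raise ValidationError(f"velocity must be >= 0, got {self.velocity!r}")
        if not (0 < self.stiffness_factor <= 1):
            raise ValidationError(
                f"stiffness_factor must be in (0, 1], got {self.stiffness_factor!r}"
            )

    @classmethod
    def from_kjmol(
        cls, kappa_kjmol: float, velocity: float, stiffness_factor: float = 1.0
    ) -> "PullingProtocol":
        """Build a protocol from a stiffness in kJ mol^-1 nm^-2."""
        return cls(stiffness_from_kjmol(kappa_kjmol), velocity, stiffness_factor)

    @property
    def loading_rate(self) -> float:
        """Nominal loading rate Fdot = stiffness_factor * kappa_s * v, pN/s."""
        return self.stiffness_factor * self.kappa_s * self.velocity * 1e9


def _resolve_shape(
    kind: ModelKind | str, shape: Optional[LandscapeShape | str]
) -> LandscapeShape:
    kind = ModelKind(kind)
    if shape is None:
        return _DEFAULT_SHAPE[kind]
    shape = LandscapeShape(shape)
    if kind is ModelKind.BSK and shape is not LandscapeShape.CUSP:
        raise ValidationError("the BSK model is defined on the cusp landscape")
    return shape


def intrinsic_rate(
    params: LandscapeParams,
    kind: ModelKind | str = ModelKind.BSK,
    shape: Optional[LandscapeShape | str] = None,
) -> float:
    """Zero-force Kramers escape rate k0 in 1/s.

    The high-barrier overdamped Kramers rate with prefactor built from D and
    the landscape curvatures implied by (deltaG, x_b):

    * linear-cubic: both curvatures equal ``6 deltaG kT / x_b^2``, giving
      ``k0 = 3 deltaG D / (pi x_b^2) * exp(-deltaG)``;
    * cusp: harmonic well of curvature ``2 deltaG kT / x_b^2`` with an
      absorbing cusp, giving
      ``k0 = 2 D deltaG^{3/2} / (x_b^2 sqrt(pi)) * exp(-deltaG)``

    with ``deltaG`` in units of kT.
    """
    shape = _resolve_shape(kind, shape)
    dG, xb, D = params.deltaG, params.x_b, params.D
    if shape is LandscapeShape.LINEAR_CUBIC:
        prefactor = 3.0 * dG * D / (np.pi * xb**2)
    else:
        prefactor = 2.0 * D * dG**1.5 / (xb**2 * np.sqrt(np.pi))
    return float(prefactor * np.exp(-dG))


def barrier_vanishing_force(
    params: LandscapeParams,
    kind: ModelKind | str = ModelKind.BSK,
    shape: Optional[LandscapeShape | str] = None,
) -> float:
    """Force (pN) at which the barrier of the tilted landscape vanishes.

    ``F_c = deltaG_energy / (nu x_b)``; infinite for the Bell model, which
    has no landscape shape of its own.
    """
    if ModelKind(kind) is ModelKind.BELL:
        return np.inf
    shape = _resolve_shape(kind, shape)
    return params.deltaG_energy / (_NU[shape] * params.x_b)


def force_dependent_rate(
    params: LandscapeParams,
    kind: ModelKind | str,
    force,
    shape: Optional[LandscapeShape | str] = None,
):
    """Escape rate k(F) in 1/s at tensile force ``force`` (pN, scalar or array).

    Bell: ``k0 exp(F x_b / kT)`` exactly.  Cusp / linear-cubic: the
    Dudko-Hummer-Szabo closed form (nu = 1/2 and 2/3 respectively), which
    reduces to Bell to first order in F and to k0 at F = 0.

    Raises
    ------
    OutOfRegimeError
        If any force lies at or beyond the barrier-vanishing point; the
        high-barrier rate theory does not extrapolate into the
        drift-dominated regime.
    """
    kind = ModelKind(kind)
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValidationError("force must be >= 0")
    k0 = intrinsic_rate(params, kind, shape)
    beta_xb = params.x_b / params.kT
    if kind is ModelKind.BELL:
        out = k0 * np.exp(F * beta_xb)
        return float(out) if np.isscalar(force) else out
    sh = _resolve_shape(kind, shape)
    nu = _NU[sh]
    Fc = barrier_vanishing_force(params, kind, sh)
    if np.any(F >= Fc):
        raise OutOfRegimeError(
            f"force {np.max(F):.3g} pN is at/beyond the barrier-vanishing "
            f"force {Fc:.3g} pN of the {sh.value} landscape"
        )
    u = 1.0 - nu * F * params.x_b / params.deltaG_energy
    out = k0 * u ** (1.0 / nu - 1.0) * np.exp(params.deltaG * (1.0 - u ** (1.0 / nu)))
    return float(out) if np.isscalar(force) else out


def default_force_grid(
    params: LandscapeParams,
    kind: ModelKind | str,
    shape: Optional[LandscapeShape | str] = None,
    n: int = 4000,
) -> np.ndarray:
    """Uniform force grid from 0 to 1% below the barrier-vanishing force.

    The Bell model has no finite critical force; its grid extends to the
    smallest F_c among the landscape shapes so that cross-model comparisons
    share a domain.
    """
    if n < 2000:
        raise ValidationError("force grid needs >= 2000 points for quadrature")
    kind = ModelKind(kind)
    if kind is ModelKind.BELL:
        Fc = params.deltaG_energy / params.x_b  # nu = 1 formal limit
    else:
        Fc = barrier_vanishing_force(params, kind, shape)
    return np.linspace(0.0, 0.99 * Fc, n)


@dataclass(frozen=True)
class RuptureForceDensity:
    """First-passage rupture-force density on a force grid.

    ``density`` integrates to ``1 - survival_deficit``; the deficit is the
    probability of surviving past the end of the grid (drift-dominated
    ruptures the quasi-adiabatic theory does not resolve).
    """

    force: np.ndarray
    density: np.ndarray
    survival_deficit: float
    loading_rate: float
    survival: np.ndarray = field(repr=False, default=None)

    def conditional_moments(self) -> tuple[float, float]:
        """Mean and sd (pN) conditional on rupture within the grid."""
        mass = simpson(self.density, x=self.force)
        if mass <= 0:
            raise ValidationError("no rupture probability mass on the grid")
        m = simpson(self.force * self.density, x=self.force) / mass
        m2 = simpson(self.force**2 * self.density, x=self.force) / mass
        return float(m), float(np.sqrt(max(m2 - m**2, 0.0)))


def rupture_force_distribution(
    params: LandscapeParams,
    kind: ModelKind | str,
    protocol: PullingProtocol,
    force_grid: Optional[np.ndarray] = None,
    shape: Optional[LandscapeShape | str] = None,
) -> RuptureForceDensity:
    """Rupture-force density under a constant loading ramp.

    Implements ``p(F) = k(F)/Fdot * exp(-(1/Fdot) int_0^F k)``, with the
    cumulative hazard evaluated by composite Simpson quadrature on the
    supplied (or default, >= 4000-point) force grid.
    """
    if protocol.velocity == 0:
        raise ValidationError("zero pulling velocity: no force ramp, no rupture density")
    if force_grid is None:
        force_grid = default_force_grid(params, kind, shape)
    F = np.asarray(force_grid, dtype=float)
    if F.ndim != 1 or F.size < 3 or np.any(np.diff(F) <= 0):
        raise ValidationError("force grid must be 1-D and strictly increasing")
    k = force_dependent_rate(params, kind, F, shape)
    Fdot = protocol.loading_rate
    hazard = cumulative_simpson(k, x=F, initial=0.0)
    S = np.exp(-hazard / Fdot)
    density = k * S / Fdot
    return RuptureForceDensity(
        force=F,
        density=density,
        survival_deficit=float(S[-1]),
        loading_rate=Fdot,
        survival=S,
    )


def mean_rupture_force(
    params: LandscapeParams,
    kind: ModelKind | str,
    protocol: PullingProtocol,
    shape: Optional[LandscapeShape | str] = None,
) -> tuple[float, float]:
    """Mean and standard deviation (pN) of the rupture force.

    Moments are taken over the admissible force range, conditional on
    rupture before the barrier vanishes; the excluded mass is available
    from :func:`rupture_force_distribution` as ``survival_deficit``.
    """
    dist = rupture_force_distribution(params, kind, protocol, shape=shape)
    return dist.conditional_moments()
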