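"""Landscape-parameter estimation from rupture-force spectra.

Three estimation routes over the (deltaG, x_b, D) landscape triple:

* constrained least squares on the per-loading-rate mean rupture forces,
  optionally subject to a thermal-stability bound on the spontaneous rate
  (k0 <= k0_max);
* an RMSD error surface over (deltaG, x_b) with the diffusivity profiled
  out, which exposes the characteristic degeneracy ridge: many (deltaG, D)
  combinations fit the mean-force curve equally well, while x_b is pinned
  by the force scale kT/x_b;
* a Bayesian grid posterior built from the per-event first-passage
  rupture-force density, under a logarithmic (Jeffreys-like) or uniform
  prior, with highest-mass 50%/95% credible regions.

Because the escape rate is proportional to D, the per-cell profile over D
and the event likelihood reuse a single rate evaluation per (deltaG, x_b)
cell: k(F) = D*g(F) with g independent of D.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import minimize
from scipy.stats import qmc

from .dfs_models import (
    LandscapeParams,
    ModelKind,
    PullingProtocol,
    ValidationError,
    barrier_vanishing_force,
    force_dependent_rate,
    intrinsic_rate,
)

__all__ = [
    "RuptureDataset",
    "FitResult",
    "ErrorSurface",
    "PosteriorGrid",
    "DEFAULT_BOUNDS",
    "default_grids",
    "model_mean_curve",
    "fit_least_squares",
    "error_surface",
    "posterior",
]

#: Optimizer/grid brackets: generous around all printed fits
#: (14.2-28.5 kT, 0.3-0.86 nm, 1e6-1.2e7 nm^2/s).
DEFAULT_BOUNDS = {"deltaG": (5.0, 60.0), "x_b": (0.1, 2.0), "D": (1e4, 1e9)}

_OPTIMIZER_SEED = 20151106


def default_grids(
    n_deltaG: int = 111, n_xb: int = 96, n_D: int = 51
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Default (deltaG, x_b, log-spaced D) grids bracketing the printed fits."""
    return (
        np.linspace(*DEFAULT_BOUNDS["deltaG"], n_deltaG),
        np.linspace(*DEFAULT_BOUNDS["x_b"], n_xb),
        np.geomspace(*DEFAULT_BOUNDS["D"], n_D),
    )


# ---------------------------------------------------------------------------
# Dataset


class RuptureDataset:
    """Records of (loading rate, rupture force) from pulling runs.

    Wraps a DataFrame with columns ``loading_rate_pN_per_s``,
    ``rupture_force_pN`` and optional ``velocity_nm_per_ns``, ``run_id``.
    """

    REQUIRED = ("loading_rate_pN_per_s", "rupture_force_pN")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"dataset missing columns {missing}")
        if len(frame) == 0:
            raise ValidationError("empty rupture dataset")
        if (frame["rupture_force_pN"] <= 0).any():
            raise ValidationError("all rupture forces must be positive")
        if (frame["loading_rate_pN_per_s"] <= 0).any():
            raise ValidationError("all loading rates must be positive")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(
        cls,
        loading_rate: Sequence[float],
        rupture_force: Sequence[float],
        velocity: Optional[Sequence[float]] = None,
        run_id: Optional[Sequence] = None,
    ) -> "RuptureDataset":
        data = {
            "loading_rate_pN_per_s": np.asarray(loading_rate, dtype=float),
            "rupture_force_pN": np.asarray(rupture_force, dtype=float),
        }
        if velocity is not None:
            data["velocity_nm_per_ns"] = np.asarray(velocity, dtype=float)
        if run_id is not None:
            data["run_id"] = list(run_id)
        return cls(pd.DataFrame(data))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RuptureDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, index=False)

    def group_means(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-loading-rate (rates, mean forces, counts), rates ascending."""
        g = (
            self.frame.groupby("loading_rate_pN_per_s")["rupture_force_pN"]
            .agg(["mean", "count"])
            .sort_index()
        )
        return (
            g.index.to_numpy(dtype=float),
            g["mean"].to_numpy(dtype=float),
            g["count"].to_numpy(dtype=int),
        )


# ---------------------------------------------------------------------------
# Model curve evaluation (D-scaled)


def _scaled_rate_grid(
    deltaG: float,
    x_b: float,
    kind: ModelKind | str,
    temperature: float,
    n_grid: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force grid to 0.99*F_c plus g = k/D and its cumulative integral G."""
    unit = LandscapeParams(deltaG, x_b, 1.0, temperature)  # rate scales with D
    Fc = barrier_vanishing_force(unit, kind)
    F = np.linspace(0.0, 0.99 * Fc, n_grid)
    g = force_dependent_rate(unit, kind, F)
    G = cumulative_simpson(g, x=F, initial=0.0)
    return F, g, G


def model_mean_curve(
    params: LandscapeParams,
    kind: ModelKind | str,
    loading_rates: Sequence[float],
    n_grid: int = 2001,
) -> np.ndarray:
    """Conditional mean rupture force (pN) at each loading rate (pN/s)."""
    rates = np.asarray(loading_rates, dtype=float)
    F, g, G = _scaled_rate_grid(params.deltaG, params.x_b, kind, params.temperature, n_grid)
    # w ~ density up to a constant factor; conditional mean is a ratio.
    expo = -params.D * G[None, :] / rates[:, None]
    w = g[None, :] * np.exp(expo - expo.max(axis=1, keepdims=True))
    num = simpson(F[None, :] * w, x=F, axis=1)
    den = simpson(w, x=F, axis=1)
    return num / den


# ---------------------------------------------------------------------------
# Constrained least squares


@dataclass
class FitResult:
    """Outcome of a rupture-spectrum fit."""

    params: LandscapeParams
    kind: ModelKind
    rmsd_force: float
    k0: float
    constraint_active: bool
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "model": self.kind.value,
            "rmsd_force_pN": self.rmsd_force,
            "k0_per_s": self.k0,
            "constraint_active": self.constraint_active,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if not isinstance(v, np.ndarray)
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _log_k0(log_theta: np.ndarray, kind: ModelKind | str, temperature: float) -> float:
    dG, xb, D = np.exp(log_theta)
    return float(np.log(intrinsic_rate(LandscapeParams(dG, xb, D, temperature), kind)))


def fit_least_squares(
    data: RuptureDataset,
    kind: ModelKind | str = ModelKind.BSK,
    protocol: Optional[PullingProtocol] = None,
    k0_max: Optional[float] = None,
    n_starts: int = 16,
    temperature: float = 300.0,
    bounds: Optional[dict] = None,
    n_grid: int = 2001,
    seed: int = _OPTIMIZER_SEED,
) -> FitResult:
    """Least-squares landscape fit to per-loading-rate mean rupture forces.

    Minimizes the RMSD between the model's conditional mean-force curve and
    the per-rate group means over (log deltaG, log x_b, log D), via
    multi-start SLSQP from a Latin-hypercube of ``n_starts`` points (fixed
    seed for deterministic refits).  When ``k0_max`` is supplied the
    spontaneous rate is constrained to ``intrinsic_rate <= k0_max``
    (thermal-stability requirement); relaxing the constraint can only lower
    the attained RMSD.

    The objective has a long degeneracy ridge (many landscapes predict
    nearly the same mean-force curve) that can leave the search box; a
    candidate pinned to the box boundary is then an artifact of where the
    box ends, not an estimate.  Among candidates whose RMSD ties within the
    statistical resolution of the objective (propagated from the per-rate
    standard errors; exactly zero for noiseless data), solutions in the
    interior -- or on the physical ``k0_max`` constraint -- are therefore
    preferred over box-pinned ones.

    ``protocol`` is accepted for interface symmetry with the spectrum
    generators; the loading rates themselves come from the dataset.
    """
    kind = ModelKind(kind)
    rates, means, counts = data.group_means()
    if rates.size < 2:
        raise ValidationError("need >= 2 distinct loading rates to fit")
    if k0_max is not None and k0_max <= 0:
        raise ValidationError("k0_max must be positive")
    b = dict(DEFAULT_BOUNDS, **(bounds or {}))
    lo = np.log([b["deltaG"][0], b["x_b"][0], b["D"][0]])
    hi = np.log([b["deltaG"][1], b["x_b"][1], b["D"][1]])

    def objective(log_theta: np.ndarray) -> float:
        dG, xb, D = np.exp(log_theta)
        try:
            model = model_mean_curve(
                LandscapeParams(dG, xb, D, temperature), kind, rates, n_grid
            )
        except (ValidationError, FloatingPointError):
            return 1e6
        return float(np.sqrt(np.mean((model - means) ** 2)))

    constraints = []
    if k0_max is not None:
        constraints.append(
            {
                "type": "ineq",
                "fun": lambda lt: np.log(k0_max) - _log_k0(lt, kind, temperature),
            }
        )

    # statistical resolution of the RMSD objective: per-rate standard errors
    # propagated to the rmsd scale (zero for noiseless data)
    g = data.frame.groupby("loading_rate_pN_per_s")["rupture_force_pN"]
    se2 = [
        float(v.var(ddof=1)) / len(v) for _, v in g if len(v) >= 2
    ]
    tie_tol = float(np.sqrt(np.mean(se2) / (2.0 * rates.size))) if se2 else 0.0

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    candidates = []
    n_converged = 0
    with np.errstate(over="ignore", under="ignore"):
        for x0 in starts:
            if k0_max is not None and _log_k0(x0, kind, temperature) > np.log(k0_max):
                # project the start into the feasible region by raising deltaG
                for _ in range(60):
                    x0 = x0 + np.array([0.05, 0.0, 0.0])
                    if x0[0] > hi[0] or _log_k0(x0, kind, temperature) <= np.log(k0_max):
                        break
                x0 = np.minimum(x0, hi)
            res = minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=list(zip(lo, hi)),
                constraints=constraints,
                options={"maxiter": 300, "ftol": 1e-10},
            )
            feasible = k0_max is None or _log_k0(res.x, kind, temperature) <= np.log(
                k0_max
            ) + 1e-6
            if res.success:
                n_converged += 1
            if feasible:
                pinned = bool(
                    np.any(res.x - lo < 1e-4) or np.any(hi - res.x < 1e-4)
                )
                candidates.append((res, pinned))
    if not candidates:
        raise RuntimeError("no feasible optimum found; best-so-far unavailable")
    best_fun = min(res.fun for res, _ in candidates)
    unpinned = [
        res
        for res, pinned in candidates
        if not pinned and res.fun <= best_fun + tie_tol
    ]
    pool = unpinned if unpinned else [res for res, _ in candidates]
    best = min(pool, key=lambda r: r.fun)
    dG, xb, D = np.exp(best.x)
    params = LandscapeParams(dG, xb, D, temperature)
    k0 = intrinsic_rate(params, kind)
    active = k0_max is not None and np.log(k0) > np.log(k0_max) - 1e-3
    if n_converged == 0:
        warnings.warn(
            f"optimizer did not report convergence from any start; "
            f"returning best-so-far (rmsd={best.fun:.3g} pN)"
        )
    return FitResult(
        params=params,
        kind=kind,
        rmsd_force=float(best.fun),
        k0=float(k0),
        constraint_active=bool(active),
        diagnostics={
            "n_starts": n_starts,
            "n_converged": n_converged,
            "n_loading_rates": int(rates.size),
            "n_events": int(len(data)),
            "success": bool(best.success),
            "tie_tolerance_pN": tie_tol,
            "box_pinned": bool(unpinned == [] and len(candidates) > 0 and
                               min(candidates, key=lambda c: c[0].fun)[1]),
        },
    )


# ---------------------------------------------------------------------------
# Error surface


@dataclass
class ErrorSurface:
    """RMSD over (deltaG, x_b) with D profiled out, plus rate-gain contours."""

    deltaG_grid: np.ndarray
    xb_grid: np.ndarray
    rmsd: np.ndarray  # (n_dG, n_xb) pN, minimal over the D grid
    best_D: np.ndarray  # (n_dG, n_xb) argmin diffusivity
    rate_gain_50pN: np.ndarray  # k(50 pN)/k0 per cell (D-independent)

    @property
    def argmin(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmin(self.rmsd), self.rmsd.shape))


def error_surface(
    data: RuptureDataset,
    kind: ModelKind | str = ModelKind.BSK,
    protocol: Optional[PullingProtocol] = None,
    deltaG_grid: Optional[np.ndarray] = None,
    xb_grid: Optional[np.ndarray] = None,
    D_grid: Optional[np.ndarray] = None,
    temperature: float = 300.0,
    n_grid: int = 1201,
) -> ErrorSurface:
    """Map the fit RMSD over a (deltaG, x_b) grid, minimizing over D per cell.

    Also evaluates the force-induced rate gain k(50 pN)/k0 per cell, the
    quantity contoured alongside the good-fit region; it is independent of
    D because the rate is proportional to the diffusivity.
    """
    kind = ModelKind(kind)
    if deltaG_grid is None or xb_grid is None or D_grid is None:
        dg_d, xb_d, D_d = default_grids()
        deltaG_grid = dg_d if deltaG_grid is None else np.asarray(deltaG_grid, float)
        xb_grid = xb_d if xb_grid is None else np.asarray(xb_grid, float)
        D_grid = D_d if D_grid is None else np.asarray(D_grid, float)
    for name, g in (("deltaG", deltaG_grid), ("x_b", xb_grid), ("D", D_grid)):
        if len(g) == 0:
            raise ValidationError(f"empty {name} grid")
        if len(g) > 1 and np.any(np.diff(g) <= 0):
            raise ValidationError(f"{name} grid must be strictly increasing")
    rates, means, _ = data.group_means()
    if rates.size < 2:
        raise ValidationError("need >= 2 distinct loading rates")

    rmsd = np.empty((deltaG_grid.size, xb_grid.size))
    bestD = np.empty_like(rmsd)
    gain = np.empty_like(rmsd)
    D = np.asarray(D_grid, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        for i, dG in enumerate(deltaG_grid):
            for j, xb in enumerate(xb_grid):
                F, g, G = _scaled_rate_grid(dG, xb, kind, temperature, n_grid)
                unit = LandscapeParams(dG, xb, 1.0, temperature)
                Fc = barrier_vanishing_force(unit, kind)
                gain[i, j] = (
                    force_dependent_rate(unit, kind, 50.0) / g[0]
                    if 50.0 < 0.99 * Fc
                    else np.inf
                )
                # (n_D, n_rates, n_F) survival exponents via D/Fdot scaling
                expo = -np.einsum("d,rf->drf", D, G[None, :] / rates[:, None])
                w = g[None, None, :] * np.exp(expo - expo.max(axis=2, keepdims=True))
                num = simpson(F[None, None, :] * w, x=F, axis=2)
                den = simpson(w, x=F, axis=2)
                resid = num / den - means[None, :]
                cell = np.sqrt(np.mean(resid**2, axis=1))
                l = int(np.argmin(cell))
                rmsd[i, j] = cell[l]
                bestD[i, j] = D[l]
    return ErrorSurface(
        deltaG_grid=np.asarray(deltaG_grid, float),
        xb_grid=np.asarray(xb_grid, float),
        rmsd=rmsd,
        best_D=bestD,
        rate_gain_50pN=gain,
    )


# ---------------------------------------------------------------------------
# Bayesian grid posterior


@dataclass
class PosteriorGrid:
    """Normalized grid posterior over (deltaG, x_b, D) with credible regions."""

    deltaG_grid: np.ndarray
    xb_grid: np.ndarray
    D_grid: np.ndarray
    prior: str
    mass: np.ndarray  # (n_dG, n_xb, n_D), sums to 1
    boundary_mass: float
    boundary_warning: bool

    @property
    def joint_deltaG_xb(self) -> np.ndarray:
        """D integrated out; (n_dG, n_xb), sums to 1."""
        return self.mass.sum(axis=2)

    @property
    def marginal_deltaG(self) -> np.ndarray:
        return self.mass.sum(axis=(1, 2))

    @property
    def marginal_xb(self) -> np.ndarray:
        return self.mass.sum(axis=(0, 2))

    def highest_mass_region(self, level: float, which: str = "joint") -> np.ndarray:
        """Boolean mask of the smallest cell set holding >= ``level`` mass."""
        if which == "joint":
            m = self.joint_deltaG_xb
        elif which == "deltaG":
            m = self.marginal_deltaG
        elif which == "xb":
            m = self.marginal_xb
        else:
            raise ValidationError(f"unknown marginal {which!r}")
        order = np.argsort(m, axis=None)[::-1]
        cum = np.cumsum(m.ravel()[order])
        n_in = int(np.searchsorted(cum, level) + 1)
        mask = np.zeros(m.size, dtype=bool)
        mask[order[:n_in]] = True
        return mask.reshape(m.shape)

    def contains(self, deltaG: float, x_b: float, level: float = 0.95) -> bool:
        """Does the joint (deltaG, x_b) credible region cover a given point?"""
        mask = self.highest_mass_region(level, "joint")
        i = int(np.argmin(np.abs(self.deltaG_grid - deltaG)))
        j = int(np.argmin(np.abs(self.xb_grid - x_b)))
        return bool(mask[i, j])

    def map_estimate(self) -> tuple[float, float, float]:
        i, j, l = np.unravel_index(np.argmax(self.mass), self.mass.shape)
        return (
            float(self.deltaG_grid[i]),
            float(self.xb_grid[j]),
            float(self.D_grid[l]),
        )

    def to_frame(self) -> pd.DataFrame:
        dg, xb, D = np.meshgrid(
            self.deltaG_grid, self.xb_grid, self.D_grid, indexing="ij"
        )
        return pd.DataFrame(
            {
                "deltaG_kT": dg.ravel(),
                "xb_nm": xb.ravel(),
                "D_nm2_per_s": D.ravel(),
                "mass": self.mass.ravel(),
            }
        )


def _cell_widths(grid: np.ndarray) -> np.ndarray:
    if grid.size == 1:
        return np.ones(1)
    return np.gradient(grid)


def posterior(
    data: RuptureDataset,
    kind: ModelKind | str = ModelKind.BSK,
    protocol: Optional[PullingProtocol] = None,
    prior: str = "logarithmic",
    deltaG_grid: Optional[np.ndarray] = None,
    xb_grid: Optional[np.ndarray] = None,
    D_grid: Optional[np.ndarray] = None,
    likelihood: str = "events",
    temperature: float = 300.0,
    n_grid: int = 1201,
) -> PosteriorGrid:
    """Grid posterior over (deltaG, x_b, D) from a rupture-force spectrum.

    The default likelihood is the product over events of the first-passage
    rupture-force density at each event's loading rate, conditioned on
    rupture within the sub-critical force range (events beyond the
    barrier-vanishing force of a candidate landscape have zero likelihood
    there).  ``likelihood="gaussian"`` substitutes unweighted Gaussian
    residuals of the per-rate means, which makes the uniform-prior MAP
    coincide with the least-squares optimum.

    Priors: ``logarithmic`` p ~ 1/(deltaG * x_b * D) or ``uniform``.
    Posterior cell masses include the local cell volume, so log-spaced and
    linear grids are treated consistently.  If more than 5% of the mass
    sits on the grid boundary, the result carries a warning flag.
    """
    kind = ModelKind(kind)
    if prior not in ("logarithmic", "uniform"):
        raise ValidationError(f"unknown prior {prior!r}")
    if likelihood not in ("events", "gaussian"):
        raise ValidationError(f"unknown likelihood {likelihood!r}")
    dg_d, xb_d, D_d = default_grids()
    dG_g = dg_d if deltaG_grid is None else np.asarray(deltaG_grid, float)
    xb_g = xb_d if xb_grid is None else np.asarray(xb_grid, float)
    D_g = D_d if D_grid is None else np.asarray(D_grid, float)

    F_e = data.frame["rupture_force_pN"].to_numpy()
    R_e = data.frame["loading_rate_pN_per_s"].to_numpy()
    rates, means, _ = data.group_means()

    loglik = np.full((dG_g.size, xb_g.size, D_g.size), -np.inf)
    with np.errstate(over="ignore", under="ignore", divide="ignore"):
        for i, dG in enumerate(dG_g):
            for j, xb in enumerate(xb_g):
                F, g, G = _scaled_rate_grid(dG, xb, kind, temperature, n_grid)
                if likelihood == "events":
                    if F_e.max() >= F[-1]:
                        continue  # an event beyond this cell's critical force
                    g_e = np.interp(F_e, F, g)
                    G_e = np.interp(F_e, F, G)
                    # (n_D, n_e)
                    A = D_g[:, None] * (G_e[None, :] / R_e[None, :])
                    A_end = D_g[:, None] * (G[-1] / R_e[None, :])
                    log_norm = np.log1p(-np.exp(-A_end))
                    ll = (
                        np.sum(np.log(g_e / R_e))
                        + F_e.size * np.log(D_g)
                        - A.sum(axis=1)
                        - log_norm.sum(axis=1)
                    )
                else:
                    expo = -D_g[None, :, None] * (
                        G[None, None, :] / rates[:, None, None]
                    )
                    w = g[None, None, :] * np.exp(
                        expo - expo.max(axis=2, keepdims=True)
                    )
                    num = simpson(F[None, None, :] * w, x=F, axis=2)
                    den = simpson(w, x=F, axis=2)
                    ll = -0.5 * np.sum((num / den - means[:, None]) ** 2, axis=0)
                loglik[i, j] = ll

    dg3, xb3, D3 = np.meshgrid(dG_g, xb_g, D_g, indexing="ij")
    logvol = (
        np.log(_cell_widths(dG_g))[:, None, None]
        + np.log(_cell_widths(xb_g))[None, :, None]
        + np.log(_cell_widths(D_g))[None, None, :]
    )
    logprior = 0.0 if prior == "uniform" else -(np.log(dg3) + np.log(xb3) + np.log(D3))
    logmass = loglik + logprior + logvol
    m = logmass.max()
    if not np.isfinite(m):
        raise ValidationError("zero likelihood everywhere on the grid")
    mass = np.exp(logmass - m)
    mass /= mass.sum()

    edge = np.zeros_like(mass, dtype=bool)
    edge[0], edge[-1] = True, True
    edge[:, 0], edge[:, -1] = True, True
    edge[:, :, 0], edge[:, :, -1] = True, True
    boundary_mass = float(mass[edge].sum())
    warn = boundary_mass > 0.05
    if warn:
        warnings.warn(
            f"{boundary_mass:.1%} of posterior mass on the grid boundary; "
            "widen the grids"
        )
    return PosteriorGrid(
        deltaG_grid=dG_g,
        xb_grid=xb_g,
        D_grid=D_g,
        prior=prior,
        mass=mass,
        boundary_mass=boundary_mass,
        boundary_warning=bool(warn),
    )
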