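"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the pulling campaign the analysis assumes: 13
pulling velocities log-spaced over 6e-3 to 1 nm/ns through a harmonic
transducer of 250 kJ mol^-1 nm^-2, 83 runs in total, rupture forces drawn
from the landscape's first-passage statistics, force traces with a
two-step interface-area collapse (intermediate plateau in the 1.5-2.8 nm^2
band), per-residue stress drops tied to the two rupture steps, and
two-domain atom clouds at controlled separation for the geometry
observables.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dfs_models import (
    LandscapeParams,
    ModelKind,
    PullingProtocol,
    ValidationError,
    rupture_force_distribution,
    stiffness_from_kjmol,
)
from .dfs_fitting import RuptureDataset
from .rupture_events import ForceTrace
from .structural_observables import CoordinateSet, StressMatrix

__all__ = [
    "ProtocolSpec",
    "TraceTruth",
    "sample_rupture_forces",
    "synth_force_trace",
    "synth_stress_matrix",
    "synth_two_domain_coordinates",
]

PAPER_KAPPA_KJMOL = 250.0
N_VELOCITIES = 13
N_RUNS_TOTAL = 83


def _default_velocities() -> np.ndarray:
    return np.geomspace(6e-3, 1.0, N_VELOCITIES)


def _default_allocation(n_velocities: int, total: int) -> np.ndarray:
    """Near-even run allocation; the remainder goes to the slowest pulls.

    83 runs over 13 velocities = 6 each plus one extra for the 5 slowest
    velocities (slow pulls carry the most information about the barrier).
    """
    base, extra = divmod(total, n_velocities)
    runs = np.full(n_velocities, base, dtype=int)
    runs[:extra] += 1
    return runs


@dataclass
class ProtocolSpec:
    """Pulling campaign: which velocities, how many runs, what stiffness."""

    velocities: np.ndarray = field(default_factory=_default_velocities)
    runs_per_velocity: Optional[Sequence[int]] = None
    kappa_s: float = stiffness_from_kjmol(PAPER_KAPPA_KJMOL)
    stiffness_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if np.any(self.velocities <= 0):
            raise ValidationError("velocities must be positive")
        if self.runs_per_velocity is None:
            self.runs_per_velocity = _default_allocation(
                self.velocities.size, N_RUNS_TOTAL
            )
        self.runs_per_velocity = np.asarray(self.runs_per_velocity, dtype=int)
        if self.runs_per_velocity.size != self.velocities.size:
            raise ValidationError("runs_per_velocity must match velocities")
        if self.runs_per_velocity.sum() < 1:
            raise ValidationError("total runs must be >= 1")

    def protocol(self, velocity: float) -> PullingProtocol:
        return PullingProtocol(self.kappa_s, velocity, self.stiffness_factor)


def _invert_survival(
    dist, u: np.ndarray
) -> np.ndarray:
    """Inverse-transform draws from the conditional rupture-force law.

    The survival function is S(F) = exp(-hazard/Fdot); conditioning on
    rupture within the admissible grid maps u ~ U(0,1) onto
    S in (S_end, 1), inverted on the precomputed hazard grid.
    """
    S_end = dist.survival_deficit
    s_target = 1.0 - u * (1.0 - S_end)
    hazard_target = -np.log(s_target) * dist.loading_rate
    hazard = -np.log(np.clip(dist.survival, 1e-300, None)) * dist.loading_rate
    return np.interp(hazard_target, hazard, dist.force)


def sample_rupture_forces(
    landscape: LandscapeParams,
    kind: ModelKind | str,
    spec: Optional[ProtocolSpec] = None,
) -> RuptureDataset:
    """Draw a rupture-force spectrum from the first-passage statistics.

    One inverse-transform draw per run, conditional on rupture within the
    sub-critical force range of the landscape (at fast pulling a fraction
    of the first-passage mass lies beyond it; conditioning mirrors the
    convention of the analytic moments).  Reproducible: the dataset is a
    pure function of ``spec.seed``.
    """
    if spec is None:
        spec = ProtocolSpec()
    rng = np.random.default_rng(spec.seed)
    rates, forces, velocities, run_ids = [], [], [], []
    run = 0
    for v, n_runs in zip(spec.velocities, spec.runs_per_velocity):
        if n_runs == 0:
            continue
        protocol = spec.protocol(v)
        dist = rupture_force_distribution(landscape, kind, protocol)
        draws = _invert_survival(dist, rng.random(n_runs))
        for F in draws:
            rates.append(protocol.loading_rate)
            forces.append(F)
            velocities.append(v)
            run_ids.append(f"run{run:03d}")
            run += 1
    return RuptureDataset.from_records(rates, forces, velocities, run_ids)


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth returned alongside a generated pulling trace."""

    rupture_time: float  # ns
    rupture_force: float  # pN
    step1_time: float  # ns, first interface-area drop (= rupture)
    step2_time: float  # ns, final collapse
    area_initial: float  # nm^2
    area_intermediate: float  # nm^2
    loading_rate: float  # pN/s


def synth_force_trace(
    landscape: LandscapeParams,
    kind: ModelKind | str,
    velocity: float,
    kappa_s: Optional[float] = None,
    seed: int = 0,
    noise_sd: float = 5.0,
    n_samples: int = 4000,
) -> tuple[ForceTrace, TraceTruth]:
    """Generate one pulling trace with known rupture and area-step truth.

    Force ramps at kappa_s*v with additive Gaussian noise up to a rupture
    time drawn from the first-passage law, then relaxes exponentially.  The
    interface area starts in the 3-4.5 nm^2 band, drops at rupture to an
    intermediate plateau in 1.5-2.8 nm^2, and collapses to zero at a second
    step; the end-to-end distance tracks the spring with a jump at each
    step.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if kappa_s is None:
        kappa_s = stiffness_from_kjmol(PAPER_KAPPA_KJMOL)
    rng = np.random.default_rng(seed)
    protocol = PullingProtocol(kappa_s, velocity)
    dist = rupture_force_distribution(landscape, kind, protocol)
    F_rup = float(_invert_survival(dist, rng.random(1))[0])
    fdot_ns = protocol.loading_rate * 1e-9  # pN/ns
    t_rup = F_rup / fdot_ns

    t_end = 1.3 * t_rup
    t = np.linspace(0.0, t_end, n_samples)
    ramp = np.where(t <= t_rup, fdot_ns * t, F_rup * np.exp(-(t - t_rup) / (0.02 * t_rup)))
    force = ramp + rng.normal(0.0, noise_sd, t.size)

    a0 = rng.uniform(3.0, 4.5)
    a1 = rng.uniform(1.5, 2.8)
    t_step2 = t_rup + rng.uniform(0.08, 0.15) * t_rup
    area = np.where(t < t_rup, a0, np.where(t < t_step2, a1, 0.0))
    area = np.clip(area + rng.normal(0.0, 0.05, t.size), 0.0, None)

    d_spring = velocity * t
    ee = 4.0 + 0.2 * d_spring + 0.8 * (t >= t_rup) + 1.2 * (t >= t_step2)
    trace = ForceTrace(
        time=t,
        spring_separation=d_spring,
        force=force,
        interface_area=area,
        end_to_end=ee,
        metadata={"velocity_nm_per_ns": velocity, "kappa_s_pN_per_nm": kappa_s,
                  "seed": seed},
    )
    truth = TraceTruth(
        rupture_time=t_rup,
        rupture_force=F_rup,
        step1_time=t_rup,
        step2_time=t_step2,
        area_initial=a0,
        area_intermediate=a1,
        loading_rate=protocol.loading_rate,
    )
    return trace, truth


def synth_stress_matrix(
    n_residues: int = 20,
    event_times: tuple[float, float] = (40.0, 60.0),
    labels: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_times: int = 800,
    t_end: float = 100.0,
    noise_sd: float = 2.0,
    base_stress: float = 80.0,
) -> tuple[StressMatrix, dict]:
    """Per-residue stress traces with known step assignments.

    ``labels`` assigns each residue "step1", "step2", "elsewhere" or
    "none"; by default the four labels cycle.  Labelled residues carry a
    90% stress drop at the corresponding time ("elsewhere" drops midway
    between the events, at a time outside both tolerance windows).
    Residue indices start at 175, inside the FERM-domain window the stress
    analysis scans.
    """
    t1, t2 = event_times
    if not t1 < t2:
        raise ValidationError("event times must satisfy step1 < step2")
    if labels is None:
        labels = [("step1", "step2", "elsewhere", "none")[i % 4] for i in range(n_residues)]
    if len(labels) != n_residues:
        raise ValidationError("labels must match n_residues")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_times)
    drop_time = {"step1": t1, "step2": t2, "elsewhere": 0.5 * (t1 + t2)}
    stress = np.empty((n_residues, n_times))
    for i, lab in enumerate(labels):
        level = base_stress * rng.uniform(0.8, 1.2)
        row = np.full(n_times, level)
        if lab != "none":
            row = np.where(t >= drop_time[lab], 0.1 * level, level)
        stress[i] = row + rng.normal(0.0, noise_sd, n_times)
    residues = np.arange(175, 175 + n_residues)
    matrix = StressMatrix(
        residue_index=residues,
        time=t,
        stress=stress,
        step1_time=t1,
        step2_time=t2,
    )
    return matrix, dict(zip(residues.tolist(), labels))


def synth_two_domain_coordinates(
    n_atoms_per_domain: int = 200,
    separation: float = 1.0,
    seed: int = 0,
    radius_nm: float = 0.17,
    cloud_size: float = 1.5,
) -> CoordinateSet:
    """Two labelled atom clouds ("F2", "C") at a controlled minimum distance.

    Each domain is a uniform ball of atoms; the second is shifted along x
    so that the closest inter-domain atom pair sits exactly ``separation``
    nm apart.
    """
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    rng = np.random.default_rng(seed)

    def ball(n: int) -> np.ndarray:
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        return pts * (cloud_size * rng.random((n, 1)) ** (1 / 3))

    a = ball(n_atoms_per_domain)
    b = ball(n_atoms_per_domain)
    # place B beyond A, then shift so the realized min gap equals `separation`
    b[:, 0] += a[:, 0].max() - b[:, 0].min() + max(separation, 1e-9) + cloud_size
    from scipy.spatial import cKDTree

    # slide B along x until the realized minimum gap matches `separation`;
    # fixed-point iteration because the closest pair can change as B moves
    for _ in range(100):
        gap = cKDTree(b).query(a, k=1)[0].min()
        err = gap - separation
        if abs(err) < 1e-9:
            break
        b[:, 0] -= err
    coords = np.vstack([a, b])
    n = coords.shape[0]
    return CoordinateSet(
        coords=coords,
        radius=np.full(n, radius_nm),
        residue_index=np.arange(1, n + 1),
        groups={
            "F2": np.arange(n_atoms_per_domain),
            "C": np.arange(n_atoms_per_domain, n),
        },
    )
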