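"""Geometry observables on labelled coordinates and stress-drop assignment.

Contacts, minimum inter-group distance and buried solvent-accessible
interface area between named atom groups (e.g. the FERM F2-lobe and the
kinase C-lobe), the inactive/active x bound/unbound state classification,
and the assignment of per-residue punctual-stress drops to the two rupture
steps of the interface collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .dfs_models import ValidationError

__all__ = [
    "CoordinateSet",
    "StressMatrix",
    "StateLabel",
    "ELEMENT_RADII_NM",
    "contact_count",
    "min_distance",
    "buried_interface_area",
    "classify_state",
    "assign_stress_steps",
]

#: Van der Waals radii (nm) used when a structure file supplies none.
ELEMENT_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}
DEFAULT_RADIUS_NM = 0.170


class StateLabel(str, Enum):
    """Conformational/anchoring states of the autoinhibited kinase."""

    INACTIVE = "i"  # FERM-kinase interface intact
    ACTIVE = "a"  # interface open
    BOUND = "b"  # membrane-anchored
    UNBOUND = "u"  # detached from the membrane


@dataclass
class CoordinateSet:
    """Labelled atomic coordinates (nm) with per-atom radii and named groups."""

    coords: np.ndarray  # (n, 3) nm
    radius: np.ndarray  # (n,) nm
    residue_index: np.ndarray  # (n,) 1-based
    groups: dict  # name -> integer index array
    atom_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if np.any(self.radius <= 0):
            raise ValidationError("atom radii must be positive")
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            self.groups[name] = idx
            if idx.size == 0:
                raise ValidationError(f"group {name!r} is empty")

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise ValidationError(
                f"unknown group {name!r}; have {sorted(self.groups)}"
            ) from None

    @classmethod
    def from_pdb(
        cls, path: Union[str, Path], selections: Union[str, Path, dict, None] = None
    ) -> "CoordinateSet":
        """Read ATOM/HETATM records via biotite (first altloc kept).

        ``selections`` maps group name -> {"chain": ..., "residues":
        [[start, stop], ...]} (residue ranges inclusive, 1-based); a YAML or
        JSON file path is accepted.  PDB coordinates (Angstrom) are
        converted to nm and radii assigned per element.
        """
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        pf = pdb.PDBFile.read(str(path))
        atoms = pdb.get_structure(pf, model=1, altloc="first")
        radii = np.array(
            [ELEMENT_RADII_NM.get(e.upper(), DEFAULT_RADIUS_NM) for e in atoms.element]
        )
        if isinstance(selections, (str, Path)):
            selections = yaml.safe_load(Path(selections).read_text())
        groups = {}
        for name, sel in (selections or {}).items():
            mask = np.ones(atoms.array_length(), dtype=bool)
            if isinstance(sel, dict):
                if "chain" in sel:
                    mask &= atoms.chain_id == sel["chain"]
                if sel.get("residues"):
                    rmask = np.zeros_like(mask)
                    for lo, hi in sel["residues"]:
                        rmask |= (atoms.res_id >= lo) & (atoms.res_id <= hi)
                    mask &= rmask
            groups[name] = np.nonzero(mask)[0]
        return cls(
            coords=atoms.coord * 0.1,
            radius=radii,
            residue_index=atoms.res_id.astype(int),
            groups=groups,
        )


@dataclass
class StressMatrix:
    """Per-residue punctual stress time series with the two rupture times."""

    residue_index: np.ndarray  # (R,) 1-based
    time: np.ndarray  # (T,)
    stress: np.ndarray  # (R, T) pN
    step1_time: float
    step2_time: float

    def __post_init__(self) -> None:
        self.stress = np.asarray(self.stress, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.stress.size == 0:
            raise ValidationError("empty stress matrix")
        if self.stress.shape != (self.residue_index.size, self.time.size):
            raise ValidationError("stress must be (n_residues, n_times)")
        if not (self.step1_time < self.step2_time):
            raise ValidationError("step1_time must precede step2_time")
        t0, t1 = self.time[0], self.time[-1]
        if not (t0 <= self.step1_time <= t1 and t0 <= self.step2_time <= t1):
            raise ValidationError("event times outside the time range")

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], step1_time: float, step2_time: float
    ) -> "StressMatrix":
        """CSV: first column residue index, remaining columns = time points."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            residue_index=df.index.to_numpy(dtype=int),
            time=df.columns.to_numpy(dtype=float),
            stress=df.to_numpy(dtype=float),
            step1_time=step1_time,
            step2_time=step2_time,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            self.stress, index=self.residue_index, columns=self.time
        ).to_csv(path)


# ---------------------------------------------------------------------------
# Geometry


def contact_count(
    coords: CoordinateSet,
    groupA: str,
    groupB: str,
    cutoff: float = 0.6,
    symmetric: bool = False,
) -> int:
    """Number of group-A atoms strictly closer than ``cutoff`` (nm) to group B.

    The count is directional (atoms *of A* near B); ``symmetric=True``
    returns the sum of both directions.  Atoms exactly at the cutoff do not
    count (strict inequality).
    """
    ia, ib = coords.group(groupA), coords.group(groupB)
    tree = cKDTree(coords.coords[ib])
    d, _ = tree.query(coords.coords[ia], k=1)
    n = int(np.count_nonzero(d < cutoff))
    if symmetric:
        tree_a = cKDTree(coords.coords[ia])
        d2, _ = tree_a.query(coords.coords[ib], k=1)
        n += int(np.count_nonzero(d2 < cutoff))
    return n


def min_distance(coords: CoordinateSet, groupA: str, groupB: str) -> float:
    """Minimum pairwise Euclidean distance (nm) between two groups."""
    ia, ib = coords.group(groupA), coords.group(groupB)
    tree = cKDTree(coords.coords[ib])
    d, _ = tree.query(coords.coords[ia], k=1)
    return float(np.min(d))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _sasa(xyz: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> float:
    """Shrake-Rupley solvent-accessible surface area (nm^2)."""
    r_ext = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    r_max = float(r_ext.max())
    total = 0.0
    for i in range(xyz.shape[0]):
        pts = xyz[i] + r_ext[i] * unit
        nbr = [j for j in tree.query_ball_point(xyz[i], r_ext[i] + r_max) if j != i]
        if nbr:
            d2 = ((pts[:, None, :] - xyz[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r_ext[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * r_ext[i] ** 2
    return total


def buried_interface_area(
    coords: CoordinateSet,
    groupA: str,
    groupB: str,
    probe: float = 0.14,
    points_per_atom: int = 960,
) -> float:
    """Buried solvent-accessible interface area between two groups, nm^2.

    ``(SASA(A) + SASA(B) - SASA(A u B)) / 2`` with Shrake-Rupley sphere-point
    sampling (default water probe 0.14 nm, 960 points per atom).
    """
    if points_per_atom < 10:
        raise ValidationError("points_per_atom too small for a meaningful area")
    ia, ib = coords.group(groupA), coords.group(groupB)
    xyz, rad = coords.coords, coords.radius
    # Disjoint groups separated beyond reach bury nothing; skip the sampling.
    if min_distance(coords, groupA, groupB) > 2 * (rad.max() + probe):
        return 0.0
    a = _sasa(xyz[ia], rad[ia], probe, points_per_atom)
    b = _sasa(xyz[ib], rad[ib], probe, points_per_atom)
    iu = np.concatenate([ia, ib])
    ab = _sasa(xyz[iu], rad[iu], probe, points_per_atom)
    return max(0.0, 0.5 * (a + b - ab))


def classify_state(N_interface: int, N_membrane: int) -> tuple[StateLabel, StateLabel]:
    """Map contact counts to (interface, anchoring) state labels.

    Interface: inactive ("i") while any F2-C contacts remain, active ("a")
    once the lobes have separated.  Anchoring: bound ("b") while the protein
    keeps membrane contacts, unbound ("u") otherwise.
    """
    if N_interface < 0 or N_membrane < 0:
        raise ValidationError("contact counts must be >= 0")
    interface = StateLabel.INACTIVE if N_interface > 0 else StateLabel.ACTIVE
    anchoring = StateLabel.BOUND if N_membrane > 0 else StateLabel.UNBOUND
    return interface, anchoring


# ---------------------------------------------------------------------------
# Stress-drop step assignment


def assign_stress_steps(
    stress: StressMatrix,
    drop_threshold: float = 0.5,
    time_window: Optional[float] = None,
    level_window: Optional[float] = None,
) -> dict:
    """Label each residue by the rupture step at which its stress collapses.

    For every residue the largest drop between the mean stress over a
    leading window and the mean over a trailing window is located.  If that
    drop is at least ``drop_threshold`` of the pre-drop level, the residue is
    labelled ``"step1"`` or ``"step2"`` when the drop time falls within
    ``time_window`` of the corresponding event time, ``"elsewhere"``
    otherwise; residues without a qualifying drop are ``"none"``.

    Returns ``{residue_index: label}``.
    """
    if not (0 < drop_threshold <= 1):
        raise ValidationError("drop_threshold must be in (0, 1]")
    t = stress.time
    span = t[-1] - t[0]
    if time_window is None:
        time_window = 0.05 * span
    if level_window is None:
        level_window = 0.05 * span
    nw = max(2, int(round(level_window / np.median(np.diff(t)))))

    labels = {}
    for row, res in zip(stress.stress, stress.residue_index):
        n = row.size
        # mean over [i-nw, i) vs [i, i+nw) at every interior sample
        c = np.concatenate([[0.0], np.cumsum(row)])
        idx = np.arange(nw, n - nw)
        pre = (c[idx] - c[idx - nw]) / nw
        post = (c[idx + nw] - c[idx]) / nw
        drops = pre - post
        j = int(np.argmax(drops))
        pre_level = pre[j]
        if pre_level <= 0 or drops[j] < drop_threshold * pre_level:
            labels[int(res)] = "none"
            continue
        t_drop = t[idx[j]]
        if abs(t_drop - stress.step1_time) <= time_window:
            labels[int(res)] = "step1"
        elif abs(t_drop - stress.step2_time) <= time_window:
            labels[int(res)] = "step2"
        else:
            labels[int(res)] = "elsewhere"
    return labels
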