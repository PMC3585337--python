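"""Shrake-Rupley solvent accessible surface area and loop-burial attribution.

Per atom, a quasi-uniform set of points is placed on a sphere of radius
(vdW radius + probe); the accessible fraction of points (not occluded by any
other included atom's probe-expanded sphere) times the sphere area is the
atom's SASA, and residue values sum over heavy atoms.  Hydrogens are
excluded throughout.  Burial attributed to a region (loop LB by default) is
the window-averaged SASA computed without the region's atoms minus the value
computed with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError
from .structures import RegionMap, Structure, Trajectory

__all__ = [
    "SasaParams",
    "BurialRecord",
    "VDW_RADII",
    "sphere_points",
    "sasa_per_residue",
    "burial_by_region",
    "windowed_exposure",
]

#: Bondi-type van der Waals radii (Angstrom) per element
VDW_RADII: dict[str, dict[str, float]] = {
    "bondi": {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
        "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    },
}


@dataclass(frozen=True)
class SasaParams:
    probe_radius_A: float = 1.4
    n_sphere_points: int = 960
    radii_set: str = "bondi"
    custom_radii: Mapping[str, float] | None = field(default=None, hash=False)

    def __post_init__(self):
        if self.probe_radius_A < 0:
            raise InputError("probe radius must be >= 0")
        if self.n_sphere_points < 60:
            raise InputError("need at least 60 sphere points")

    def radii(self) -> Mapping[str, float]:
        if self.custom_radii is not None:
            return self.custom_radii
        try:
            return VDW_RADII[self.radii_set]
        except KeyError:
            raise ConfigError(f"unknown radii set {self.radii_set!r}") from None


@dataclass
class BurialRecord:
    residue_number: int
    window_ps: tuple[float, float]
    sasa_with_A2: float
    sasa_without_A2: float

    @property
    def buried_A2(self) -> float:
        return self.sasa_without_A2 - self.sasa_with_A2


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _atom_radii(struct: Structure, indices: np.ndarray,
                radii: Mapping[str, float]) -> np.ndarray:
    out = np.empty(indices.size)
    for k, i in enumerate(indices):
        el = str(struct.elements[i])
        try:
            out[k] = radii[el]
        except KeyError:
            raise ConfigError(
                f"element {el!r} missing from radii table") from None
    return out


def sasa_per_residue(frame: Structure,
                     params: SasaParams = SasaParams(),
                     atom_subset: np.ndarray | None = None) -> dict[int, float]:
    """Per-residue SASA in A^2 over the included heavy atoms.

    ``atom_subset`` (atom indices) restricts both the atoms contributing
    area and the occluders; hydrogens are always excluded.
    """
    heavy = frame.is_heavy
    if atom_subset is not None:
        include = np.zeros(frame.n_atoms, dtype=bool)
        include[np.asarray(atom_subset, dtype=int)] = True
        include &= heavy
    else:
        include = heavy
    idx = np.flatnonzero(include)
    if idx.size == 0:
        raise InputError("no heavy atoms included in SASA computation")
    radii = _atom_radii(frame, idx, params.radii())
    coords = frame.coords[idx]
    expanded = radii + params.probe_radius_A
    pts = sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(idx.size)
    for k in range(idx.size):
        neigh = [j for j in tree.query_ball_point(coords[k], max_reach)
                 if j != k]
        sphere = coords[k] + expanded[k] * pts
        if neigh:
            d = cdist(sphere, coords[neigh])
            occluded = (d < expanded[neigh]).any(axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        areas[k] = frac * 4.0 * np.pi * expanded[k] ** 2
    result: dict[int, float] = {}
    for k, i in enumerate(idx):
        r = int(frame.residue_numbers[i])
        result[r] = result.get(r, 0.0) + float(areas[k])
    return result


def _window_frames(traj: Trajectory,
                   window_ps: tuple[float, float] | None) -> np.ndarray:
    if window_ps is None:
        return np.arange(traj.n_frames)
    idx = traj.window_indices(*window_ps)
    if idx.size == 0:
        raise InputError(f"window {window_ps} selects no frames")
    return idx


def burial_by_region(traj: Trajectory,
                     target_residues: Sequence[int],
                     region_map: RegionMap,
                     mask_region: str = "LB",
                     window_ps: tuple[float, float] | None = None,
                     params: SasaParams = SasaParams(),
                     ) -> tuple[list[BurialRecord], float]:
    """Window-averaged SASA of target residues with and without a mask region.

    Returns per-residue :class:`BurialRecord` entries plus the summed buried
    area over all targets.  The mask region must be disjoint from the
    targets.
    """
    mask_residues = set(region_map.residues_in(mask_region))
    overlap = mask_residues & set(int(r) for r in target_residues)
    if overlap:
        raise InputError(
            f"target residues {sorted(overlap)} lie inside mask region "
            f"{mask_region!r}")
    topo = traj.topology
    keep = np.asarray(
        [int(r) not in mask_residues for r in topo.residue_numbers])
    without_subset = np.flatnonzero(keep)
    frames = _window_frames(traj, window_ps)
    targets = [int(r) for r in target_residues]
    sums_with = dict.fromkeys(targets, 0.0)
    sums_without = dict.fromkeys(targets, 0.0)
    for fi in frames:
        frame = traj.frame(int(fi))
        full = sasa_per_residue(frame, params)
        masked = sasa_per_residue(frame, params, atom_subset=without_subset)
        for r in targets:
            sums_with[r] += full.get(r, 0.0)
            sums_without[r] += masked.get(r, 0.0)
    nf = len(frames)
    if window_ps is None:
        window_ps = (float(traj.times_ps[0]), float(traj.times_ps[-1]))
    records = [
        BurialRecord(residue_number=r, window_ps=window_ps,
                     sasa_with_A2=sums_with[r] / nf,
                     sasa_without_A2=sums_without[r] / nf)
        for r in targets
    ]
    total_buried = float(sum(rec.buried_A2 for rec in records))
    return records, total_buried


def windowed_exposure(traj: Trajectory,
                      residues: Sequence[int],
                      windows: Sequence[tuple[float, float]],
                      params: SasaParams = SasaParams(),
                      threshold_A2: float = 40.0) -> pd.DataFrame:
    """Average per-residue SASA in each time window with buried/exposed labels.

    A residue is labelled *buried* in a window when its average SASA is below
    ``threshold_A2``.  The returned table also carries the change between the
    last and the first window.
    """
    residues = [int(r) for r in residues]
    averages = np.zeros((len(residues), len(windows)))
    for w, window in enumerate(windows):
        frames = _window_frames(traj, window)
        for fi in frames:
            vals = sasa_per_residue(traj.frame(int(fi)), params)
            for k, r in enumerate(residues):
                averages[k, w] += vals.get(r, 0.0)
        averages[:, w] /= len(frames)
    data: dict[str, list] = {"residue": residues}
    for w in range(len(windows)):
        data[f"window{w + 1}_A2"] = list(averages[:, w])
        data[f"window{w + 1}_label"] = [
            "buried" if a < threshold_A2 else "exposed"
            for a in averages[:, w]]
    data["delta_last_first_A2"] = list(averages[:, -1] - averages[:, 0])
    return pd.DataFrame(data)
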