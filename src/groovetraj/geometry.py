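"""Backbone dihedrals, Kabsch superposition, RMSD series and minimum distances.

Angles follow the IUPAC convention (right-handed positive), in degrees in
(-180, 180]; ties at +/-180 are reported as +180.  Dihedrals spanning a chain
break (peptide C-N distance >= 2 A) are undefined and returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, SelectionError
from .structures import RegionMap, Structure, Trajectory

__all__ = [
    "DihedralPair",
    "RmsdSeries",
    "dihedral_angle",
    "backbone_dihedrals",
    "trajectory_dihedrals",
    "superpose_kabsch",
    "rmsd_series",
    "min_residue_distance",
    "min_distance_series",
]

#: peptide-bond C-N distance above which consecutive residues are treated as
#: unbonded (the loop-deleted Bcl-XL construct joins residue 44 to 85; a
#: sequence-consecutive rule would fabricate a dihedral across that gap)
CHAIN_BREAK_CN_A = 2.0


@dataclass(frozen=True)
class DihedralPair:
    residue_number: int
    phi_deg: float | None
    psi_deg: float | None


@dataclass
class RmsdSeries:
    times_ps: np.ndarray
    values_A: np.ndarray
    atom_selection: str

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values_A = np.asarray(self.values_A, dtype=float)
        if self.times_ps.shape != self.values_A.shape:
            raise InputError("times and values must have equal length")


# ----------------------------------------------------------------------
# Dihedrals
# ----------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral(s) in degrees for points of shape (..., 3)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 (closed upper end of the convention)
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang


def _backbone_index_table(topology: Structure, chain: str | None):
    """Per-residue indices of N, CA, C atoms (first occurrence), chain-ordered."""
    residues = []
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i in range(topology.n_atoms):
        ch = str(topology.chains[i])
        if chain is not None and ch != chain:
            continue
        key = (ch, int(topology.residue_numbers[i]))
        if key not in table:
            table[key] = {}
            residues.append(key)
        name = str(topology.names[i])
        if name in ("N", "CA", "C") and name not in table[key]:
            table[key][name] = i
    return residues, table


def trajectory_dihedrals(
    traj: Trajectory,
    chain: str | None = None,
    break_threshold_A: float = CHAIN_BREAK_CN_A,
):
    """phi/psi for every residue over every frame, vectorised.

    Returns ``(residue_numbers, phi, psi)`` with phi/psi of shape
    ``(n_frames, n_residues)``; undefined angles are NaN (chain termini,
    missing backbone atoms, or an unbonded peptide link in that frame).
    """
    residues, table = _backbone_index_table(traj.topology, chain)
    if not residues:
        raise SelectionError("no residues in selection")
    n_res = len(residues)
    frames = traj.frames
    n_frames = frames.shape[0]
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)

    def _has(key, *names):
        return all(n in table[key] for n in names)

    for j, key in enumerate(residues):
        if not _has(key, "N", "CA", "C"):
            continue
        n_i, ca_i, c_i = (table[key][n] for n in ("N", "CA", "C"))
        # phi: C(prev) - N - CA - C, requires bonded previous residue
        if j > 0:
            prev = residues[j - 1]
            if prev[0] == key[0] and "C" in table[prev]:
                pc = table[prev]["C"]
                d = np.linalg.norm(frames[:, n_i] - frames[:, pc], axis=-1)
                ok = d < break_threshold_A
                if ok.any():
                    vals = dihedral_angle(frames[:, pc], frames[:, n_i],
                                          frames[:, ca_i], frames[:, c_i])
                    phi[ok, j] = vals[ok]
        # psi: N - CA - C - N(next), requires bonded next residue
        if j < n_res - 1:
            nxt = residues[j + 1]
            if nxt[0] == key[0] and "N" in table[nxt]:
                nn = table[nxt]["N"]
                d = np.linalg.norm(frames[:, nn] - frames[:, c_i], axis=-1)
                ok = d < break_threshold_A
                if ok.any():
                    vals = dihedral_angle(frames[:, n_i], frames[:, ca_i],
                                          frames[:, c_i], frames[:, nn])
                    psi[ok, j] = vals[ok]
    residue_numbers = np.asarray([num for _, num in residues], dtype=int)
    return residue_numbers, phi, psi


def backbone_dihedrals(frame: Structure,
                       chain: str | None = None) -> list[DihedralPair]:
    """phi/psi for each residue of a single structure (None if undefined)."""
    traj = Trajectory(topology=frame, frames=frame.coords[None, :, :])
    residue_numbers, phi, psi = trajectory_dihedrals(traj, chain=chain)
    out = []
    for j, num in enumerate(residue_numbers):
        p = None if np.isnan(phi[0, j]) else float(phi[0, j])
        s = None if np.isnan(psi[0, j]) else float(psi[0, j])
        out.append(DihedralPair(residue_number=int(num), phi_deg=p, psi_deg=s))
    return out


# ----------------------------------------------------------------------
# Superposition / RMSD
# ----------------------------------------------------------------------

def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_A)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference`` over all proper rigid transforms (no reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InputError("superposition requires at least 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise InputError("coordinates must be finite")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def _ca_selection(struct: Structure, residue_numbers: Sequence[int]) -> dict[int, int]:
    idx = struct.atom_indices(residue_numbers=residue_numbers, names=["CA"])
    return {int(struct.residue_numbers[i]): int(i) for i in idx}


def rmsd_series(traj: Trajectory, reference: Structure,
                region_map: RegionMap, regions: Sequence[str]) -> RmsdSeries:
    """Per-frame C-alpha RMSD to a reference over selected regions.

    Each frame's selected C-alpha set is least-squares fitted onto the same
    selection of the reference before measuring the RMSD.  Residues missing a
    C-alpha in either the reference or the trajectory topology are excluded.
    """
    wanted: list[int] = []
    for name in regions:
        wanted.extend(region_map.residues_in(name))
    ref_ca = _ca_selection(reference, wanted)
    traj_ca = _ca_selection(traj.topology, wanted)
    common = sorted(set(ref_ca) & set(traj_ca))
    if not common:
        raise SelectionError(
            f"no common C-alpha atoms for regions {list(regions)}")
    ref_coords = reference.coords[[ref_ca[r] for r in common]]
    traj_idx = [traj_ca[r] for r in common]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, values[i] = superpose_kabsch(traj.frames[i][traj_idx], ref_coords)
    selection = (f"CA of regions {','.join(regions)} "
                 f"({len(common)} residues)")
    return RmsdSeries(times_ps=traj.times_ps, values_A=values,
                      atom_selection=selection)


# ----------------------------------------------------------------------
# Minimum inter-residue distances
# ----------------------------------------------------------------------

def _residue_atom_indices(struct: Structure, residue: int,
                          heavy_only: bool) -> np.ndarray:
    idx = struct.atom_indices(residue_numbers=[residue], heavy_only=heavy_only)
    if idx.size == 0:
        raise SelectionError(
            f"residue {residue} has no {'heavy ' if heavy_only else ''}atoms")
    return idx


def min_residue_distance(frame: Structure, residue_a: int, residue_b: int,
                         heavy_only: bool = True) -> float:
    """Minimum (heavy-)atom pair distance between two residues, in Angstrom."""
    ia = _residue_atom_indices(frame, residue_a, heavy_only)
    ib = _residue_atom_indices(frame, residue_b, heavy_only)
    return float(cdist(frame.coords[ia], frame.coords[ib]).min())


def min_distance_series(traj: Trajectory, residue_a: int, residue_b: int,
                        heavy_only: bool = True) -> np.ndarray:
    """Per-frame minimum (heavy-)atom distance between two residues."""
    ia = _residue_atom_indices(traj.topology, residue_a, heavy_only)
    ib = _residue_atom_indices(traj.topology, residue_b, heavy_only)
    a = traj.frames[:, ia][:, :, None, :]
    b = traj.frames[:, ib][:, None, :, :]
    d = np.sqrt(np.sum((a - b) ** 2, axis=-1))
    return d.reshape(traj.n_frames, -1).min(axis=1)
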