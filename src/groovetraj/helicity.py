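"""Dihedral-window helicity classification and stable-segment detection.

A residue is right-handed alpha-helical in a frame when both backbone
dihedrals fall inside a rectangular (phi, psi) window (closed intervals).
Per-residue occupancy over the analysed frames then defines stable helical
segments: maximal runs of at least ``min_len`` consecutive residues each
helical in at least ``occupancy_threshold`` of frames.  Consensus segments
apply the same run rule to residues stable in at least ``min_sims``
replicate simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import trajectory_dihedrals
from .structures import Structure, Trajectory

__all__ = [
    "HelixWindow",
    "HelicityMask",
    "Segment",
    "classify_helical",
    "helicity_mask",
    "helical_content_series",
    "structure_helical_content",
    "stable_segments",
    "consensus_segments",
    "helicity_timeline",
]


@dataclass(frozen=True)
class HelixWindow:
    """Rectangular right-handed alpha-helix window in (phi, psi), degrees.

    Defaults admit the ideal helix (-57, -47) with a wide margin and exclude
    canonical beta-strand conformations.
    """

    phi_min: float = -100.0
    phi_max: float = -30.0
    psi_min: float = -80.0
    psi_max: float = -5.0

    def __post_init__(self):
        if not (self.phi_min < self.phi_max and self.psi_min < self.psi_max):
            raise InputError("helix window bounds must satisfy min < max")


DEFAULT_WINDOW = HelixWindow()


@dataclass
class Segment:
    """An inclusive residue range (length >= 4 for helical segments)."""

    start_residue: int
    end_residue: int

    def __post_init__(self):
        if self.end_residue < self.start_residue:
            raise InputError("segment end before start")

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1

    def residues(self) -> range:
        return range(self.start_residue, self.end_residue + 1)

    def as_tuple(self) -> tuple[int, int]:
        return (self.start_residue, self.end_residue)


@dataclass
class HelicityMask:
    """Residue x frame helicity assignment."""

    residues: np.ndarray        # (n_res,) residue numbers
    mask: np.ndarray            # (n_res, n_frames) booleans

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.residues.size:
            raise InputError("mask must be (n_residues, n_frames)")

    @property
    def n_frames(self) -> int:
        return self.mask.shape[1]

    @property
    def occupancy(self) -> np.ndarray:
        """Per-residue fraction of frames in helical conformation."""
        return self.mask.mean(axis=1)


def classify_helical(phi_deg: float, psi_deg: float,
                     window: HelixWindow = DEFAULT_WINDOW) -> bool:
    """True iff both dihedrals lie inside the window (closed intervals)."""
    return bool(
        window.phi_min <= phi_deg <= window.phi_max
        and window.psi_min <= psi_deg <= window.psi_max
    )


def _classify_arrays(phi: np.ndarray, psi: np.ndarray,
                     window: HelixWindow) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        ok = ((phi >= window.phi_min) & (phi <= window.phi_max)
              & (psi >= window.psi_min) & (psi <= window.psi_max))
    # NaN comparisons are False already: undefined dihedrals are non-helical
    return ok


def helicity_mask(traj: Trajectory, window: HelixWindow = DEFAULT_WINDOW,
                  chain: str | None = None) -> HelicityMask:
    """Classify every residue in every frame of a trajectory."""
    if traj.n_frames == 0:
        raise InputError("empty trajectory")
    residues, phi, psi = trajectory_dihedrals(traj, chain=chain)
    mask = _classify_arrays(phi, psi, window)      # (n_frames, n_res)
    return HelicityMask(residues=residues, mask=mask.T)


def helical_content_series(traj: Trajectory,
                           window: HelixWindow = DEFAULT_WINDOW,
                           chain: str | None = None) -> np.ndarray:
    """Per-frame helical content in percent.

    The denominator is every residue of the analysed chain; residues with
    undefined dihedrals (termini, chain breaks) count as non-helical.
    """
    hm = helicity_mask(traj, window=window, chain=chain)
    return 100.0 * hm.mask.mean(axis=0)


def structure_helical_content(frame: Structure,
                              window: HelixWindow = DEFAULT_WINDOW,
                              chain: str | None = None) -> float:
    """Helical content (percent) of a single structure."""
    traj = Trajectory(topology=frame, frames=frame.coords[None, :, :])
    return float(helical_content_series(traj, window=window, chain=chain)[0])


# ----------------------------------------------------------------------
# Segments
# ----------------------------------------------------------------------

def _runs_to_segments(residues: np.ndarray, flags: np.ndarray,
                      min_len: int) -> list[Segment]:
    """Maximal runs of flagged, consecutively-numbered residues."""
    segments: list[Segment] = []
    start = None
    prev = None
    for num, flag in zip(residues, flags):
        contiguous = prev is not None and num == prev + 1
        if flag and start is not None and contiguous:
            prev = num
            continue
        if start is not None and prev - start + 1 >= min_len:
            segments.append(Segment(int(start), int(prev)))
        start = num if flag else None
        prev = num if flag else num
    if start is not None and prev - start + 1 >= min_len:
        segments.append(Segment(int(start), int(prev)))
    return segments


def stable_segments(mask: HelicityMask, occupancy_threshold: float = 0.80,
                    min_len: int = 4) -> list[Segment]:
    """Maximal runs of >= min_len consecutive residues with occupancy >=
    occupancy_threshold ("at least 80% of the simulation time" is
    non-strict)."""
    if mask.mask.size == 0:
        raise InputError("empty helicity mask")
    stable = mask.occupancy >= occupancy_threshold
    return _runs_to_segments(mask.residues, stable, min_len)


def consensus_segments(per_sim_masks: Sequence[HelicityMask],
                       min_sims: int = 2,
                       occupancy_threshold: float = 0.80,
                       min_len: int = 4) -> list[Segment]:
    """Segments stable in at least ``min_sims`` of the replicate simulations.

    A residue is consensus-stable if it lies inside a stable segment of at
    least ``min_sims`` replicates; consensus segments are maximal runs of
    >= ``min_len`` consensus-stable residues.
    """
    if not per_sim_masks:
        raise InputError("no masks given")
    residues = per_sim_masks[0].residues
    for m in per_sim_masks[1:]:
        if not np.array_equal(m.residues, residues):
            raise InputError("masks have inconsistent residue axes")
    counts = np.zeros(residues.size, dtype=int)
    pos = {int(r): i for i, r in enumerate(residues)}
    for m in per_sim_masks:
        in_stable = np.zeros(residues.size, dtype=bool)
        for seg in stable_segments(m, occupancy_threshold, min_len):
            for r in seg.residues():
                if r in pos:
                    in_stable[pos[r]] = True
        counts += in_stable
    consensus = counts >= min_sims
    return _runs_to_segments(residues, consensus, min_len)


def helicity_timeline(mask: HelicityMask,
                      frame_range: tuple[int, int] | None = None,
                      csv_path: str | Path | None = None,
                      png_path: str | Path | None = None) -> pd.DataFrame:
    """Residue x frame helicity matrix, optionally written as CSV and PNG.

    Rows are ordered by residue number; entries are 0/1.  ``frame_range`` is
    a half-open (start, stop) frame slice.
    """
    if frame_range is not None:
        start, stop = frame_range
        if not (0 <= start < stop <= mask.n_frames):
            raise InputError(f"empty or out-of-range frame range {frame_range}")
        sub = mask.mask[:, start:stop]
        cols = np.arange(start, stop)
    else:
        sub = mask.mask
        cols = np.arange(mask.n_frames)
    order = np.argsort(mask.residues, kind="stable")
    df = pd.DataFrame(sub[order].astype(int),
                      index=mask.residues[order], columns=cols)
    df.index.name = "residue"
    if csv_path is not None:
        df.to_csv(csv_path)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        ax.imshow(df.values, aspect="auto", interpolation="nearest",
                  cmap="Greys", origin="lower",
                  extent=(cols[0], cols[-1] + 1,
                          float(df.index[0]), float(df.index[-1]) + 1))
        ax.set_xlabel("frame")
        ax.set_ylabel("residue")
        ax.set_title("helicity timeline")
        fig.tight_layout()
        fig.savefig(png_path, dpi=100)
        plt.close(fig)
    return df
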