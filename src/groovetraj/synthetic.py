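"""Synthetic helical-bundle trajectories with known ground truth.

Chains are rebuilt each frame from internal coordinates (NeRF): ideal bond
lengths/angles, omega fixed at 180 deg, and per-residue (phi, psi) sampled
from Gaussian *regimes* (helical or coil means with configurable spread).  A
regime may switch mid-run, emulating the unwinding of a helix segment.
Contact schedules translate a designated chain each frame so that a chosen
residue pair is in heavy-atom contact with a prescribed Bernoulli
probability.  Every stochastic choice derives from the spec's seed, and a
ground-truth manifest (implied helicity mask, stable segments, realised
contact draws, shielding events) accompanies each trajectory.

The generator covers the reduced atom set N, CA, C, O plus CB for non-Gly
residues, which suffices for backbone dihedrals, heavy-atom contacts and
SASA exercises; full side chains are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .helicity import DEFAULT_WINDOW, HelixWindow, Segment, _runs_to_segments
from .structures import Structure, Trajectory, write_structure, write_trajectory

__all__ = [
    "HELIX_PHI", "HELIX_PSI", "COIL_PHI", "COIL_PSI", "COIL_SIGMA",
    "ResidueRegime", "Placement", "ContactSchedule", "ChainSpec",
    "SyntheticSpec", "GroundTruthManifest",
    "build_helix", "build_chain", "simulate_trajectory", "emit_fixture_suite",
]

# ideal alpha-helix dihedrals and the default coil regime (outside any
# admissible helix window)
HELIX_PHI, HELIX_PSI = -57.0, -47.0
COIL_PHI, COIL_PSI, COIL_SIGMA = -80.0, 150.0, 25.0

# backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.8, 110.4
_T_N_C_CA_CB = 122.6  # L-amino-acid branch torsion (N-C-CA-CB)
_OMEGA = 180.0

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Place atom D bonded to C given reference atoms A-B-C.

    Batched: a/b/c may be (..., 3) and torsion_deg may broadcast over the
    leading axes, so a whole trajectory's worth of placements runs at once.
    """
    ang = np.radians(angle_deg)
    tor = np.radians(np.asarray(torsion_deg, dtype=float))[..., None]
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    return (c - bond * np.cos(ang) * bc
            + bond * np.sin(ang) * (np.cos(tor) * m + np.sin(tor) * n))


def build_chain(sequence: str,
                phi_deg: Sequence[float],
                psi_deg: Sequence[float],
                first_residue: int = 1,
                chain_id: str = "A",
                serial_start: int = 1) -> Structure:
    """Build a peptide backbone (N, CA, C, O, CB for non-Gly) from dihedrals.

    ``phi_deg[0]`` is ignored (the first residue has no phi); ``psi_deg[-1]``
    is used only to orient the final carbonyl oxygen.
    """
    sequence = sequence.upper()
    if not sequence:
        raise InputError("sequence must be non-empty")
    for letter in sequence:
        if letter not in _AA3:
            raise InputError(f"unknown residue letter {letter!r}")
    n_res = len(sequence)
    phi = np.asarray(phi_deg, dtype=float)
    psi = np.asarray(psi_deg, dtype=float)
    if phi.shape != (n_res,) or psi.shape != (n_res,):
        raise InputError("phi/psi must have one value per residue")

    serials, names, elements, resnums, resnames, chains, coords = \
        [], [], [], [], [], [], []
    serial = serial_start

    def emit(name, element, resnum, resname, xyz):
        nonlocal serial
        serials.append(serial)
        names.append(name)
        elements.append(element)
        resnums.append(resnum)
        resnames.append(resname)
        chains.append(chain_id)
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    backbone: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.radians(_A_N_CA_C)
            c_pos = ca_pos + _B_CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = backbone[i - 1]
            n_pos = _nerf(prev["N"], prev["CA"], prev["C"],
                          _B_C_N, _A_CA_C_N, psi[i - 1])
            ca_pos = _nerf(prev["CA"], prev["C"], n_pos,
                           _B_N_CA, _A_C_N_CA, _OMEGA)
            c_pos = _nerf(prev["C"], n_pos, ca_pos,
                          _B_CA_C, _A_N_CA_C, phi[i])
        backbone.append({"N": n_pos, "CA": ca_pos, "C": c_pos})

    for i, letter in enumerate(sequence):
        resnum = first_residue + i
        resname = _AA3[letter]
        bb = backbone[i]
        o_pos = _nerf(bb["N"], bb["CA"], bb["C"],
                      _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        emit("N", "N", resnum, resname, bb["N"])
        emit("CA", "C", resnum, resname, bb["CA"])
        emit("C", "C", resnum, resname, bb["C"])
        emit("O", "O", resnum, resname, o_pos)
        if letter != "G":
            cb_pos = _nerf(bb["N"], bb["C"], bb["CA"],
                           _B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB)
            emit("CB", "C", resnum, resname, cb_pos)
    return Structure(serials, names, elements, resnums, resnames, chains,
                     np.stack(coords))


def _build_chain_coords_batch(sequence: str, phi: np.ndarray,
                              psi: np.ndarray) -> np.ndarray:
    """Coordinates for every frame at once: phi/psi are (n_frames, n_res).

    Same geometry as :func:`build_chain`; returns (n_frames, n_atoms, 3) in
    the same atom order.
    """
    sequence = sequence.upper()
    n_frames, n_res = phi.shape
    ang = np.radians(_A_N_CA_C)
    n_pos = np.zeros((n_frames, 3))
    ca_pos = np.tile([_B_N_CA, 0.0, 0.0], (n_frames, 1))
    c_pos = ca_pos + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(n_pos, ca_pos, c_pos)]
    for i in range(1, n_res):
        pn, pca, pc = backbone[i - 1]
        n_pos = _nerf(pn, pca, pc, _B_C_N, _A_CA_C_N, psi[:, i - 1])
        ca_pos = _nerf(pca, pc, n_pos, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_pos = _nerf(pc, n_pos, ca_pos, _B_CA_C, _A_N_CA_C, phi[:, i])
        backbone.append((n_pos, ca_pos, c_pos))
    parts = []
    for i, letter in enumerate(sequence):
        bb_n, bb_ca, bb_c = backbone[i]
        o_pos = _nerf(bb_n, bb_ca, bb_c, _B_C_O, _A_CA_C_O,
                      psi[:, i] + 180.0)
        parts.extend([bb_n, bb_ca, bb_c, o_pos])
        if letter != "G":
            parts.append(_nerf(bb_n, bb_c, bb_ca, _B_CA_CB, _A_C_CA_CB,
                               _T_N_C_CA_CB))
    return np.stack(parts, axis=1)


def build_helix(sequence: str, phi_deg: float = HELIX_PHI,
                psi_deg: float = HELIX_PSI, first_residue: int = 1,
                chain_id: str = "A") -> Structure:
    """An ideal alpha-helix (constant phi/psi) for the given sequence."""
    n = len(sequence)
    return build_chain(sequence, [phi_deg] * n, [psi_deg] * n,
                       first_residue=first_residue, chain_id=chain_id)


# ----------------------------------------------------------------------
# Simulation spec
# ----------------------------------------------------------------------

@dataclass
class ResidueRegime:
    """Gaussian (phi, psi) sampling regime, optionally switching mid-run."""

    residue_number: int
    phi_mean: float = HELIX_PHI
    psi_mean: float = HELIX_PSI
    sigma_deg: float = 5.0
    switch_frame: int | None = None
    phi_mean2: float = COIL_PHI
    psi_mean2: float = COIL_PSI
    sigma2_deg: float = COIL_SIGMA

    def __post_init__(self):
        if self.sigma_deg < 0 or self.sigma2_deg < 0:
            raise InputError("regime sigma must be >= 0")

    def means_at(self, frame: int) -> tuple[float, float, float]:
        if self.switch_frame is not None and frame >= self.switch_frame:
            return self.phi_mean2, self.psi_mean2, self.sigma2_deg
        return self.phi_mean, self.psi_mean, self.sigma_deg


def coil_regime(residue_number: int,
                sigma_deg: float = COIL_SIGMA) -> ResidueRegime:
    return ResidueRegime(residue_number, phi_mean=COIL_PHI, psi_mean=COIL_PSI,
                         sigma_deg=sigma_deg)


@dataclass
class Placement:
    """Rigid placement of a chain, optionally switching mid-run."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    switch_frame: int | None = None
    rotation2: np.ndarray | None = None
    translation2: np.ndarray | None = None

    def apply(self, coords: np.ndarray, frame: int) -> np.ndarray:
        rot, trans = self.rotation, self.translation
        if self.switch_frame is not None and frame >= self.switch_frame:
            rot = self.rotation2 if self.rotation2 is not None else rot
            trans = (self.translation2 if self.translation2 is not None
                     else trans)
        return coords @ np.asarray(rot, dtype=float).T + np.asarray(
            trans, dtype=float)


@dataclass
class ContactSchedule:
    """Per-frame Bernoulli contact between residues on two chains.

    On contact frames the *mobile* chain (``chain_b``) is translated so that
    the pair's minimum heavy-atom distance equals ``contact_dist_A``;
    otherwise it sits at ``separated_dist_A``.
    """

    chain_a: int
    res_a: int
    chain_b: int
    res_b: int
    probability: float
    contact_dist_A: float = 3.5
    separated_dist_A: float = 9.0

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise InputError("contact probability must be in [0, 1]")
        if self.chain_a == self.chain_b:
            raise ConfigError("contact schedule needs two distinct chains")


@dataclass
class ChainSpec:
    sequence: str
    regimes: list[ResidueRegime]
    placement: Placement = field(default_factory=Placement)
    first_residue: int = 1
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.regimes) != len(self.sequence):
            raise ConfigError("one regime per residue required")
        expected = range(self.first_residue,
                         self.first_residue + len(self.sequence))
        got = [r.residue_number for r in self.regimes]
        if got != list(expected):
            raise ConfigError("regime residue numbers must be consecutive "
                              "and match first_residue")


@dataclass
class SyntheticSpec:
    chains: list[ChainSpec]
    n_frames: int
    contact_schedules: list[ContactSchedule] = field(default_factory=list)
    dt_ps: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        mobile = [s.chain_b for s in self.contact_schedules]
        if len(mobile) != len(set(mobile)):
            raise ConfigError("a chain may be the mobile partner of at most "
                              "one contact schedule")
        anchors = {s.chain_a for s in self.contact_schedules}
        if anchors & set(mobile):
            raise ConfigError("a schedule's mobile chain may not anchor "
                              "another schedule")
        for r in self.regimes_flat():
            if r.switch_frame is not None and not (
                    0 <= r.switch_frame <= self.n_frames):
                raise ConfigError(
                    f"switch_frame {r.switch_frame} outside trajectory")

    def regimes_flat(self) -> list[ResidueRegime]:
        return [r for ch in self.chains for r in ch.regimes]


@dataclass
class GroundTruthManifest:
    """Truth implied by a SyntheticSpec (plus its seed-fixed draws)."""

    residues: np.ndarray                  # all chains, topology order
    true_mask: np.ndarray                 # (n_res, n_frames) from regime means
    true_stable_segments: list[tuple[int, int]]
    contact_draws: dict[tuple[int, int], np.ndarray]   # realised Bernoulli
    unwind_events: list[dict]             # {"residues": [a, b], "switch_frame": f}
    shield_events: list[dict]             # {"chain_id": c, "switch_frame": f}

    @property
    def true_occupancy(self) -> np.ndarray:
        return self.true_mask.mean(axis=1)

    def contact_fraction(self, res_a: int, res_b: int) -> float:
        return float(self.contact_draws[(res_a, res_b)].mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "residues": [int(r) for r in self.residues],
            "true_occupancy": [float(x) for x in self.true_occupancy],
            "true_mask": ["".join("1" if v else "0" for v in row)
                          for row in self.true_mask],
            "true_stable_segments": [list(s) for s in self.true_stable_segments],
            "contact_draws": {
                f"{a}-{b}": "".join("1" if v else "0" for v in draws)
                for (a, b), draws in self.contact_draws.items()},
            "unwind_events": self.unwind_events,
            "shield_events": self.shield_events,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        mask = np.asarray(
            [[c == "1" for c in row] for row in payload["true_mask"]],
            dtype=bool)
        draws = {}
        for key, bits in payload["contact_draws"].items():
            a, b = key.split("-")
            draws[(int(a), int(b))] = np.asarray(
                [c == "1" for c in bits], dtype=bool)
        return cls(
            residues=np.asarray(payload["residues"], dtype=int),
            true_mask=mask,
            true_stable_segments=[tuple(s) for s in
                                  payload["true_stable_segments"]],
            contact_draws=draws,
            unwind_events=payload["unwind_events"],
            shield_events=payload["shield_events"],
        )


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def _true_mask_for_spec(spec: SyntheticSpec,
                        window: HelixWindow = DEFAULT_WINDOW):
    """Classify each residue's *mean* dihedrals per frame; termini are
    non-helical (their phi or psi is undefined in any rebuilt chain)."""
    rows = []
    residues = []
    for ch in spec.chains:
        n = len(ch.sequence)
        for k, regime in enumerate(ch.regimes):
            residues.append(regime.residue_number)
            row = np.zeros(spec.n_frames, dtype=bool)
            if 0 < k < n - 1:
                for f in range(spec.n_frames):
                    phi, psi, _ = regime.means_at(f)
                    row[f] = (window.phi_min <= phi <= window.phi_max
                              and window.psi_min <= psi <= window.psi_max)
            rows.append(row)
    return np.asarray(residues, dtype=int), np.stack(rows)


def _true_segments(residues: np.ndarray, mask: np.ndarray,
                   occupancy_threshold: float = 0.80,
                   min_len: int = 4) -> list[tuple[int, int]]:
    occ = mask.mean(axis=1)
    segs = _runs_to_segments(residues, occ >= occupancy_threshold, min_len)
    return [s.as_tuple() for s in segs]


def simulate_trajectory(spec: SyntheticSpec,
                        ) -> tuple[Trajectory, GroundTruthManifest]:
    """Generate a trajectory and its ground-truth manifest.

    Deterministic under ``spec.seed``: the same spec always yields
    bit-identical frames and draws.
    """
    rng = np.random.default_rng(spec.seed)
    chain_structs = [
        build_chain(ch.sequence,
                    [r.phi_mean for r in ch.regimes],
                    [r.psi_mean for r in ch.regimes],
                    first_residue=ch.first_residue, chain_id=ch.chain_id)
        for ch in spec.chains
    ]
    offsets = np.cumsum([0] + [s.n_atoms for s in chain_structs])
    topo = _concat_structures(chain_structs)
    n_atoms = topo.n_atoms

    # pre-draw contact Bernoullis and dihedral noise (stable draw order)
    draws: dict[tuple[int, int], np.ndarray] = {}
    for sched in spec.contact_schedules:
        draws[(sched.res_a, sched.res_b)] = (
            rng.random(spec.n_frames) < sched.probability)
    chain_coords = []
    for ch in spec.chains:
        n_res = len(ch.sequence)
        phi_m = np.empty((spec.n_frames, n_res))
        psi_m = np.empty((spec.n_frames, n_res))
        sig = np.empty((spec.n_frames, n_res))
        frame_axis = np.arange(spec.n_frames)
        for j, regime in enumerate(ch.regimes):
            if regime.switch_frame is None:
                phi_m[:, j], psi_m[:, j], sig[:, j] = (
                    regime.phi_mean, regime.psi_mean, regime.sigma_deg)
            else:
                late = frame_axis >= regime.switch_frame
                phi_m[:, j] = np.where(late, regime.phi_mean2, regime.phi_mean)
                psi_m[:, j] = np.where(late, regime.psi_mean2, regime.psi_mean)
                sig[:, j] = np.where(late, regime.sigma2_deg, regime.sigma_deg)
        noise = rng.standard_normal((2, spec.n_frames, n_res))
        coords = _build_chain_coords_batch(
            ch.sequence, phi_m + sig * noise[0], psi_m + sig * noise[1])
        placed = np.empty_like(coords)
        for f in range(spec.n_frames):
            placed[f] = ch.placement.apply(coords[f], f)
        chain_coords.append(placed)
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        coords_parts = [chain_coords[ci][f]
                        for ci in range(len(spec.chains))]
        for sched in spec.contact_schedules:
            _apply_contact(spec, chain_structs, coords_parts, sched,
                           bool(draws[(sched.res_a, sched.res_b)][f]))
        frames[f] = np.concatenate(coords_parts, axis=0)

    traj = Trajectory(topology=topo.with_coords(frames[0]),
                      frames=frames, dt_ps=spec.dt_ps)
    residues, true_mask = _true_mask_for_spec(spec)
    unwind = []
    for ch in spec.chains:
        for r in ch.regimes:
            if r.switch_frame is not None:
                unwind.append({"residue": int(r.residue_number),
                               "switch_frame": int(r.switch_frame)})
    shield = [{"chain_id": ch.chain_id,
               "switch_frame": int(ch.placement.switch_frame)}
              for ch in spec.chains
              if ch.placement.switch_frame is not None]
    manifest = GroundTruthManifest(
        residues=residues,
        true_mask=true_mask,
        true_stable_segments=_true_segments(residues, true_mask),
        contact_draws=draws,
        unwind_events=_group_unwind(unwind),
        shield_events=shield,
    )
    return traj, manifest


def _group_unwind(events: list[dict]) -> list[dict]:
    """Collapse per-residue switch events into contiguous residue ranges."""
    out: list[dict] = []
    for ev in sorted(events, key=lambda e: (e["switch_frame"], e["residue"])):
        if (out and out[-1]["switch_frame"] == ev["switch_frame"]
                and ev["residue"] == out[-1]["residues"][1] + 1):
            out[-1]["residues"][1] = ev["residue"]
        else:
            out.append({"residues": [ev["residue"], ev["residue"]],
                        "switch_frame": ev["switch_frame"]})
    return out


def _concat_structures(parts: list[Structure]) -> Structure:
    serial = 1
    serials, names, elements, resnums, resnames, chains, coords = \
        [], [], [], [], [], [], []
    for p in parts:
        for i in range(p.n_atoms):
            serials.append(serial)
            serial += 1
        names.extend(p.names)
        elements.extend(p.elements)
        resnums.extend(p.residue_numbers)
        resnames.extend(p.residue_names)
        chains.extend(p.chains)
        coords.append(p.coords)
    return Structure(serials, names, elements, resnums, resnames, chains,
                     np.concatenate(coords, axis=0))


def _apply_contact(spec: SyntheticSpec, chain_structs: list[Structure],
                   coords_parts: list[np.ndarray], sched: ContactSchedule,
                   in_contact: bool) -> None:
    target = sched.contact_dist_A if in_contact else sched.separated_dist_A
    sa = chain_structs[sched.chain_a]
    sb = chain_structs[sched.chain_b]
    ia = sa.atom_indices(residue_numbers=[sched.res_a], heavy_only=True)
    ib = sb.atom_indices(residue_numbers=[sched.res_b], heavy_only=True)
    if ia.size == 0 or ib.size == 0:
        raise ConfigError("contact schedule names a residue with no heavy "
                          "atoms on its chain")
    ca = coords_parts[sched.chain_a][ia]
    cb = coords_parts[sched.chain_b][ib]
    diff = cb[None, :, :] - ca[:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    k = np.unravel_index(np.argmin(d), d.shape)
    dmin = d[k]
    u = diff[k] / dmin
    coords_parts[sched.chain_b] = (
        coords_parts[sched.chain_b] + (target - dmin) * u)


# ----------------------------------------------------------------------
# Canonical fixtures
# ----------------------------------------------------------------------

def replicate_bundle_spec(replicate: int, seed: int = 0,
                          n_frames: int = 300,
                          sigma_deg: float = 6.0) -> SyntheticSpec:
    """One replicate of the 4-simulation unwinding set.

    A 76-residue chain with programmed helical regions (5-20), (26-40),
    (46-60) and (64-72); the second region unwinds at 40% of the run in
    replicates 1-3 and stays helical in replicate 4, emulating the
    Apo-I/Apo-II/Holo-I/Holo-II pattern in which the central BH3-analogue
    helix is destabilised in most replicates.
    """
    if replicate not in (1, 2, 3, 4):
        raise InputError("replicate must be 1..4")
    helical = [(5, 20), (26, 40), (46, 60), (64, 72)]
    unwound_region = (26, 40)
    switch = int(0.4 * n_frames)
    regimes = []
    for resnum in range(1, 77):
        in_helix = any(a <= resnum <= b for a, b in helical)
        if not in_helix:
            regimes.append(coil_regime(resnum))
            continue
        r = ResidueRegime(resnum, sigma_deg=sigma_deg)
        if (replicate <= 3
                and unwound_region[0] <= resnum <= unwound_region[1]):
            r.switch_frame = switch
        regimes.append(r)
    chain = ChainSpec(sequence="A" * 76, regimes=regimes)
    return SyntheticSpec(chains=[chain], n_frames=n_frames,
                         seed=seed * 10 + replicate)


def contact_pair_spec(probability: float = 0.70, n_frames: int = 2000,
                      seed: int = 0) -> SyntheticSpec:
    """Two short helices with a scheduled Bernoulli contact (res 6 vs 106)."""
    chain_a = ChainSpec(
        sequence="A" * 12,
        regimes=[ResidueRegime(r, sigma_deg=4.0) for r in range(1, 13)],
        first_residue=1, chain_id="A")
    chain_b = ChainSpec(
        sequence="A" * 12,
        regimes=[ResidueRegime(r, sigma_deg=4.0) for r in range(101, 113)],
        first_residue=101, chain_id="B",
        placement=Placement(translation=np.array([20.0, 0.0, 0.0])))
    sched = ContactSchedule(chain_a=0, res_a=6, chain_b=1, res_b=106,
                            probability=probability)
    return SyntheticSpec(chains=[chain_a, chain_b], n_frames=n_frames,
                         contact_schedules=[sched], seed=seed)


def unwinding_spec(n_frames: int = 1000, switch_fraction: float = 0.4,
                   seed: int = 0, sigma_deg: float = 6.0) -> SyntheticSpec:
    """A 24-residue chain whose residues 8-15 unwind at a scheduled frame."""
    switch = int(switch_fraction * n_frames)
    regimes = []
    for resnum in range(1, 25):
        r = ResidueRegime(resnum, sigma_deg=sigma_deg)
        if 8 <= resnum <= 15:
            r.switch_frame = switch
        regimes.append(r)
    chain = ChainSpec(sequence="A" * 24, regimes=regimes)
    return SyntheticSpec(chains=[chain], n_frames=n_frames, seed=seed)


def shielding_spec(n_frames: int = 20, seed: int = 0) -> SyntheticSpec:
    """A target helix whose residue 5 is covered by a second chain mid-run.

    Chain B starts 40 A away and moves flush against the face of residue 5
    at half-run, emulating a groove residue shielded by a mobile loop.
    """
    switch = n_frames // 2
    target = ChainSpec(
        sequence="A" * 10,
        regimes=[ResidueRegime(r, sigma_deg=0.0) for r in range(1, 11)],
        first_residue=1, chain_id="A")
    plate = ChainSpec(
        sequence="A" * 8,
        regimes=[ResidueRegime(r, sigma_deg=0.0) for r in range(101, 109)],
        first_residue=101, chain_id="B",
        placement=Placement(
            translation=np.array([40.0, 0.0, 0.0]),
            switch_frame=switch,
            translation2=np.array([0.0, 0.0, 0.0]),  # calibrated by caller
        ))
    return SyntheticSpec(chains=[target, plate], n_frames=n_frames, seed=seed)


def calibrated_shielding_spec(n_frames: int = 20,
                              seed: int = 0) -> SyntheticSpec:
    """Shielding fixture with the plate placed against residue 5's CB face."""
    spec = shielding_spec(n_frames=n_frames, seed=seed)
    target = build_chain("A" * 10, [HELIX_PHI] * 10, [HELIX_PSI] * 10)
    cb_idx = target.atom_indices(residue_numbers=[5], names=["CB"])[0]
    ca_idx = target.atom_indices(residue_numbers=[5], names=["CA"])[0]
    outward = target.coords[cb_idx] - target.coords[ca_idx]
    outward /= np.linalg.norm(outward)
    plate = build_chain("A" * 8, [HELIX_PHI] * 8, [HELIX_PSI] * 8,
                        first_residue=101, chain_id="B")
    # put the plate's centroid just beyond the CB along the outward normal
    anchor = target.coords[cb_idx] + 4.2 * outward
    shift = anchor - plate.coords.mean(axis=0)
    spec.chains[1].placement.translation2 = shift
    return spec


def emit_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical test fixtures (trajectories + manifests).

    Produces the ideal helix, the 4-replicate unwinding set, the
    contact-probability pair and the SASA shielding set, all as multi-model
    PDB with JSON manifests.  Identical seeds yield identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    helix = build_helix("A" * 20)
    p = out / "ideal_helix.pdb"
    write_structure(helix, p)
    written["ideal_helix"] = p

    for rep in (1, 2, 3, 4):
        spec = replicate_bundle_spec(rep, seed=seed)
        traj, manifest = simulate_trajectory(spec)
        p = out / f"replicate_{rep}.pdb"
        write_trajectory(traj, p)
        manifest.to_json(out / f"replicate_{rep}.manifest.json")
        written[f"replicate_{rep}"] = p

    spec = contact_pair_spec(seed=seed, n_frames=500)
    traj, manifest = simulate_trajectory(spec)
    p = out / "contact_pair.pdb"
    write_trajectory(traj, p)
    manifest.to_json(out / "contact_pair.manifest.json")
    written["contact_pair"] = p

    spec = calibrated_shielding_spec(seed=seed)
    traj, manifest = simulate_trajectory(spec)
    p = out / "sasa_shield.pdb"
    write_trajectory(traj, p)
    manifest.to_json(out / "sasa_shield.manifest.json")
    written["sasa_shield"] = p
    return written
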