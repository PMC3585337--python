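"""Structures, trajectories and the helix/loop region map.

Coordinates are in Angstrom throughout.  Residue numbers are taken verbatim
from the input files (for Bcl-X_L_ they follow UniProt Q64373 numbering) and
all residue intervals are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

from .errors import ConfigError, FormatError, ParseError, TopologyError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RegionMap",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "load_region_map",
    "default_region_map",
]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    coords: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


class Structure:
    """An ordered collection of atoms with array-backed storage.

    Parameters mirror PDB atom records; arrays must share the same length.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        chains: Sequence[str],
        coords: np.ndarray,
    ):
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.serials)
        for arr in (self.names, self.elements, self.residue_numbers,
                    self.residue_names, self.chains):
            if len(arr) != n:
                raise ValueError("structure field arrays must share one length")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def is_heavy(self) -> np.ndarray:
        return np.asarray([e not in _HYDROGEN_ELEMENTS for e in self.elements])

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield self.atom(i)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_number=int(self.residue_numbers[i]),
            residue_name=str(self.residue_names[i]),
            chain=str(self.chains[i]),
            coords=self.coords[i].copy(),
        )

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_number, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for ch, num, nam in zip(self.chains, self.residue_numbers, self.residue_names):
            key = (str(ch), int(num))
            if key not in seen:
                seen.add(key)
                out.append((str(ch), int(num), str(nam)))
        return out

    # -- selections ----------------------------------------------------
    def atom_indices(
        self,
        residue_numbers: Iterable[int] | None = None,
        names: Iterable[str] | None = None,
        chain: str | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_numbers is not None:
            wanted = set(int(r) for r in residue_numbers)
            mask &= np.asarray([int(r) in wanted for r in self.residue_numbers])
        if names is not None:
            wanted_names = set(names)
            mask &= np.asarray([str(n) in wanted_names for n in self.names])
        if chain is not None:
            mask &= np.asarray([str(c) == chain for c in self.chains])
        if heavy_only:
            mask &= self.is_heavy
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.serials[idx], self.names[idx], self.elements[idx],
            self.residue_numbers[idx], self.residue_names[idx],
            self.chains[idx], self.coords[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.serials, self.names, self.elements,
            self.residue_numbers, self.residue_names, self.chains, coords,
        )


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over a fixed topology."""

    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3) Angstrom
    dt_ps: float = 1.0
    time_origin_ps: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return self.time_origin_ps + self.dt_ps * np.arange(self.n_frames)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def window_indices(self, t_start_ps: float, t_end_ps: float) -> np.ndarray:
        """Frame indices with t_start <= t <= t_end (start boundary inclusive)."""
        t = self.times_ps
        return np.flatnonzero((t >= t_start_ps - 1e-9) & (t <= t_end_ps + 1e-9))


@dataclass
class RegionMap:
    """Named residue regions (helices H1..H6, loops LA..LD).

    Each region is a list of inclusive 1-based ``(start, end)`` intervals; a
    region may be discontiguous (H2 spans 42-44 and 85-100 in the
    loop-deleted Bcl-X_L_ construct, where residue 44 is covalently linked to
    residue 85).
    """

    regions: dict[str, list[tuple[int, int]]]
    helix_names: list[str] = field(default_factory=list)
    loop_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        for name, intervals in self.regions.items():
            if not intervals:
                raise ConfigError(f"region {name!r} has no intervals")
            ivs = sorted((int(a), int(b)) for a, b in intervals)
            for a, b in ivs:
                if a > b:
                    raise ConfigError(
                        f"region {name!r}: interval {a}-{b} has start > end")
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise ConfigError(
                        f"region {name!r}: overlapping intervals "
                        f"{a1}-{b1} and {a2}-{b2}")
            self.regions[name] = ivs

    def residues_in(self, name: str) -> list[int]:
        try:
            intervals = self.regions[name]
        except KeyError:
            raise ConfigError(f"unknown region {name!r}") from None
        out: list[int] = []
        for a, b in intervals:
            out.extend(range(a, b + 1))
        return out

    def region_of(self, residue_number: int,
                  names: Iterable[str] | None = None) -> str | None:
        """Region containing the residue, or None; first match in map order."""
        search = list(names) if names is not None else list(self.regions)
        for name in search:
            for a, b in self.regions[name]:
                if a <= residue_number <= b:
                    return name
        return None

    def overlapping_regions(self) -> list[tuple[str, str, int]]:
        """Report (region_a, region_b, residue) for residues claimed twice."""
        claims: dict[int, str] = {}
        conflicts = []
        for name, intervals in self.regions.items():
            for a, b in intervals:
                for r in range(a, b + 1):
                    if r in claims and claims[r] != name:
                        conflicts.append((claims[r], name, r))
                    else:
                        claims.setdefault(r, name)
        return conflicts


# ----------------------------------------------------------------------
# PDB reading / writing (via biotite's fixed-column codec)
# ----------------------------------------------------------------------

def _structure_from_atom_array(arr) -> Structure:
    import biotite.structure as bst

    protein = arr[bst.filter_amino_acids(arr)]
    if protein.array_length() == 0:
        raise ParseError("no protein atoms found")
    serials = (protein.get_annotation("atom_id")
               if "atom_id" in protein.get_annotation_categories()
               else np.arange(1, protein.array_length() + 1))
    return Structure(
        serials=np.asarray(serials, dtype=int),
        names=protein.atom_name,
        elements=protein.element,
        residue_numbers=protein.res_id,
        residue_names=protein.res_name,
        chains=protein.chain_id,
        coords=protein.coord,
    )


def read_structure(path: str | Path, model_index: int | None = None,
                   chain: str | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters/ions are dropped; hydrogens are kept (flagged non-heavy);
    alternate locations are resolved to the highest-occupancy conformer.
    ``model_index`` is 0-based (default: first model).
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    midx = 0 if model_index is None else int(model_index)
    if not 0 <= midx < n_models:
        raise IndexError(
            f"model_index {midx} out of range for {path} ({n_models} models)")
    try:
        arr = pdb.get_structure(model=midx + 1, altloc="occupancy",
                                extra_fields=["atom_id"])
    except Exception as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    struct = _structure_from_atom_array(arr)
    if chain is not None:
        idx = struct.atom_indices(chain=chain)
        if idx.size == 0:
            raise ParseError(f"chain {chain!r} not found in {path}")
        struct = struct.subset(idx)
    return struct


def _to_atom_array(struct: Structure, coords: np.ndarray | None = None):
    import biotite.structure as bst

    n = struct.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else struct.coords,
                           dtype=np.float32)
    arr.atom_name = struct.names.astype("U6")
    arr.element = struct.elements.astype("U2")
    arr.res_id = struct.residue_numbers
    arr.res_name = struct.residue_names.astype("U5")
    arr.chain_id = struct.chains.astype("U4")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", struct.serials)
    return arr


def write_structure(struct: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(struct))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates to 0.001 A)."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    arrs = [_to_atom_array(traj.topology, traj.frames[i])
            for i in range(traj.n_frames)]
    stack = bst.stack(arrs)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(topology_path: str | Path, traj_path: str | Path,
                    dt_ps: float | None = None,
                    chain: str | None = None) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) over a PDB topology.

    ``dt_ps`` overrides the frame spacing; otherwise it is taken from the
    trajectory metadata when available and defaults to 1 ps.
    """
    topology_path = Path(topology_path)
    traj_path = Path(traj_path)
    topo = read_structure(topology_path, chain=chain)
    suffix = traj_path.suffix.lower()
    if suffix == ".pdb":
        frames, file_dt = _read_multimodel_pdb_frames(traj_path, chain)
    elif suffix in {".dcd", ".xtc"}:
        frames, file_dt = _read_mdtraj_frames(traj_path, topology_path)
    else:
        raise FormatError(f"unsupported trajectory format {suffix!r}")
    if frames.shape[1] != topo.n_atoms:
        raise TopologyError(
            f"trajectory has {frames.shape[1]} atoms per frame but topology "
            f"{topology_path} has {topo.n_atoms}")
    return Trajectory(topology=topo, frames=frames,
                      dt_ps=dt_ps if dt_ps is not None else (file_dt or 1.0))


def _read_multimodel_pdb_frames(path: Path, chain: str | None):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        frames = []
        for m in range(1, n_models + 1):
            arr = pdb.get_structure(model=m, altloc="occupancy",
                                    extra_fields=["atom_id"])
            s = _structure_from_atom_array(arr)
            if chain is not None:
                s = s.subset(s.atom_indices(chain=chain))
            frames.append(s.coords)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse trajectory PDB {path}: {exc}") from exc
    try:
        stack = np.stack(frames)
    except ValueError as exc:
        raise TopologyError(
            f"models in {path} differ in atom count") from exc
    return stack, None


def _read_mdtraj_frames(traj_path: Path, topology_path: Path):
    import mdtraj

    t = mdtraj.load(str(traj_path), top=str(topology_path))
    frames = np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Angstrom
    dt = float(t.timestep) if t.n_frames > 1 else None
    return frames, dt


# ----------------------------------------------------------------------
# Region map
# ----------------------------------------------------------------------

def _region_map_from_dict(cfg: dict) -> RegionMap:
    if "regions" not in cfg:
        raise ConfigError("region map config must contain a 'regions' mapping")
    regions: dict[str, list[tuple[int, int]]] = {}
    for name, intervals in cfg["regions"].items():
        parsed = []
        for iv in intervals:
            if len(iv) != 2:
                raise ConfigError(
                    f"region {name!r}: interval {iv!r} must be [start, end]")
            parsed.append((int(iv[0]), int(iv[1])))
        regions[str(name)] = parsed
    return RegionMap(
        regions=regions,
        helix_names=[str(h) for h in cfg.get("helices", [])],
        loop_names=[str(l) for l in cfg.get("loops", [])],
    )


def load_region_map(config_path: str | Path) -> RegionMap:
    """Load a region map from a YAML or JSON config file."""
    path = Path(config_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"region map config {path} is not a mapping")
    return _region_map_from_dict(cfg)


def default_region_map() -> RegionMap:
    """The Bcl-X_L_ region map shipped with the package.

    Helix ranges are the experimentally observed stable helical regions
    common to the 1PQ0/1PQ1 crystal structures; loop LB is residues 101-119.
    """
    with resources.files("groovetraj").joinpath(
            "data/bclxl_regions.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return _region_map_from_dict(cfg)
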