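"""Residue-contact identification, persistence tracking and stability rules.

Two residues interact when at least one pair of heavy atoms is within 4 A
(strict).  Over a trajectory window the persistence of a contact is the
fraction of frames below the cutoff; a contact is *stable* when that
fraction exceeds 50% (strict) in at least 2 of 4 replicate simulations
(non-strict).  The scan for helix-destabilising sequence features flags
glycines and like-charged residue pairs spaced 3-4 apart, which stack on the
same helix face and repel.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, InputError
from .geometry import min_distance_series
from .helicity import Segment
from .structures import RegionMap, Structure, Trajectory

__all__ = [
    "ContactPair",
    "PersistenceRecord",
    "DestabilizationReport",
    "interacting_pairs",
    "pair_persistence",
    "stable_pairs",
    "pairs_unique_to_group",
    "destabilization_scan",
]

ACIDIC = set("DE")
BASIC = set("KR")


@dataclass(frozen=True, order=True)
class ContactPair:
    res_a: int
    res_b: int
    region_a: str = field(compare=False)
    region_b: str = field(compare=False)

    def __post_init__(self):
        if self.res_a >= self.res_b:
            raise InputError("ContactPair requires res_a < res_b")

    def __eq__(self, other):
        return (isinstance(other, ContactPair)
                and (self.res_a, self.res_b) == (other.res_a, other.res_b))

    def __hash__(self):
        return hash((self.res_a, self.res_b))


@dataclass
class PersistenceRecord:
    pair: ContactPair
    sim_id: str
    mean_min_dist_A: float
    frac_below_cutoff: float
    window_ps: tuple[float, float]

    def __post_init__(self):
        if not 0.0 <= self.frac_below_cutoff <= 1.0:
            raise InputError("fraction must be in [0, 1]")
        if self.mean_min_dist_A < 0:
            raise InputError("mean distance must be non-negative")


def _allowed_region_names(region_map: RegionMap,
                          allowed_regions: Sequence[str] | None) -> list[str]:
    if allowed_regions is not None:
        names = list(allowed_regions)
    else:
        names = list(region_map.helix_names) + [
            l for l in region_map.loop_names if l != "LA"]
    if not names:
        raise ConfigError("allowed-region set is empty")
    for n in names:
        if n not in region_map.regions:
            raise ConfigError(f"region {n!r} not in region map")
    return names


def interacting_pairs(structures: Iterable[Structure],
                      region_map: RegionMap,
                      cutoff_A: float = 4.0,
                      min_seq_sep: int = 3,
                      allowed_regions: Sequence[str] | None = None,
                      ) -> set[ContactPair]:
    """Union over structures of residue pairs in heavy-atom contact.

    A pair qualifies when its minimum heavy-atom distance is < ``cutoff_A``,
    both residues lie in allowed regions (helices plus loops LB/LC/LD by
    default), the regions differ, and the sequence separation is at least
    ``min_seq_sep``.
    """
    names = _allowed_region_names(region_map, allowed_regions)
    out: set[ContactPair] = set()
    for struct in structures:
        heavy = struct.atom_indices(heavy_only=True)
        res = struct.residue_numbers[heavy]
        regions = np.asarray(
            [region_map.region_of(int(r), names) for r in res], dtype=object)
        keep = regions != None  # noqa: E711  (vectorised None comparison)
        heavy, res, regions = heavy[keep], res[keep], regions[keep]
        if heavy.size == 0:
            continue
        coords = struct.coords[heavy]
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(cutoff_A):
            d = np.linalg.norm(coords[i] - coords[j])
            if d >= cutoff_A:
                continue
            ra, rb = int(res[i]), int(res[j])
            if ra == rb or abs(ra - rb) < min_seq_sep:
                continue
            ga, gb = str(regions[i]), str(regions[j])
            if ga == gb:
                continue
            if ra > rb:
                ra, rb, ga, gb = rb, ra, gb, ga
            out.add(ContactPair(ra, rb, ga, gb))
    return out


def pair_persistence(traj: Trajectory, pair: ContactPair,
                     cutoff_A: float = 4.0,
                     window_ps: tuple[float, float] | None = None,
                     sim_id: str = "") -> PersistenceRecord:
    """Mean minimum heavy-atom distance and below-cutoff fraction in a window."""
    if window_ps is None:
        window_ps = (float(traj.times_ps[0]), float(traj.times_ps[-1]))
    idx = traj.window_indices(*window_ps)
    if idx.size == 0:
        raise InputError(f"window {window_ps} selects no frames")
    series = min_distance_series(traj, pair.res_a, pair.res_b)[idx]
    return PersistenceRecord(
        pair=pair,
        sim_id=sim_id,
        mean_min_dist_A=float(series.mean()),
        frac_below_cutoff=float((series < cutoff_A).mean()),
        window_ps=(float(window_ps[0]), float(window_ps[1])),
    )


def stable_pairs(records: Iterable[PersistenceRecord],
                 frac_threshold: float = 0.5,
                 min_sims: int = 2) -> set[ContactPair]:
    """Pairs whose persistence strictly exceeds the threshold in >= min_sims
    simulations ("more than 50% ... in at least 2 out of 4")."""
    counts: dict[ContactPair, set[str]] = defaultdict(set)
    for rec in records:
        if rec.frac_below_cutoff > frac_threshold:
            counts[rec.pair].add(rec.sim_id)
    return {pair for pair, sims in counts.items() if len(sims) >= min_sims}


def pairs_unique_to_group(group_a: set[ContactPair],
                          group_b: set[ContactPair]) -> set[ContactPair]:
    """Contacts present in group_a but not group_b (set difference)."""
    return set(group_a) - set(group_b)


@dataclass
class DestabilizationReport:
    helix: Segment
    glycines: list[int]
    acidic_pairs: list[tuple[int, int]]
    basic_pairs: list[tuple[int, int]]

    @property
    def is_clean(self) -> bool:
        return not (self.glycines or self.acidic_pairs or self.basic_pairs)


def destabilization_scan(sequence: str, helix: Segment,
                         first_residue: int = 1) -> DestabilizationReport:
    """Scan a helix for sequence features that destabilise helical structure.

    ``sequence`` is a one-letter string whose first character is residue
    ``first_residue``.  Reports glycine positions and like-charged pairs
    (acidic D/E with D/E, basic K/R with K/R) at sequence separation 3 or 4
    within the helix.
    """
    last_residue = first_residue + len(sequence) - 1
    if helix.start_residue < first_residue or helix.end_residue > last_residue:
        raise InputError(
            f"helix {helix.as_tuple()} outside sequence range "
            f"{first_residue}-{last_residue}")

    def aa(resnum: int) -> str:
        return sequence[resnum - first_residue].upper()

    residues = list(helix.residues())
    glycines = [r for r in residues if aa(r) == "G"]
    acidic_pairs = []
    basic_pairs = []
    for r in residues:
        for sep in (3, 4):
            s = r + sep
            if s > helix.end_residue:
                continue
            if aa(r) in ACIDIC and aa(s) in ACIDIC:
                acidic_pairs.append((r, s))
            if aa(r) in BASIC and aa(s) in BASIC:
                basic_pairs.append((r, s))
    return DestabilizationReport(helix=helix, glycines=glycines,
                                 acidic_pairs=acidic_pairs,
                                 basic_pairs=basic_pairs)
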