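import itertools

import numpy as np
import pytest

from helpers import brute_force_min_distance
from groovetraj.contacts import (ContactPair, PersistenceRecord,
                                 destabilization_scan, interacting_pairs,
                                 pair_persistence, pairs_unique_to_group,
                                 stable_pairs)
from groovetraj.errors import ConfigError, InputError
from groovetraj.helicity import Segment
from groovetraj.structures import RegionMap, Structure, Trajectory
from groovetraj.synthetic import build_helix

# Bcl-X_L_ helix H2 (residues 85-100); positions 87/91/92/94/95/96/98 carry
# K/R/E/G/D/E/E, the features implicated in H2 unwinding
H2_SEQ = "AVKQALREAGDEFELR"
H2_FIRST = 85

TWO_HELIX_MAP = RegionMap(regions={"HA": [(1, 12)], "HB": [(101, 112)]},
                          helix_names=["HA", "HB"])


def _two_helices(offset):
    a = build_helix("L" * 12, first_residue=1, chain_id="A")
    b = build_helix("L" * 12, first_residue=101, chain_id="B")
    coords = np.concatenate([a.coords, b.coords + np.asarray(offset)])
    n = a.n_atoms + b.n_atoms
    return Structure(
        serials=range(1, n + 1),
        names=list(a.names) + list(b.names),
        elements=list(a.elements) + list(b.elements),
        residue_numbers=list(a.residue_numbers) + list(b.residue_numbers),
        residue_names=list(a.residue_names) + list(b.residue_names),
        chains=list(a.chains) + list(b.chains),
        coords=coords)


def _oracle_pairs(struct, region_map, cutoff, min_seq_sep):
    """Exhaustive reference: all residue pairs, brute-force min distances."""
    heavy = struct.atom_indices(heavy_only=True)
    by_res = {}
    for i in heavy:
        by_res.setdefault(int(struct.residue_numbers[i]), []).append(i)
    names = region_map.helix_names + region_map.loop_names
    expected = set()
    for ra, rb in itertools.combinations(sorted(by_res), 2):
        ga = region_map.region_of(ra, names)
        gb = region_map.region_of(rb, names)
        if ga is None or gb is None or ga == gb or abs(ra - rb) < min_seq_sep:
            continue
        d = brute_force_min_distance(struct.coords[by_res[ra]],
                                     struct.coords[by_res[rb]])
        if d < cutoff:
            expected.add((ra, rb))
    return expected


class TestInteractingPairs:
    def test_matches_exhaustive_oracle(self):
        struct = _two_helices([7.5, 1.0, 0.5])
        expected = _oracle_pairs(struct, TWO_HELIX_MAP, 4.0, 3)
        got = interacting_pairs([struct], TWO_HELIX_MAP)
        assert {(p.res_a, p.res_b) for p in got} == expected
        assert expected    # the fixture geometry does produce contacts

    def test_distant_helices_give_empty_set(self):
        struct = _two_helices([20.0, 20.0, 0.0])
        assert interacting_pairs([struct], TWO_HELIX_MAP) == set()

    def test_monotone_in_cutoff(self):
        struct = _two_helices([8.0, 0.0, 0.0])
        small = interacting_pairs([struct], TWO_HELIX_MAP, cutoff_A=3.5)
        large = interacting_pairs([struct], TWO_HELIX_MAP, cutoff_A=4.0)
        assert small <= large

    def test_union_over_structures(self):
        s1 = _two_helices([7.5, 0.0, 0.0])
        s2 = _two_helices([0.0, 7.5, 0.0])
        both = interacting_pairs([s1, s2], TWO_HELIX_MAP)
        assert both == (interacting_pairs([s1], TWO_HELIX_MAP)
                        | interacting_pairs([s2], TWO_HELIX_MAP))

    def test_same_region_pairs_excluded(self):
        struct = _two_helices([20.0, 0.0, 0.0])
        one_region = RegionMap(regions={"ALL": [(1, 112)]},
                               helix_names=["ALL"])
        assert interacting_pairs([struct], one_region) == set()

    def test_empty_allowed_set_rejected(self):
        struct = _two_helices([7.5, 0.0, 0.0])
        with pytest.raises(ConfigError):
            interacting_pairs([struct], RegionMap(regions={"X": [(1, 5)]}),
                              allowed_regions=[])


def _pairwise_trajectory(distances):
    s = Structure(serials=[1, 2], names=["CA", "CA"], elements=["C", "C"],
                  residue_numbers=[1, 2], residue_names=["ALA", "ALA"],
                  chains=["A", "A"], coords=np.zeros((2, 3)))
    frames = np.zeros((len(distances), 2, 3))
    frames[:, 1, 0] = distances
    return Trajectory(topology=s, frames=frames)


PAIR12 = ContactPair(1, 2, "HA", "HB")


class TestPersistence:
    def test_counting_fraction(self):
        traj = _pairwise_trajectory([3.0] * 7 + [5.0] * 3)
        rec = pair_persistence(traj, PAIR12)
        assert rec.frac_below_cutoff == pytest.approx(0.7)

    def test_constant_trace(self):
        traj = _pairwise_trajectory([3.0] * 10)
        rec = pair_persistence(traj, PAIR12)
        assert rec.mean_min_dist_A == pytest.approx(3.0)
        assert rec.frac_below_cutoff == pytest.approx(1.0)

    def test_window_restricts_frames(self):
        traj = _pairwise_trajectory([3.0] * 5 + [9.0] * 5)
        rec = pair_persistence(traj, PAIR12, window_ps=(5.0, 9.0))
        assert rec.frac_below_cutoff == pytest.approx(0.0)

    def test_empty_window_rejected(self):
        traj = _pairwise_trajectory([3.0] * 5)
        with pytest.raises(InputError):
            pair_persistence(traj, PAIR12, window_ps=(100.0, 200.0))

    def test_fraction_reaches_one_for_large_cutoff(self):
        traj = _pairwise_trajectory([3.0, 12.0, 30.0])
        rec = pair_persistence(traj, PAIR12, cutoff_A=1e6)
        assert rec.frac_below_cutoff == pytest.approx(1.0)

    def test_scheduled_contact_recovers_draws(self, contact_sim):
        traj, manifest = contact_sim
        pair = ContactPair(6, 106, "HA", "HB")
        rec = pair_persistence(traj, pair)
        assert rec.frac_below_cutoff == pytest.approx(
            manifest.contact_fraction(6, 106), abs=1e-9)


def _records(fracs, pair=PAIR12):
    return [PersistenceRecord(pair=pair, sim_id=f"sim{i}",
                              mean_min_dist_A=3.5, frac_below_cutoff=f,
                              window_ps=(0.0, 10.0))
            for i, f in enumerate(fracs)]


class TestStablePairs:
    def test_two_sims_strictly_above_half(self):
        assert stable_pairs(_records([0.6, 0.4, 0.55, 0.1])) == {PAIR12}

    def test_exactly_half_is_not_stable(self):
        assert stable_pairs(_records([0.5, 0.5, 0.5, 0.5])) == set()

    def test_one_sim_is_not_enough(self):
        assert stable_pairs(_records([0.9, 0.2, 0.2, 0.2])) == set()

    def test_min_sims_one_threshold_zero_gives_all_ever_contacting(self):
        recs = _records([0.01, 0.0, 0.0, 0.0])
        assert stable_pairs(recs, frac_threshold=0.0, min_sims=1) == {PAIR12}


class TestSetDifference:
    def test_difference(self):
        p1 = ContactPair(1, 5, "HA", "HB")
        p2 = ContactPair(2, 6, "HA", "HB")
        p3 = ContactPair(3, 7, "HA", "HB")
        assert pairs_unique_to_group({p1, p2, p3}, {p2}) == {p1, p3}

    def test_identical_groups_empty(self):
        p = {ContactPair(1, 5, "HA", "HB")}
        assert pairs_unique_to_group(p, p) == set()

    def test_empty_reference_returns_all(self):
        p = {ContactPair(1, 5, "HA", "HB")}
        assert pairs_unique_to_group(p, set()) == p


class TestDestabilizationScan:
    def test_bclxl_h2_worked_example(self):
        report = destabilization_scan(H2_SEQ, Segment(85, 100),
                                      first_residue=H2_FIRST)
        assert report.glycines == [94]
        assert sorted(report.acidic_pairs) == [(92, 95), (92, 96), (95, 98)]
        assert report.basic_pairs == [(87, 91)]

    def test_separation_three_acidic_pair(self):
        report = destabilization_scan("AEAAEAA", Segment(1, 7))
        assert report.acidic_pairs == [(2, 5)]
        assert report.basic_pairs == []
        assert report.glycines == []

    def test_all_alanine_is_clean(self):
        report = destabilization_scan("AAAAAAAA", Segment(1, 8))
        assert report.is_clean

    def test_helix_outside_sequence_rejected(self):
        with pytest.raises(InputError):
            destabilization_scan("AAAA", Segment(1, 10))
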