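import numpy as np
import pytest

from eemcc.hierarchy import build_hierarchy
from eemcc.shells import (assign_hbonds, compute_shell_map,
                          label_waters, rad_shell, rad_shell_bruteforce,
                          shell_statistics)
from eemcc.synthetic import (concat_topologies, dipeptide_coordinates,
                             dipeptide_topology, water_topology)
from eemcc.topology import Topology


def _acceptor_site(name, x, y, z, charge=-0.834, resid=1):
    """Single negatively charged point monomer used as an H-bond acceptor."""
    return Topology(
        names=np.array([name], dtype=object),
        elements=np.array(["O"], dtype=object),
        masses=np.array([15.9994]), charges=np.array([charge]),
        resids=np.array([resid]), resnames=np.array(["ACC"], dtype=object),
        segids=np.array(["X"], dtype=object),
    ), np.array([x, y, z])


class TestRadShell:
    def test_two_particles_are_mutual_neighbors(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert rad_shell(pos, 0) == [1]
        assert rad_shell(pos, 1) == [0]

    def test_collinear_farther_particle_is_blocked(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert rad_shell(pos, 0) == [1]

    def test_perpendicular_particle_is_not_blocked(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])
        assert rad_shell(pos, 0) == [1, 2]

    def test_coincident_positions_raise(self):
        pos = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            rad_shell(pos, 0)

    def test_matches_bruteforce_on_small_random_configurations(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            pos = rng.uniform(0, 6, size=(n, 3))
            center = int(rng.integers(n))
            assert rad_shell(pos, center, cutoff=50.0) == \
                rad_shell_bruteforce(pos, center)

    def test_closest_neighbor_always_in_shell(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pos = rng.uniform(0, 8, size=(12, 3))
            d = np.linalg.norm(pos[1:] - pos[0], axis=1)
            nearest = 1 + int(np.argmin(d))
            assert rad_shell(pos, 0, cutoff=50.0)[0] == nearest

    def test_minimum_image_wraps_neighbors(self):
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0.5, 5, 5], [9.5, 5, 5]])
        shell = rad_shell(pos, 0, box=box)
        assert shell == [1]

    def test_accepted_only_variant_agrees_on_water_box(self, water_box):
        _, hier, batch = water_box
        pos = hier.ua_positions(batch.coordinates[0])
        box = batch.box[0]
        for i in range(0, 216, 24):
            assert rad_shell(pos, i, box=box) == \
                rad_shell(pos, i, box=box, blockers="accepted")


class TestHBonds:
    def _donor_system(self, r1, r2):
        wtop = water_topology(1)
        a1, p1 = _acceptor_site("O1", 0.9572 + r1, 0.0, 0.0, resid=5)
        a2, p2 = _acceptor_site("O2", 0.9572, r2, 0.0, resid=6)
        top = concat_topologies([wtop, a1, a2])
        coords = np.array([
            [0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.24, 0.927, 0.0],
            p1, p2,
        ])
        hier = build_hierarchy(top)
        shells = [rad_shell(hier.ua_positions(coords), i, cutoff=50.0)
                  for i in range(3)]
        return hier, coords, shells

    def test_closer_acceptor_wins_at_equal_charge(self):
        # q_D q_A / r^2: -0.107 at 1.8 Å beats -0.087 at 2.0 Å
        hier, coords, shells = self._donor_system(2.0, 1.8)
        recs = assign_hbonds(hier, coords, None, shells)
        by_h = {r.donor_hydrogen: r for r in recs}
        assert by_h[1].acceptor_ua == 2  # the closer acceptor's UA
        assert by_h[1].r == pytest.approx(1.8)

    def test_tie_breaks_to_lowest_atom_index(self):
        hier, coords, shells = self._donor_system(1.8, 1.8)
        recs = assign_hbonds(hier, coords, None, shells)
        by_h = {r.donor_hydrogen: r for r in recs}
        assert by_h[1].acceptor_ua == 1

    def test_no_candidate_means_no_bond(self, two_waters):
        top, hier = two_waters
        coords = np.array([
            [0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0],
            [50.0, 0, 0], [50.96, 0, 0], [49.76, 0.93, 0],
        ])
        shells = [[], []]  # nothing in shell
        assert assign_hbonds(hier, coords, None, shells) == []

    def test_water_donates_at_most_two_per_frame(self, water_box):
        _, hier, batch = water_box
        smap = compute_shell_map(hier, batch.coordinates[:1], batch.box[:1])
        donors = {}
        for rec in smap.hbonds[0]:
            donors.setdefault(rec.donor_ua, set()).add(rec.donor_hydrogen)
        assert donors and all(len(h) <= 2 for h in donors.values())


class TestProximityGrouping:
    def _solute_with_waters(self):
        ptop = dipeptide_topology()
        pcoords = dipeptide_coordinates(-80.0, 150.0)
        wtop = water_topology(2, resid_start=50)
        top = concat_topologies([ptop, wtop])
        hier = build_hierarchy(top)
        # waters near the ACE methyl (atom CH3) and the NME methyl
        ace_ch3 = pcoords[0]
        nme_ch3 = pcoords[-4]
        w1 = ace_ch3 + np.array([0.0, 0.0, 3.0])
        w2 = nme_ch3 + np.array([0.0, 0.0, -3.1])
        coords = np.vstack([
            pcoords,
            [w1, w1 + [0.96, 0, 0], w1 + [-0.24, 0.93, 0]],
            [w2, w2 + [0.96, 0, 0], w2 + [-0.24, 0.93, 0]],
        ])
        return hier, coords

    def test_labels_match_bruteforce_nearest_scan(self):
        hier, coords = self._solute_with_waters()
        shells = [rad_shell(hier.ua_positions(coords), i, cutoff=50.0)
                  for i in range(len(hier.uas))]
        labels = label_waters(hier, coords, None, shells)
        pos = hier.ua_positions(coords)
        is_water = hier.is_water_ua()
        for wm, lab in labels.items():
            wua = hier.monomers[wm].uas[0]
            d = np.linalg.norm(pos - pos[wua], axis=1)
            d[is_water] = np.inf
            assert lab.nearest_ua == int(np.argmin(d))
            assert lab.nearest_monomer == hier.uas[int(np.argmin(d))].monomer

    def test_residue_pairs_emitted_for_multi_contact_waters(self):
        hier, coords = self._solute_with_waters()
        shells = [rad_shell(hier.ua_positions(coords), i, cutoff=50.0)
                  for i in range(len(hier.uas))]
        labels = label_waters(hier, coords, None, shells)
        for lab in labels.values():
            pairs = lab.residue_pairs()
            n = len(lab.contacted_monomers)
            assert len(pairs) == n * (n - 1) // 2
            for a, b in pairs:
                assert a < b

    def test_isolated_water_is_bulk(self, two_waters):
        top, hier = two_waters
        coords = np.array([
            [0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0],
            [3.0, 0, 0], [3.96, 0, 0], [2.76, 0.93, 0],
        ])
        shells = [rad_shell(hier.ua_positions(coords), i) for i in range(2)]
        labels = label_waters(hier, coords, None, shells)
        assert all(lab.is_bulk for lab in labels.values())
        assert all(lab.label == "bulk" for lab in labels.values())


class TestShellStatistics:
    def test_bulk_water_coordination_number_in_physical_band(self, water_box):
        _, hier, batch = water_box
        smap = compute_shell_map(hier, batch.coordinates[:1], batch.box[:1],
                                 with_hbonds=False)
        nc, _ = shell_statistics(hier, smap)
        assert 4.0 <= nc.mean() <= 7.0

    def test_nearest_residue_counts_partition_first_shell(self, solvated):
        _, hier, batch = solvated
        smap = compute_shell_map(hier, batch.coordinates[:1], batch.box[:1],
                                 with_hbonds=False)
        labels = smap.water_labels[0]
        first_shell = [l for l in labels.values() if not l.is_bulk]
        by_res = {}
        for lab in first_shell:
            by_res[lab.nearest_monomer] = by_res.get(lab.nearest_monomer, 0) + 1
        assert sum(by_res.values()) == len(first_shell)
        assert len(labels) == len(hier.water_monomers)
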