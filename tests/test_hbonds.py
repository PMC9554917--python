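"""Hydrogen-bond geometry, occupancy exactness, and oracle equivalence."""

import itertools

import numpy as np
import pytest

from lipsite.core import AtomRecord, SegmentClass, Selection, Topology, Trajectory, select
from lipsite.hbonds import HBondCriteria, find_hbonds, hbond_occupancy, water_site_occupancy
from lipsite.synth import (
    HBondProgram,
    TrajectorySchedule,
    WaterSiteProgram,
    simulate_trajectory,
)


def nho_topology():
    """N(H) donor plus O acceptor, as separate residues."""
    atoms = [
        AtomRecord(0, "N", "N", 0, "RES", "A", SegmentClass.PROTEIN),
        AtomRecord(1, "H", "H", 0, "RES", "A", SegmentClass.PROTEIN),
        AtomRecord(2, "O", "O", 1, "RES", "A", SegmentClass.PROTEIN),
    ]
    return Topology(atoms=atoms, bonds={(0, 1)})


def nho_frame(d_no: float, angle_deg: float = 180.0) -> np.ndarray:
    """Donor at origin, H at 1 A along +x; acceptor placed so the
    D-H...A angle is ``angle_deg`` at donor-acceptor distance d_no."""
    h = np.array([1.0, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg)
    # position acceptor relative to H along a direction making the angle
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # choose |H-A| so that |D-A| = d_no
    # solve |h + t*direction| = d_no
    b = 2 * np.dot(h, direction)
    c = 1.0 - d_no ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    a = h + t * direction
    return np.array([[0.0, 0, 0], h, a])


DONORS = Selection((0,))
ACCEPTORS = Selection((2,))


class TestFindHbonds:
    def test_collinear_within_cutoff_detected(self):
        frame = nho_frame(2.8, 180.0)
        out = find_hbonds(frame, nho_topology(), DONORS, ACCEPTORS)
        assert out == [(0, 1, 2)]

    def test_beyond_distance_cutoff_not_detected(self):
        # the 3.2 A donor-acceptor criterion rejects a 3.5 A contact
        frame = nho_frame(3.5, 180.0)
        assert find_hbonds(frame, nho_topology(), DONORS, ACCEPTORS) == []

    def test_angle_gate_rejects_bent_geometry(self):
        frame = nho_frame(2.8, 90.0)
        assert find_hbonds(frame, nho_topology(), DONORS, ACCEPTORS) == []

    def test_donor_without_hydrogen_is_error(self):
        atoms = [
            AtomRecord(0, "N", "N", 0, "RES", "A", SegmentClass.PROTEIN),
            AtomRecord(1, "O", "O", 1, "RES", "A", SegmentClass.PROTEIN),
        ]
        topo = Topology(atoms=atoms)
        with pytest.raises(ValueError, match="without bonded hydrogens"):
            find_hbonds(np.zeros((2, 3)), topo, Selection((0,)), Selection((1,)))

    def test_minimum_image_applied_when_box_present(self):
        frame = np.array([[0.5, 0, 0], [1.5, 0, 0], [19.3, 0.0, 0.0]])
        topo = nho_topology()
        box = np.array([20.0, 20.0, 20.0])
        # unwrapped distance 18.8 A; minimum image 1.2 A with the
        # acceptor's image at x = -0.7, so put H between them
        frame[1] = [-0.2, 0.0, 0.0]
        out = find_hbonds(frame, topo, DONORS, ACCEPTORS,
                          HBondCriteria(), box=box)
        assert out == [(0, 1, 2)]

    def test_monotone_in_cutoffs(self):
        """Occupancy never decreases as d_cut grows or angle_cut shrinks."""
        rng = np.random.default_rng(3)
        topo = nho_topology()
        frames = []
        for _ in range(40):
            d = rng.uniform(2.4, 4.0)
            ang = rng.uniform(100.0, 180.0)
            frames.append(nho_frame(d, ang))
        traj = Trajectory(np.stack(frames))
        prev = -1.0
        for d_cut in (2.6, 3.0, 3.4, 3.8):
            occ = hbond_occupancy(traj, topo, DONORS, ACCEPTORS,
                                  HBondCriteria(d_cut=d_cut)).occupancy
            assert occ >= prev
            prev = occ
        prev = -1.0
        for angle_cut in (170.0, 150.0, 120.0, 90.0):
            occ = hbond_occupancy(traj, topo, DONORS, ACCEPTORS,
                                  HBondCriteria(angle_cut=angle_cut)).occupancy
            assert occ >= prev
            prev = occ

    def test_matches_all_pairs_oracle(self, rng):
        """Brute-force O(N^2) oracle over every donor/acceptor pair."""
        n_donors, n_acceptors = 6, 7
        atoms, bonds = [], set()
        for i in range(n_donors):
            atoms.append(AtomRecord(2 * i, f"N{i}", "N", i, "RES", "A",
                                    SegmentClass.PROTEIN))
            atoms.append(AtomRecord(2 * i + 1, f"H{i}", "H", i, "RES", "A",
                                    SegmentClass.PROTEIN))
            bonds.add((2 * i, 2 * i + 1))
        off = 2 * n_donors
        for j in range(n_acceptors):
            atoms.append(AtomRecord(off + j, f"O{j}", "O", n_donors + j,
                                    "RES", "A", SegmentClass.PROTEIN))
        topo = Topology(atoms=atoms, bonds=bonds)
        frame = rng.uniform(-4, 4, size=(len(atoms), 3))
        donors = Selection(tuple(2 * i for i in range(n_donors)))
        acceptors = Selection(tuple(off + j for j in range(n_acceptors)))
        crit = HBondCriteria()
        got = set(find_hbonds(frame, topo, donors, acceptors, crit))
        expected = set()
        for d, a in itertools.product(donors, acceptors):
            if np.linalg.norm(frame[a] - frame[d]) > crit.d_cut:
                continue
            h = d + 1
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
            if ang >= crit.angle_cut:
                expected.add((d, h, a))
        assert got == expected


class TestOccupancy:
    def test_programmed_occupancy_recovered_exactly(self, toy_system):
        topo = toy_system.topology
        donor = select(topo, segment="ligand", names=["LN1"]).indices[0]
        h = topo.bonded_hydrogens(donor)[0]
        acc = select(topo, segment="protein", names=["O"],
                     residue_ids=[5]).indices[0]
        sched = TrajectorySchedule(
            n_frames=100, noise_sigma=0.05, seed=2,
            hbond_programs=[HBondProgram(donor, h, acc, 0.65)],
        )
        traj = simulate_trajectory(toy_system, sched)
        rep = hbond_occupancy(traj, topo, Selection((donor,)), Selection((acc,)))
        assert rep.occupancy == 0.65
        assert rep.frames_hit == 65 and rep.n_frames == 100

    @pytest.mark.parametrize("target", [0.0, 1.0])
    def test_occupancy_bounds(self, toy_system, target):
        topo = toy_system.topology
        donor = select(topo, segment="ligand", names=["LN1"]).indices[0]
        h = topo.bonded_hydrogens(donor)[0]
        acc = select(topo, segment="protein", names=["O"],
                     residue_ids=[5]).indices[0]
        sched = TrajectorySchedule(
            n_frames=20,
            hbond_programs=[HBondProgram(donor, h, acc, target)],
        )
        traj = simulate_trajectory(toy_system, sched)
        rep = hbond_occupancy(traj, topo, Selection((donor,)), Selection((acc,)))
        assert rep.occupancy == target

    def test_any_of_semantics_over_alternating_donors(self):
        """Two donors where exactly one qualifies per frame, alternating:
        the pair occupancy is 1.0, verified against an exhaustive scan."""
        atoms = [
            AtomRecord(0, "N1", "N", 0, "RES", "A", SegmentClass.PROTEIN),
            AtomRecord(1, "H1", "H", 0, "RES", "A", SegmentClass.PROTEIN),
            AtomRecord(2, "N2", "N", 1, "RES", "A", SegmentClass.PROTEIN),
            AtomRecord(3, "H2", "H", 1, "RES", "A", SegmentClass.PROTEIN),
            AtomRecord(4, "O", "O", 2, "RES", "A", SegmentClass.PROTEIN),
        ]
        topo = Topology(atoms=atoms, bonds={(0, 1), (2, 3)})
        near = nho_frame(2.8, 180.0)
        frames = []
        for i in range(10):
            f = np.zeros((5, 3))
            far = np.array([30.0, 30.0, 30.0])
            if i % 2 == 0:
                f[0], f[1], f[4] = near
                f[2], f[3] = far, far + [1, 0, 0]
            else:
                f[2], f[3], f[4] = near
                f[0], f[1] = far, far + [1, 0, 0]
            frames.append(f)
        traj = Trajectory(np.stack(frames))
        donors = Selection((0, 2))
        rep = hbond_occupancy(traj, topo, donors, Selection((4,)))
        assert rep.occupancy == 1.0
        # exhaustive per-frame oracle: each frame must have >= 1 triple
        for f in range(traj.n_frames):
            assert find_hbonds(traj.frame(f), topo, donors, Selection((4,)))

    def test_empty_selection_is_error(self, toy_system):
        traj = simulate_trajectory(toy_system, TrajectorySchedule(n_frames=1))
        with pytest.raises(ValueError, match="empty"):
            hbond_occupancy(traj, toy_system.topology, Selection(()),
                            Selection((0,)))


class TestWaterSiteOccupancy:
    def _site(self, toy_system):
        return select(toy_system.topology, segment="protein", names=["O"],
                      residue_ids=[3])

    def _traj(self, toy_system, n_alt=1, target=0.51):
        site = self._site(toy_system)
        sched = TrajectorySchedule(
            n_frames=100, noise_sigma=0.05, seed=4,
            water_site_programs=[WaterSiteProgram(tuple(site.indices), target,
                                                  n_alternating_waters=n_alt)],
        )
        return simulate_trajectory(toy_system, sched)

    def test_programmed_water_occupancy_exact(self, toy_system):
        traj = self._traj(toy_system)
        rep = water_site_occupancy(traj, toy_system.topology,
                                   self._site(toy_system), mode="any")
        assert rep.occupancy == 0.51

    def test_water_identity_is_irrelevant(self, toy_system):
        traj = self._traj(toy_system, n_alt=2)
        rep = water_site_occupancy(traj, toy_system.topology,
                                   self._site(toy_system), mode="any")
        assert rep.occupancy == 0.51

    def test_mode_all_requires_every_site_atom(self, toy_system):
        site3 = select(toy_system.topology, segment="protein", names=["O"],
                       residue_ids=[3, 4, 5])
        sched = TrajectorySchedule(
            n_frames=50, noise_sigma=0.05, seed=4,
            water_site_programs=[WaterSiteProgram(tuple(site3.indices), 0.5)],
        )
        traj = simulate_trajectory(toy_system, sched)
        rep = water_site_occupancy(traj, toy_system.topology, site3, mode="all")
        assert rep.occupancy == 0.0  # only the first site atom is engaged

    def test_no_waters_is_error(self):
        from lipsite.synth import ToySystemSpec, build_toy_system

        system = build_toy_system(ToySystemSpec(seed=5, n_waters=0,
                                                n_lipids_per_leaflet=0))
        traj = simulate_trajectory(system, TrajectorySchedule(n_frames=1))
        site = select(system.topology, segment="protein", names=["O"],
                      residue_ids=[1])
        with pytest.raises(ValueError, match="water"):
            water_site_occupancy(traj, system.topology, site)
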