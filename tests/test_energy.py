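"""Lennard-Jones/Coulomb pair terms, group sums vs a brute-force oracle,
per-residue decomposition additivity, and the lipid contact census."""

import numpy as np
import pytest

from lipsite.core import (
    AtomRecord,
    SegmentClass,
    Selection,
    Topology,
    Trajectory,
    select,
)
from lipsite.energy import (
    COULOMB_CONSTANT,
    NBParams,
    coulomb_pair,
    group_interaction_energy,
    lipid_contact_census,
    lj_pair,
    per_residue_decomposition,
)
from lipsite.synth import ToySystemSpec, TrajectorySchedule, build_toy_system, simulate_trajectory

from conftest import make_atoms


def brute_force_energy(frame, box, topo, idx_a, idx_b, params):
    """Independent O(N^2) oracle: explicit python loop over every cross
    pair, minimum image applied per component."""
    vdw = elec = 0.0
    for i in idx_a:
        ai = topo.atoms[i]
        for j in idx_b:
            aj = topo.atoms[j]
            d = frame[j] - frame[i]
            if box is not None:
                d = d - box * np.round(d / box)
            r = float(np.sqrt((d ** 2).sum()))
            if r > params.cutoff:
                continue
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = (ai.lj_epsilon * aj.lj_epsilon) ** 0.5
            x6 = (rmin / r) ** 6
            vdw += eps * (x6 * x6 - 2 * x6)
            elec += params.coulomb_constant * ai.charge * aj.charge / r
    return vdw, elec


class TestPairTerms:
    def test_lj_minimum_is_minus_epsilon(self):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.12), ("B", "C", 0.0, 1.7, 0.09)])
        rmin = 1.8 + 1.7
        eps = (0.12 * 0.09) ** 0.5
        assert lj_pair(rmin, topo.atoms[0], topo.atoms[1]) == pytest.approx(-eps)

    def test_lj_zero_crossing(self):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.12), ("B", "C", 0.0, 1.7, 0.09)])
        r = (1.8 + 1.7) * 2 ** (-1 / 6)
        assert lj_pair(r, topo.atoms[0], topo.atoms[1]) == pytest.approx(0.0, abs=1e-12)

    def test_lj_direct_evaluation(self):
        # eps_ij = 0.1, Rmin_ij = 3.5, r = 4.0
        topo = make_atoms([("A", "C", 0.0, 1.75, 0.1), ("B", "C", 0.0, 1.75, 0.1)])
        expected = 0.1 * ((3.5 / 4.0) ** 12 - 2 * (3.5 / 4.0) ** 6)
        got = lj_pair(4.0, topo.atoms[0], topo.atoms[1])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-0.069617, abs=5e-6)

    def test_lj_hard_truncation_beyond_cutoff(self):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.12), ("B", "C", 0.0, 1.7, 0.09)])
        assert lj_pair(10.5, topo.atoms[0], topo.atoms[1]) == 0.0

    def test_lj_singularity(self):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.12)])
        with pytest.raises(ValueError, match="r must be > 0"):
            lj_pair(0.0, topo.atoms[0], topo.atoms[0])

    def test_coulomb_zero_charges(self):
        assert coulomb_pair(3.0, 0.0, 0.0) == 0.0

    def test_coulomb_direct_evaluation(self):
        assert coulomb_pair(3.0, 0.5, 0.5) == pytest.approx(
            COULOMB_CONSTANT * 0.25 / 3.0)
        assert coulomb_pair(3.0, 0.5, 0.5) == pytest.approx(27.672, abs=1e-3)

    def test_coulomb_sign_for_opposite_charges(self):
        got = coulomb_pair(3.32, 1.0, -1.0)
        assert got == pytest.approx(-COULOMB_CONSTANT / 3.32)
        assert got == pytest.approx(-100.019, abs=1e-3)


class TestGroupEnergy:
    def test_zero_when_beyond_cutoff(self):
        topo = make_atoms([("A", "C", 0.5, 1.8, 0.1), ("B", "C", -0.5, 1.8, 0.1)])
        frame = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        traj = Trajectory.single_frame(frame)
        vdw, elec = group_interaction_energy(
            traj, topo, Selection((0,)), Selection((1,)))
        assert vdw[0] == 0.0 and elec[0] == 0.0

    def test_matches_hand_sum_on_three_atoms(self):
        topo = make_atoms([
            ("A1", "C", 0.3, 1.8, 0.1),
            ("A2", "O", -0.4, 1.6, 0.15),
            ("B1", "N", 0.2, 1.85, 0.17),
        ])
        frame = np.array([[0.0, 0, 0], [1.5, 0.5, 0], [3.0, 1.0, -0.5]])
        traj = Trajectory.single_frame(frame)
        vdw, elec = group_interaction_energy(
            traj, topo, Selection((0, 1)), Selection((2,)))
        r02 = np.linalg.norm(frame[2] - frame[0])
        r12 = np.linalg.norm(frame[2] - frame[1])
        want_vdw = (lj_pair(r02, topo.atoms[0], topo.atoms[2])
                    + lj_pair(r12, topo.atoms[1], topo.atoms[2]))
        want_elec = (coulomb_pair(r02, 0.3, 0.2) + coulomb_pair(r12, -0.4, 0.2))
        assert vdw[0] == pytest.approx(want_vdw, abs=1e-12)
        assert elec[0] == pytest.approx(want_elec, abs=1e-12)

    def test_symmetric_in_group_order(self, rng):
        specs = [(f"X{i}", "C", rng.uniform(-0.5, 0.5), rng.uniform(1.4, 2.0),
                  rng.uniform(0.05, 0.2)) for i in range(20)]
        topo = make_atoms(specs)
        frame = rng.uniform(-6, 6, size=(20, 3))
        traj = Trajectory.single_frame(frame)
        a, b = Selection(tuple(range(10))), Selection(tuple(range(10, 20)))
        vdw_ab, elec_ab = group_interaction_energy(traj, topo, a, b)
        vdw_ba, elec_ba = group_interaction_energy(traj, topo, b, a)
        assert vdw_ab[0] == vdw_ba[0] and elec_ab[0] == elec_ba[0]

    def test_overlapping_selections_rejected(self, rng):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.1)] * 1)
        traj = Trajectory.single_frame(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="overlap"):
            group_interaction_energy(traj, topo, Selection((0,)), Selection((0,)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_random_systems(self, seed):
        """Randomized systems (with and without a box) agree with the
        explicit-loop oracle to 1e-8 kcal/mol."""
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(5, 40))
        n_b = int(rng.integers(5, 40))
        n = n_a + n_b
        specs = [(f"X{i}", "C", float(rng.uniform(-1, 1)),
                  float(rng.uniform(1.2, 2.0)), float(rng.uniform(0.05, 0.2)))
                 for i in range(n)]
        topo = make_atoms(specs)
        # rejection-sample positions so no cross pair sits below 1.5 A:
        # physical systems have no sub-A clashes, and such a clash makes
        # |E| so large that absolute float error exceeds 1e-8
        box = np.array([24.0, 24.0, 24.0]) if seed % 2 else None
        while True:
            frame = rng.uniform(0, 24, size=(n, 3))
            d = frame[:n_a, None, :] - frame[None, n_a:, :]
            if box is not None:
                d = d - box * np.round(d / box)
            if np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min() >= 1.5:
                break
        traj = Trajectory.single_frame(frame, box)
        params = NBParams()
        a = Selection(tuple(range(n_a)))
        b = Selection(tuple(range(n_a, n)))
        vdw, elec = group_interaction_energy(traj, topo, a, b, params)
        want_vdw, want_elec = brute_force_energy(
            frame, box, topo, a.indices, b.indices, params)
        assert abs(vdw[0] - want_vdw) < 1e-8
        assert abs(elec[0] - want_elec) < 1e-8


class TestPerResidueDecomposition:
    def _three_residue_system(self, rng):
        atoms = []
        coords = []
        # ligand: residue 0, two atoms at the origin region
        for k, name in enumerate(("L1", "L2")):
            atoms.append(AtomRecord(len(atoms), name, "C", 0, "LIG", "X",
                                    SegmentClass.LIGAND, 0.2, 1.8, 0.1))
            coords.append([0.5 * k, 0.0, 0.0])
        # three protein residues at 3, 4.5 and 6.5 A minimum distance
        for r, dist in enumerate((3.0, 4.5, 6.5), start=1):
            for k, (name, el, q) in enumerate(
                    (("N", "N", -0.4), ("CA", "C", 0.4))):
                atoms.append(AtomRecord(len(atoms), name, el, r, "RES", "P",
                                        SegmentClass.PROTEIN, q, 1.8, 0.12))
                coords.append([dist + 0.8 * k, 1.0 * r, 0.0])
        topo = Topology(atoms=atoms)
        return topo, np.array(coords)

    def test_single_residue_row_equals_group_energy(self, rng):
        topo, coords = self._three_residue_system(rng)
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        table = per_residue_decomposition(traj, topo, lig, shell=3.5)
        assert len(table) == 1
        res1 = select(topo, segment="protein", residue_ids=[1])
        vdw, elec = group_interaction_energy(traj, topo, lig, res1)
        assert table.iloc[0]["mean_vdw"] == pytest.approx(vdw[0], abs=1e-12)
        assert table.iloc[0]["mean_elec"] == pytest.approx(elec[0], abs=1e-12)

    def test_shell_gate_excludes_distant_residue(self, rng):
        topo, coords = self._three_residue_system(rng)
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        table = per_residue_decomposition(traj, topo, lig, shell=5.0)
        assert set(table["residue_id"]) == {1, 2}  # residue 3 at 6 A stays out

    def test_rows_sum_to_shell_total(self, rng):
        """Additivity: per-residue rows sum to the ligand-vs-all-shell
        total within 1e-8 kcal/mol."""
        topo, coords = self._three_residue_system(rng)
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        table = per_residue_decomposition(traj, topo, lig, shell=5.0)
        shell_atoms = select(topo, segment="protein", residue_ids=[1, 2])
        vdw, elec = group_interaction_energy(traj, topo, lig, shell_atoms)
        assert table["mean_vdw"].sum() == pytest.approx(vdw[0], abs=1e-8)
        assert table["mean_elec"].sum() == pytest.approx(elec[0], abs=1e-8)

    def test_empty_shell_gives_empty_table(self, rng):
        topo, coords = self._three_residue_system(rng)
        coords[2:] += 100.0  # push every residue out of range
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        table = per_residue_decomposition(traj, topo, lig, shell=5.0)
        assert len(table) == 0


class TestLipidCensus:
    def _census_system(self):
        """Ligand bead plus two lipids: one tail adjacent, one far away."""
        atoms = [AtomRecord(0, "L1", "C", 0, "LIG", "X",
                            SegmentClass.LIGAND, -0.3, 2.0, 0.2)]
        coords = [[0.0, 0.0, 0.0]]
        for lip, xy in enumerate(((4.0, 0.0), (30.0, 30.0)), start=1):
            atoms.append(AtomRecord(len(atoms), "P", "P", lip, "LIP", "L",
                                    SegmentClass.LIPID, 0.5, 2.0, 0.2))
            coords.append([xy[0], xy[1], 6.0])
            for t in range(3):
                atoms.append(AtomRecord(len(atoms), f"C{t+1}", "C", lip, "LIP",
                                        "L", SegmentClass.LIPID, 0.0, 2.0, 0.2))
                coords.append([xy[0], xy[1], 3.0 - 1.5 * t])
        return Topology(atoms=atoms), np.array(coords)

    def test_adjacent_tail_counted(self):
        topo, coords = self._census_system()
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        # the near tail sits ~4-5 A away (mean vdW about -0.5 kcal/mol
        # for these toy parameters); the far one is out of cutoff
        out = lipid_contact_census(traj, topo, lig, vdw_threshold=-0.3)
        assert out["tail_count"] == 1

    def test_all_far_gives_zero_counts(self):
        topo, coords = self._census_system()
        coords[1:] += 200.0
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        out = lipid_contact_census(traj, topo, lig)
        assert out["tail_count"] == 0 and out["head_count"] == 0

    def test_counts_monotone_in_threshold(self):
        """Lowering (more negative) thresholds can only shrink counts."""
        topo, coords = self._census_system()
        traj = Trajectory.single_frame(coords)
        lig = select(topo, segment="ligand")
        prev = None
        for thr in (-0.1, -0.5, -1.0, -2.0, -5.0):
            out = lipid_contact_census(traj, topo, lig, vdw_threshold=thr,
                                       polar_threshold=thr)
            counts = (out["tail_count"], out["head_count"])
            if prev is not None:
                assert counts[0] <= prev[0] and counts[1] <= prev[1]
            prev = counts

    def test_no_lipids_is_error(self, rng):
        topo = make_atoms([("A", "C", 0.0, 1.8, 0.1)])
        traj = Trajectory.single_frame(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="lipid"):
            lipid_contact_census(traj, topo, Selection((0,)))
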