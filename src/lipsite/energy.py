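"""Pairwise Lennard-Jones and Coulomb interaction energies.

Functional forms follow the Amber convention: 12-6 LJ written in
Rmin–epsilon form, E = eps_ij [(Rmin_ij/r)^12 − 2 (Rmin_ij/r)^6], with
Lorentz–Berthelot combining (Rmin_ij = Rmin/2_i + Rmin/2_j, eps_ij =
sqrt(eps_i eps_j)); Coulomb E = k q_i q_j / r with k = 332.0636
kcal·Å·mol⁻¹·e⁻² and dielectric 1.  Interactions are hard-truncated at
the cutoff (10 Å default).  All pairs handled here are intermolecular,
so no 1-4 scaling or exclusions apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AtomRecord,
    Selection,
    SegmentClass,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COULOMB_CONSTANT",
    "NBParams",
    "lj_pair",
    "coulomb_pair",
    "group_interaction_energy",
    "per_residue_decomposition",
    "lipid_contact_census",
]

COULOMB_CONSTANT = 332.0636  # kcal * A / (mol * e^2)


@dataclass(frozen=True)
class NBParams:
    cutoff: float = 10.0
    coulomb_constant: float = COULOMB_CONSTANT
    truncation: str = "hard"  # "hard" | "none"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.truncation not in ("hard", "none"):
            raise ValueError("truncation must be 'hard' or 'none'")


def lj_pair(r: float, atom_i: AtomRecord, atom_j: AtomRecord,
            params: NBParams = NBParams()) -> float:
    """12-6 LJ energy for one pair at separation r (Å)."""
    if r <= 0:
        raise ValueError("r must be > 0 (singularity at r = 0)")
    if params.truncation == "hard" and r > params.cutoff:
        return 0.0
    rmin = atom_i.lj_rmin_half + atom_j.lj_rmin_half
    eps = np.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    x6 = (rmin / r) ** 6
    return float(eps * (x6 * x6 - 2.0 * x6))


def coulomb_pair(r: float, q_i: float, q_j: float,
                 params: NBParams = NBParams()) -> float:
    """Coulomb energy for one pair at separation r (Å), dielectric 1."""
    if r <= 0:
        raise ValueError("r must be > 0 (singularity at r = 0)")
    if params.truncation == "hard" and r > params.cutoff:
        return 0.0
    return float(params.coulomb_constant * q_i * q_j / r)


def _frame_group_energy(
    frame: np.ndarray,
    box: np.ndarray | None,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    charges: np.ndarray,
    rmin_half: np.ndarray,
    eps: np.ndarray,
    params: NBParams,
) -> tuple[float, float]:
    d = frame[idx_a][:, None, :] - frame[idx_b][None, :, :]
    d = minimum_image_displacement(d, box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    mask = r <= params.cutoff if params.truncation == "hard" else np.ones_like(r, bool)
    r_safe = np.where(r > 0, r, np.inf)
    rmin_ij = rmin_half[idx_a][:, None] + rmin_half[idx_b][None, :]
    eps_ij = np.sqrt(eps[idx_a][:, None] * eps[idx_b][None, :])
    x6 = (rmin_ij / r_safe) ** 6
    vdw = float(np.sum(np.where(mask, eps_ij * (x6 * x6 - 2.0 * x6), 0.0)))
    qq = charges[idx_a][:, None] * charges[idx_b][None, :]
    elec = float(np.sum(np.where(mask, params.coulomb_constant * qq / r_safe, 0.0)))
    return vdw, elec


def group_interaction_energy(
    traj: Trajectory,
    topology: Topology,
    sel_a: Selection,
    sel_b: Selection,
    params: NBParams = NBParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (vdW, electrostatic) energy between two disjoint
    groups, summed over all cross pairs inside the cutoff."""
    if set(sel_a.indices) & set(sel_b.indices):
        raise ValueError("selections overlap; interaction energy undefined")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty selection")
    # canonical argument order makes E(A,B) == E(B,A) bit-exact (the
    # summation order would otherwise differ in the last ulp)
    if sel_b.indices < sel_a.indices:
        sel_a, sel_b = sel_b, sel_a
    idx_a, idx_b = sel_a.as_array(), sel_b.as_array()
    q = topology.charges()
    rh = topology.rmin_half()
    ep = topology.epsilon()
    vdw = np.empty(traj.n_frames)
    elec = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        vdw[f], elec[f] = _frame_group_energy(
            traj.frame(f), traj.frame_box(f), idx_a, idx_b, q, rh, ep, params
        )
    return vdw, elec


def _residue_groups(topology: Topology, segment=None) -> dict[tuple, list[int]]:
    groups: dict[tuple, list[int]] = {}
    for a in topology.atoms:
        if segment is not None and a.segment_class is not SegmentClass(segment):
            continue
        key = (a.chain, a.residue_id, a.residue_name, a.segment_class.value)
        groups.setdefault(key, []).append(a.atom_id)
    return groups


def shell_residues(
    traj: Trajectory,
    topology: Topology,
    ligand_sel: Selection,
    shell: float = 5.0,
    membership: str = "first_frame",
    segments: tuple[str, ...] = ("protein",),
) -> list[tuple]:
    """Residues with any heavy atom within ``shell`` Å of any ligand
    atom; decided on the first analyzed frame by default, or as the
    union over all frames with ``membership='any_frame'``."""
    if membership not in ("first_frame", "any_frame"):
        raise ValueError("membership must be 'first_frame' or 'any_frame'")
    lig_idx = ligand_sel.as_array()
    frames = [0] if membership == "first_frame" else list(range(traj.n_frames))
    keys = []
    for key, atom_ids in _residue_groups(topology).items():
        if key[3] not in segments:
            continue
        heavy = [i for i in atom_ids if topology.atoms[i].is_heavy]
        if not heavy:
            continue
        hit = False
        for f in frames:
            frame, box = traj.frame(f), traj.frame_box(f)
            d = frame[heavy][:, None, :] - frame[lig_idx][None, :, :]
            d = minimum_image_displacement(d, box)
            r2 = np.einsum("ijk,ijk->ij", d, d)
            if np.any(r2 <= shell * shell):
                hit = True
                break
        if hit:
            keys.append(key)
    return keys


def per_residue_decomposition(
    traj: Trajectory,
    topology: Topology,
    ligand_sel: Selection,
    shell: float = 5.0,
    params: NBParams = NBParams(),
    membership: str = "first_frame",
    segments: tuple[str, ...] = ("protein",),
) -> pd.DataFrame:
    """Mean ± sd vdW and electrostatic energy between the ligand and
    each residue inside the distance shell.

    Returns a DataFrame with one row per residue; empty (with a logged
    warning) when nothing is inside the shell.
    """
    if len(ligand_sel) == 0:
        raise ValueError("empty ligand selection")
    keys = shell_residues(traj, topology, ligand_sel, shell, membership, segments)
    if not keys:
        logger.warning("no residues within %.1f A shell of the ligand", shell)
        return pd.DataFrame(
            columns=["chain", "residue_id", "residue_name", "segment",
                     "mean_vdw", "sd_vdw", "mean_elec", "sd_elec", "n_frames"]
        )
    groups = _residue_groups(topology)
    lig_set = set(ligand_sel.indices)
    rows = []
    for key in sorted(keys, key=lambda k: (k[0], k[1])):
        atom_ids = [i for i in groups[key] if i not in lig_set]
        res_sel = Selection(tuple(atom_ids), f"residue {key[1]}")
        vdw, elec = group_interaction_energy(traj, topology, ligand_sel, res_sel, params)
        rows.append({
            "chain": key[0],
            "residue_id": key[1],
            "residue_name": key[2],
            "segment": key[3],
            "mean_vdw": float(np.mean(vdw)),
            "sd_vdw": float(np.std(vdw, ddof=1)) if traj.n_frames > 1 else 0.0,
            "mean_elec": float(np.mean(elec)),
            "sd_elec": float(np.std(elec, ddof=1)) if traj.n_frames > 1 else 0.0,
            "n_frames": traj.n_frames,
        })
    return pd.DataFrame(rows)


def lipid_contact_census(
    traj: Trajectory,
    topology: Topology,
    target_sel: Selection,
    params: NBParams = NBParams(),
    vdw_threshold: float = -1.0,
    polar_threshold: float = -1.0,
) -> dict:
    """Count lipid tails and head groups engaged with the target.

    A lipid *tail* (its bonded carbon chain) counts as engaged when its
    mean vdW energy with the target is at or below ``vdw_threshold``;
    a *head group* (non-carbon lipid beads) when its mean electrostatic
    energy is at or below ``polar_threshold``.  Thresholds are reporting
    conveniences and are logged.
    """
    logger.info(
        "lipid census thresholds: vdW <= %.2f, elec <= %.2f kcal/mol",
        vdw_threshold, polar_threshold,
    )
    lipid_groups = _residue_groups(topology, SegmentClass.LIPID)
    if not lipid_groups:
        raise ValueError("no lipid atoms in topology")
    rows = []
    tails = heads = 0
    for key in sorted(lipid_groups, key=lambda k: (k[0], k[1])):
        atom_ids = lipid_groups[key]
        tail_ids = [i for i in atom_ids if topology.atoms[i].element.upper() == "C"]
        head_ids = [i for i in atom_ids if topology.atoms[i].element.upper() != "C"]
        row = {"chain": key[0], "residue_id": key[1]}
        if tail_ids:
            vdw, _ = group_interaction_energy(
                traj, topology, target_sel,
                Selection(tuple(tail_ids), "lipid tail"), params)
            row["tail_mean_vdw"] = float(np.mean(vdw))
            if row["tail_mean_vdw"] <= vdw_threshold:
                tails += 1
                row["tail_engaged"] = True
            else:
                row["tail_engaged"] = False
        if head_ids:
            _, elec = group_interaction_energy(
                traj, topology, target_sel,
                Selection(tuple(head_ids), "lipid head"), params)
            row["head_mean_elec"] = float(np.mean(elec))
            if row["head_mean_elec"] <= polar_threshold:
                heads += 1
                row["head_engaged"] = True
            else:
                row["head_engaged"] = False
        rows.append(row)
    return {
        "tail_count": tails,
        "head_count": heads,
        "per_lipid": pd.DataFrame(rows),
        "vdw_threshold": vdw_threshold,
        "polar_threshold": polar_threshold,
    }
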