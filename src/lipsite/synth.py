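"""Synthetic membrane–protein–ligand systems with programmable ground truth.

The generator emulates the geometry of a lipid-embedded helical-bundle
receptor with an extrahelical (lipid-facing) pocket: pseudo-helix rods
of 4-atom residues (N, H, CA, O) arranged on a circle with one widened
angular gap forming an open groove, a slab of pseudo-lipids (head
particles plus tail carbons) in two leaflets, a rigid multi-fragment
ligand docked in the groove, and waters in the two solvent layers.

Nothing here integrates forces.  Trajectories are *programmed*:
hydrogen-bond events are deterministic frame assignments (so occupancy
recovery is exact, not stochastic), lipid tail carbons can be resampled
each frame with a prescribed density enrichment inside a region (so the
grid-free-energy recovery has an analytic expectation), and everything
else receives isotropic Gaussian positional noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AtomRecord, SegmentClass, Selection, Topology, Trajectory
from . import io as lio

__all__ = [
    "LigandFragmentSpec",
    "ToySystemSpec",
    "ToySystem",
    "HBondProgram",
    "WaterSiteProgram",
    "LipidEnrichment",
    "TrajectorySchedule",
    "build_toy_system",
    "build_pocket_fixture",
    "simulate_trajectory",
    "export_system",
    "default_ligand",
]

# Toy nonbonded parameters, physically plausible ranges
# (epsilon in [0.05, 0.2] kcal/mol, Rmin/2 in [1.2, 2.0] A, |q| <= 1 e).
_LJ = {
    "C": (2.0, 0.10),
    "N": (1.85, 0.17),
    "O": (1.70, 0.12),
    "H": (1.20, 0.05),
    "P": (2.0, 0.20),
}


@dataclass(frozen=True)
class LigandFragmentSpec:
    """A rigid group of ligand beads: (name, element, charge, local xyz)."""

    label: str
    beads: tuple[tuple[str, str, float, tuple[float, float, float]], ...]

    @property
    def net_charge(self) -> float:
        return float(sum(b[2] for b in self.beads))


def default_ligand() -> list[LigandFragmentSpec]:
    """Two-fragment ligand: an N-bearing aromatic-like ring (H-bond
    acceptor/donor anchor) and an O-bearing dioxole-like group."""
    ring = LigandFragmentSpec(
        "ring_n",
        (
            ("LC1", "C", 0.10, (0.0, 0.0, 0.0)),
            ("LC2", "C", 0.00, (1.4, 0.0, 0.0)),
            ("LC3", "C", 0.00, (2.1, 1.2, 0.0)),
            ("LC4", "C", 0.00, (1.4, 2.4, 0.0)),
            ("LN1", "N", -0.40, (0.0, 2.4, 0.6)),
            ("LH1", "H", 0.30, (-0.6, 3.2, 0.6)),
        ),
    )
    dioxole = LigandFragmentSpec(
        "dioxole",
        (
            ("LC5", "C", 0.30, (0.0, 0.0, 4.0)),
            ("LC6", "C", 0.10, (1.4, 0.0, 4.0)),
            ("LO1", "O", -0.25, (2.1, 1.1, 4.3)),
            ("LO2", "O", -0.25, (-0.7, 1.1, 4.3)),
            ("LC7", "C", 0.10, (0.7, 2.0, 4.6)),
        ),
    )
    return [ring, dioxole]


@dataclass
class ToySystemSpec:
    """Parameters of the generated system.  Same spec + seed gives a
    bit-identical system."""

    n_helices: int = 7  # helical-bundle-like, as in a 7TM receptor
    beads_per_helix: int = 12  # residues per rod; each residue = N,H,CA,O
    helix_radius: float = 9.0  # bundle radius, A
    residue_rise: float = 1.5  # A per residue along z
    groove_extra_angle: float = 0.4  # rad widening between rods 0 and 1
    n_lipids_per_leaflet: int = 40
    lipid_tail_length: int = 8
    n_waters: int = 60
    box: tuple[float, float, float] = (60.0, 60.0, 76.0)
    ligand: list[LigandFragmentSpec] = field(default_factory=default_ligand)
    ligand_net_charge: float | None = None
    seed: int = 0
    max_placement_retries: int = 2000

    def __post_init__(self):
        for name in ("n_helices", "beads_per_helix", "n_lipids_per_leaflet",
                     "lipid_tail_length", "n_waters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ToySystem:
    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3)
    box: np.ndarray  # (3,)
    manifest: dict

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def selection(self, segment: SegmentClass | str) -> Selection:
        idx = self.topology.segment_indices(segment)
        return Selection(tuple(int(i) for i in idx), f"segment={SegmentClass(segment).value}")


class GenerationError(RuntimeError):
    pass


def build_toy_system(spec: ToySystemSpec) -> ToySystem:
    """Deterministically build the toy system for ``spec``.

    Atom order: protein rods, ligand, lipids (upper then lower leaflet,
    head beads first within a lipid), waters.  The open groove between
    rods 0 and 1 seeds the extrahelical pocket; its centroid and extent
    are recorded in the manifest.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    atoms: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()
    coords: list[np.ndarray] = []
    rid = 0

    def add_atom(name, element, resname, chain, seg, charge, pos):
        i = len(atoms)
        rmin, eps = _LJ[element]
        atoms.append(AtomRecord(i, name, element, rid, resname, chain, seg,
                                charge, rmin, eps))
        coords.append(np.asarray(pos, dtype=float))
        return i

    # ---- protein rods ------------------------------------------------
    # rods on a circle; the angular gap between rod 0 and rod 1 is
    # widened to open the groove.
    z0 = -0.5 * (spec.beads_per_helix - 1) * spec.residue_rise
    if spec.n_helices > 0:
        base = 2.0 * np.pi / spec.n_helices
        angles = []
        a = 0.0
        for h in range(spec.n_helices):
            angles.append(a)
            a += base + (spec.groove_extra_angle if h == 0 else
                         -spec.groove_extra_angle / max(spec.n_helices - 1, 1))
    else:
        angles = []
    groove_angle = (angles[0] + (angles[1] if len(angles) > 1 else 0.0)) / 2.0
    for h, ang in enumerate(angles):
        cx = spec.helix_radius * np.cos(ang)
        cy = spec.helix_radius * np.sin(ang)
        for b in range(spec.beads_per_helix):
            z = z0 + b * spec.residue_rise
            n_i = add_atom("N", "N", "HLX", "P", SegmentClass.PROTEIN,
                           -0.45, (cx, cy, z))
            h_i = add_atom("HN", "H", "HLX", "P", SegmentClass.PROTEIN,
                           0.25, (cx + 0.7, cy + 0.7, z))
            ca_i = add_atom("CA", "C", "HLX", "P", SegmentClass.PROTEIN,
                            0.60, (cx, cy, z + 0.5))
            o_i = add_atom("O", "O", "HLX", "P", SegmentClass.PROTEIN,
                           -0.40, (cx - 0.7, cy - 0.7, z + 0.8))
            bonds.update({(n_i, h_i), (n_i, ca_i), (ca_i, o_i)})
            rid += 1

    # ---- ligand in the groove ---------------------------------------
    # just outside the bundle surface, in the widened groove: an
    # extrahelical ligand sits against the flanking rods (~4-5 A)
    pocket_center = np.array([
        (spec.helix_radius + 2.0) * np.cos(groove_angle),
        (spec.helix_radius + 2.0) * np.sin(groove_angle),
        0.0,
    ])
    ligand_first_atom = len(atoms)
    lig_charges = [b[2] for f in spec.ligand for b in f.beads]
    charge_shift = 0.0
    if spec.ligand_net_charge is not None and lig_charges:
        charge_shift = (spec.ligand_net_charge - sum(lig_charges)) / len(lig_charges)
    for frag in spec.ligand:
        frag_first = len(atoms)
        local = np.array([b[3] for b in frag.beads], dtype=float)
        centre = local.mean(axis=0)
        for (name, element, q, off) in frag.beads:
            pos = pocket_center + (np.asarray(off) - centre)
            add_atom(name, element, "LIG", "X", SegmentClass.LIGAND,
                     q + charge_shift, pos)
        # chain bonds within the fragment so H donors resolve
        for k in range(frag_first, len(atoms) - 1):
            bonds.add((k, k + 1))
        rid += 1

    # ---- lipids ------------------------------------------------------
    tail_len = spec.lipid_tail_length
    slab_half = tail_len * 1.5 + 2.0  # tails reach toward z=0
    min_xy_dist = 4.5
    placed_xy: list[np.ndarray] = []

    def place_xy():
        for _ in range(spec.max_placement_retries):
            xy = (rng.random(2) - 0.5) * (box[:2] - 4.0)
            if np.hypot(*xy) < spec.helix_radius + 5.0:
                continue  # keep out of the protein footprint
            if all(np.linalg.norm(xy - p) >= min_xy_dist for p in placed_xy):
                placed_xy.append(xy)
                return xy
        raise GenerationError(
            "could not place a lipid without overlap after "
            f"{spec.max_placement_retries} retries; reduce n_lipids or enlarge box"
        )

    for leaflet in (+1, -1):
        for _ in range(spec.n_lipids_per_leaflet):
            xy = place_xy()
            z_head = leaflet * slab_half
            p_i = add_atom("P", "P", "LIP", "L", SegmentClass.LIPID,
                           0.40, (xy[0], xy[1], z_head))
            og_i = add_atom("OG", "O", "LIP", "L", SegmentClass.LIPID,
                            -0.40, (xy[0], xy[1], z_head - leaflet * 1.0))
            bonds.add((p_i, og_i))
            prev = og_i
            for t in range(tail_len):
                z = z_head - leaflet * (2.0 + 1.5 * t)
                c_i = add_atom(f"C{t + 1}", "C", "LIP", "L",
                               SegmentClass.LIPID, 0.0, (xy[0], xy[1], z))
                bonds.add((prev, c_i))
                prev = c_i
            rid += 1

    # ---- waters ------------------------------------------------------
    solvent_floor = slab_half + 3.0
    for w in range(spec.n_waters):
        side = 1 if w % 2 == 0 else -1
        x, y = (rng.random(2) - 0.5) * (box[:2] - 4.0)
        zspan = box[2] / 2.0 - solvent_floor - 2.0
        z = side * (solvent_floor + rng.random() * max(zspan, 1.0))
        o_i = add_atom("OW", "O", "WAT", "W", SegmentClass.WATER,
                       -0.834, (x, y, z))
        h1 = add_atom("HW1", "H", "WAT", "W", SegmentClass.WATER,
                      0.417, (x + 0.76, y + 0.59, z))
        h2 = add_atom("HW2", "H", "WAT", "W", SegmentClass.WATER,
                      0.417, (x - 0.76, y + 0.59, z))
        bonds.update({(o_i, h1), (o_i, h2)})
        rid += 1

    topo = Topology(atoms=atoms, bonds=bonds)
    coords_arr = np.array(coords, dtype=float)
    manifest = {
        "spec": _spec_to_json(spec),
        "seed": spec.seed,
        "n_atoms": topo.n_atoms,
        "pocket_seed": {
            "center": [float(x) for x in pocket_center],
            "half_extent": [5.0, 5.0, 6.0],
        },
        "ligand_first_atom": ligand_first_atom,
        "membrane_slab_z": [-slab_half, slab_half],
        "ligand_net_charge": topo.net_charge(
            topo.segment_indices(SegmentClass.LIGAND)
        ),
    }
    return ToySystem(topo, coords_arr, box, manifest)


def _spec_to_json(spec: ToySystemSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["ligand"] = [
        {"label": f.label, "beads": [list(b[:3]) + [list(b[3])] for b in f.beads]}
        for f in spec.ligand
    ]
    return d


# ---------------------------------------------------------------------
# Trajectory programs

@dataclass(frozen=True)
class HBondProgram:
    """Deterministic donor–acceptor distance schedule.

    Exactly round(target_occupancy * n_frames) frames place the pair at
    ``bound_distance`` with a collinear donor–H···acceptor geometry; the
    remaining frames use ``unbound_distance``.
    """

    donor: int
    hydrogen: int
    acceptor: int
    target_occupancy: float
    bound_distance: float = 2.8
    unbound_distance: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must be in [0, 1]")
        if self.bound_distance > self.unbound_distance:
            raise ValueError(
                "infeasible program: bound_distance > unbound_distance"
            )


@dataclass(frozen=True)
class WaterSiteProgram:
    """Place a water hydrogen-bonded to the first site atom in exactly
    round(target_occupancy * n_frames) frames.  ``n_alternating_waters``
    rotates which water molecule plays partner across hit frames."""

    site_atoms: tuple[int, ...]
    target_occupancy: float
    bound_distance: float = 2.8
    n_alternating_waters: int = 1

    def __post_init__(self):
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must be in [0, 1]")
        if self.n_alternating_waters < 1:
            raise ValueError("n_alternating_waters must be >= 1")


@dataclass(frozen=True)
class LipidEnrichment:
    """Resample lipid tail carbons i.i.d. each frame so that the
    *expected* per-cell occupancy inside ``region`` over the membrane
    slab is ``ratio`` times the bulk value."""

    region_lo: tuple[float, float, float]
    region_hi: tuple[float, float, float]
    ratio: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("enrichment ratio must be > 0")
        if not all(h > l for l, h in zip(self.region_lo, self.region_hi)):
            raise ValueError("region_hi must exceed region_lo on every axis")


@dataclass
class TrajectorySchedule:
    n_frames: int
    hbond_programs: list[HBondProgram] = field(default_factory=list)
    water_site_programs: list[WaterSiteProgram] = field(default_factory=list)
    lipid_enrichment: LipidEnrichment | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _hit_frames(target: float, n_frames: int) -> np.ndarray:
    k = int(round(target * n_frames))
    return np.arange(n_frames) < k


def simulate_trajectory(system: ToySystem, schedule: TrajectorySchedule) -> Trajectory:
    """Generate a programmed trajectory from the base system.

    Gaussian noise of ``noise_sigma`` per coordinate is applied to every
    atom except those owned by an H-bond or water-site program (their
    geometry is exact by construction).  Lipid tail carbons are
    resampled i.i.d. per frame when an enrichment program is present.
    """
    topo = system.topology
    n = schedule.n_frames
    rng = np.random.default_rng(schedule.seed)
    base = system.coordinates
    frames = np.repeat(base[None, :, :], n, axis=0)
    if schedule.noise_sigma > 0:
        frames += rng.normal(0.0, schedule.noise_sigma, size=frames.shape)

    protected: set[int] = set()
    for p in schedule.hbond_programs:
        protected.update((p.donor, p.hydrogen, p.acceptor))
    water_o = [a.atom_id for a in topo.atoms
               if a.segment_class is SegmentClass.WATER and a.name == "OW"]
    for p in schedule.water_site_programs:
        protected.update(p.site_atoms)
        for w in range(min(p.n_alternating_waters, len(water_o))):
            o = water_o[w]
            protected.update([o] + topo.bonded_hydrogens(o))
    if protected:
        pidx = sorted(protected)
        frames[:, pidx, :] = base[pidx, :]

    # -- programmed hydrogen bonds ------------------------------------
    for p in schedule.hbond_programs:
        for aid in (p.donor, p.hydrogen, p.acceptor):
            if not 0 <= aid < topo.n_atoms:
                raise ValueError(f"hbond program references missing atom {aid}")
        d_pos = base[p.donor]
        # approach axis: outward from the donor residue's centroid, so
        # the relocated acceptor never passes through the donor's own
        # molecule; fall back to the donor->acceptor direction
        donor_res = topo.atoms[p.donor].residue_id
        res_atoms = [a.atom_id for a in topo.atoms if a.residue_id == donor_res
                     and a.segment_class is topo.atoms[p.donor].segment_class]
        u = d_pos - base[res_atoms].mean(axis=0)
        nrm = np.linalg.norm(u)
        if nrm < 1e-6:
            u = base[p.acceptor] - d_pos
            nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        hits = _hit_frames(p.target_occupancy, n)
        dists = np.where(hits, p.bound_distance, p.unbound_distance)
        frames[:, p.donor, :] = d_pos
        frames[:, p.hydrogen, :] = d_pos + u[None, :] * 1.0
        frames[:, p.acceptor, :] = d_pos[None, :] + u[None, :] * dists[:, None]

    # -- programmed water-site visits ---------------------------------
    for p in schedule.water_site_programs:
        if not water_o:
            raise ValueError("water-site program but no waters in topology")
        site = p.site_atoms[0]
        a_pos = base[site]
        away = a_pos - base[:len(base)].mean(axis=0)
        nrm = np.linalg.norm(away)
        v = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        hits = _hit_frames(p.target_occupancy, n)
        hit_rank = 0
        for f in range(n):
            if hits[f]:
                o = water_o[hit_rank % p.n_alternating_waters]
                hs = topo.bonded_hydrogens(o)
                o_pos = a_pos + v * p.bound_distance
                frames[f, o, :] = o_pos
                if hs:
                    frames[f, hs[0], :] = a_pos + v * (p.bound_distance - 1.0)
                if len(hs) > 1:
                    perp = np.cross(v, [0.0, 0.0, 1.0])
                    if np.linalg.norm(perp) < 1e-6:
                        perp = np.cross(v, [0.0, 1.0, 0.0])
                    perp /= np.linalg.norm(perp)
                    frames[f, hs[1], :] = o_pos + 0.96 * perp
                hit_rank += 1
            else:
                for w in range(min(p.n_alternating_waters, len(water_o))):
                    o = water_o[w]
                    frames[f, o, :] = base[o]
                    for k, hh in enumerate(topo.bonded_hydrogens(o)):
                        frames[f, hh, :] = base[hh]

    # -- lipid enrichment resampling ----------------------------------
    if schedule.lipid_enrichment is not None:
        enr = schedule.lipid_enrichment
        carbons = np.array(
            [a.atom_id for a in topo.atoms
             if a.segment_class is SegmentClass.LIPID and a.element == "C"],
            dtype=int,
        )
        if len(carbons) == 0:
            raise ValueError("enrichment program but no lipid carbons")
        z_lo, z_hi = system.manifest["membrane_slab_z"]
        slab_lo = np.array([-system.box[0] / 2, -system.box[1] / 2, z_lo])
        slab_hi = np.array([system.box[0] / 2, system.box[1] / 2, z_hi])
        r_lo = np.maximum(np.asarray(enr.region_lo, dtype=float), slab_lo)
        r_hi = np.minimum(np.asarray(enr.region_hi, dtype=float), slab_hi)
        if np.any(r_hi <= r_lo):
            raise ValueError("enrichment region does not intersect the slab")
        v_region = float(np.prod(r_hi - r_lo))
        v_slab = float(np.prod(slab_hi - slab_lo))
        v_bulk = v_slab - v_region
        rho = enr.ratio
        # expected density(region)/density(bulk) = rho
        p_in = rho * v_region / (rho * v_region + v_bulk)
        m = n * len(carbons)
        in_region = rng.random(m) < p_in
        pts = np.empty((m, 3))
        k_in = int(in_region.sum())
        pts[in_region] = r_lo + rng.random((k_in, 3)) * (r_hi - r_lo)
        # rejection-sample the slab complement of the region
        k_out = m - k_in
        out = np.empty((k_out, 3))
        filled = 0
        while filled < k_out:
            cand = slab_lo + rng.random((k_out - filled, 3)) * (slab_hi - slab_lo)
            ok = ~np.all((cand >= r_lo) & (cand < r_hi), axis=1)
            sel = cand[ok]
            out[filled:filled + len(sel)] = sel
            filled += len(sel)
        pts[~in_region] = out
        frames[:, carbons, :] = pts.reshape(n, len(carbons), 3)

    box = np.repeat(system.box[None, :], n, axis=0)
    return Trajectory(frames, box)


def build_pocket_fixture(
    inner: float = 12.0,
    wall_spacing: float = 1.5,
    with_lipid_wall: bool = True,
) -> ToySystem:
    """A five-walled protein box open on +x, optionally sealed by a
    plane of lipid carbons: the minimal geometry in which adding the
    lipid wall turns an open groove into an enclosed cavity.

    ``inner`` is the edge length (Å) of the empty interior between wall
    atom centers; walls are square lattices of carbon atoms at
    ``wall_spacing``.  Deterministic (no randomness).
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    h = inner / 2.0
    rid = 0

    def add(seg: SegmentClass, pos):
        i = len(atoms)
        rmin, eps = _LJ["C"]
        name = "CW" if seg is SegmentClass.PROTEIN else "CL"
        res = "WAL" if seg is SegmentClass.PROTEIN else "LIP"
        chain = "P" if seg is SegmentClass.PROTEIN else "L"
        atoms.append(AtomRecord(i, name, "C", rid, res, chain, seg,
                                0.0, rmin, eps))
        coords.append(np.asarray(pos, dtype=float))

    ticks = np.arange(-h, h + 1e-9, wall_spacing)
    for u in ticks:
        for v in ticks:
            add(SegmentClass.PROTEIN, (-h, u, v))   # back wall (-x)
            add(SegmentClass.PROTEIN, (u, -h, v))   # side walls
            add(SegmentClass.PROTEIN, (u, +h, v))
            add(SegmentClass.PROTEIN, (u, v, -h))   # floor / ceiling
            add(SegmentClass.PROTEIN, (u, v, +h))
            if with_lipid_wall:
                add(SegmentClass.LIPID, (+h, u, v))  # front wall (+x)
    rid += 1
    # a pseudo-ligand spanning the interior marks the site seed; the
    # beads near the open face keep the whole lipid wall inside the
    # 6 A lipid margin measured from seed atoms
    rmin, eps = _LJ["C"]
    seed_offsets = [
        (0.0, 0.0, 0.0),
        (0.66 * h, 0.5 * h, 0.5 * h),
        (0.66 * h, -0.5 * h, 0.5 * h),
        (0.66 * h, 0.5 * h, -0.5 * h),
        (0.66 * h, -0.5 * h, -0.5 * h),
    ]
    for k, off in enumerate(seed_offsets):
        i = len(atoms)
        atoms.append(AtomRecord(i, f"LC{k + 1}", "C", rid, "LIG", "X",
                                SegmentClass.LIGAND, 0.0, rmin, eps))
        coords.append(np.asarray(off, dtype=float))
    topo = Topology(atoms=atoms, bonds=set())
    box = np.array([4 * h + 20.0] * 3)
    manifest = {
        "pocket_seed": {"center": [0.0, 0.0, 0.0],
                        "half_extent": [h, h, h]},
        "seed": 0,
        "n_atoms": topo.n_atoms,
        "membrane_slab_z": [-h, h],
        "fixture": "pocket_wall",
    }
    return ToySystem(topo, np.array(coords), box, manifest)


def export_system(
    system: ToySystem,
    trajectory: Trajectory | None,
    outdir: str | Path,
    prefix: str = "system",
    schedule: TrajectorySchedule | None = None,
) -> dict:
    """Emit PDB + topology TSV + bonds TSV (+ DCD) + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame0 = Trajectory.single_frame(system.coordinates, system.box)
    paths = {
        "pdb": str(outdir / f"{prefix}.pdb"),
        "topology": str(outdir / f"{prefix}.topology.tsv"),
        "bonds": str(outdir / f"{prefix}.bonds.tsv"),
        "manifest": str(outdir / f"{prefix}.manifest.json"),
    }
    lio.write_structure(paths["pdb"], system.topology, frame0)
    lio.write_topology_table(paths["topology"], system.topology)
    lio.write_bonds_table(paths["bonds"], system.topology)
    if trajectory is not None:
        paths["dcd"] = str(outdir / f"{prefix}.dcd")
        lio.write_dcd(paths["dcd"], system.topology, trajectory)
    manifest = dict(system.manifest)
    if schedule is not None:
        manifest["schedule"] = {
            "n_frames": schedule.n_frames,
            "seed": schedule.seed,
            "noise_sigma": schedule.noise_sigma,
            "hbond_programs": [dataclasses.asdict(p) for p in schedule.hbond_programs],
            "water_site_programs": [
                dataclasses.asdict(p) for p in schedule.water_site_programs
            ],
            "lipid_enrichment": (
                None if schedule.lipid_enrichment is None
                else dataclasses.asdict(schedule.lipid_enrichment)
            ),
        }
    # basenames only: the manifest must not depend on where the run
    # directory happens to live
    manifest["files"] = {k: Path(v).name for k, v in paths.items()}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
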