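"""Geometric hydrogen-bond detection and trajectory occupancy.

A hydrogen bond D–H···A is counted when the donor–acceptor heavy-atom
distance is at most ``d_cut`` (3.2 Å default, matching the distance
criterion used for the occupancy statistics this package reports) AND
the D–H···A angle is at least ``angle_cut`` (150° default).  The angle
gate keeps grazing contacts out; both parameters are configuration, and
every run logs the values it used.  Minimum-image distances are used
whenever the frame has a box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    Selection,
    SegmentClass,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "OccupancyReport",
    "find_hbonds",
    "hbond_occupancy",
    "water_site_occupancy",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_cut: float = 3.2          # donor-acceptor heavy-atom distance, A
    angle_cut: float = 150.0    # minimum D-H...A angle, degrees
    require_hydrogen: bool = True

    def __post_init__(self):
        if self.d_cut <= 0:
            raise ValueError("d_cut must be > 0")
        if not 0 < self.angle_cut <= 180:
            raise ValueError("angle_cut must be in (0, 180]")


@dataclass(frozen=True)
class OccupancyReport:
    label: str
    frames_hit: int
    n_frames: int

    @property
    def occupancy(self) -> float:
        return self.frames_hit / self.n_frames

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "occupancy": self.occupancy,
            "frames_hit": self.frames_hit,
            "n_frames": self.n_frames,
        }


_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


def _angle_deg(d_pos, h_pos, a_pos, box) -> float:
    v1 = minimum_image_displacement(d_pos - h_pos, box)
    v2 = minimum_image_displacement(a_pos - h_pos, box)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 0.0
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def find_hbonds(
    frame: np.ndarray,
    topology: Topology,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    box: np.ndarray | None = None,
) -> list[tuple[int, int | None, int]]:
    """All qualifying (donor, hydrogen, acceptor) triples in one frame.

    Donor atoms must be N/O; with ``require_hydrogen`` each donor must
    have at least one bonded hydrogen, and the best (largest) D–H···A
    angle over its hydrogens must pass the gate.  Without it, the
    distance criterion alone decides and the hydrogen slot is None.
    """
    frame = np.asarray(frame, dtype=float)
    don = [i for i in donors if topology.atoms[i].element.upper() in _DONOR_ELEMENTS]
    acc = [i for i in acceptors if topology.atoms[i].element.upper() in _ACCEPTOR_ELEMENTS]
    if criteria.require_hydrogen:
        missing = [i for i in don if not topology.bonded_hydrogens(i)]
        if missing:
            raise ValueError(
                f"donor atoms without bonded hydrogens: {missing}"
            )
    out = []
    for d in don:
        for a in acc:
            if a == d:
                continue
            dv = minimum_image_displacement(frame[a] - frame[d], box)
            dist = float(np.linalg.norm(dv))
            if dist > criteria.d_cut:
                continue
            if not criteria.require_hydrogen:
                out.append((d, None, a))
                continue
            best_h, best_ang = None, -1.0
            for h in topology.bonded_hydrogens(d):
                ang = _angle_deg(frame[d], frame[h], frame[a], box)
                if ang > best_ang:
                    best_h, best_ang = h, ang
            if best_ang >= criteria.angle_cut:
                out.append((d, best_h, a))
    return out


def hbond_occupancy(
    traj: Trajectory,
    topology: Topology,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    label: str = "",
) -> OccupancyReport:
    """Fraction of frames in which *any* qualifying triple exists
    between the two selections."""
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("empty donor or acceptor selection")
    logger.info(
        "hbond occupancy: d_cut=%.2f A angle_cut=%.1f deg require_hydrogen=%s",
        criteria.d_cut, criteria.angle_cut, criteria.require_hydrogen,
    )
    hits = 0
    for f in range(traj.n_frames):
        if find_hbonds(traj.frame(f), topology, donors, acceptors,
                       criteria, traj.frame_box(f)):
            hits += 1
    return OccupancyReport(label or "hbond", hits, traj.n_frames)


def water_site_occupancy(
    traj: Trajectory,
    topology: Topology,
    site_atoms: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    mode: str = "any",
    label: str = "water_site",
) -> OccupancyReport:
    """Fraction of frames in which water hydrogen-bonds to the site.

    ``mode='any'`` counts a frame when at least one water is H-bonded to
    at least one site atom (either direction: water O as donor to a site
    acceptor, or a site N/O donor to the water O).  ``mode='all'``
    additionally requires every listed site atom to be engaged by some
    water in that frame.  Which water plays partner is irrelevant.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    water_idx = topology.segment_indices(SegmentClass.WATER)
    if len(water_idx) == 0:
        raise ValueError("no water atoms in topology")
    water_sel = Selection(tuple(int(i) for i in water_idx), "segment=water")
    # site atoms act as acceptors always, and as donors only when they
    # actually carry a bonded hydrogen (backbone O has none)
    site_donor_ids = tuple(
        i for i in site_atoms
        if criteria.require_hydrogen is False or topology.bonded_hydrogens(i)
    )
    site_donors = Selection(site_donor_ids, "site donors") if site_donor_ids else None
    hits = 0
    for f in range(traj.n_frames):
        frame, box = traj.frame(f), traj.frame_box(f)
        triples = find_hbonds(frame, topology, water_sel, site_atoms, criteria, box)
        if site_donors is not None:
            triples += find_hbonds(
                frame, topology, site_donors, water_sel, criteria, box
            )
        if mode == "any":
            if triples:
                hits += 1
        else:
            engaged = {t[2] for t in triples if t[2] in site_atoms.indices}
            engaged |= {t[0] for t in triples if t[0] in site_atoms.indices}
            if engaged >= set(site_atoms.indices):
                hits += 1
    return OccupancyReport(label, hits, traj.n_frames)
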