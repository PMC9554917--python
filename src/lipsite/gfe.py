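"""Lipid-carbon occupancy grids and grid free energy (GFE) maps.

Per-voxel free energies follow the SILCS-style conversion of a probe
occupancy ratio:

    GFE = min( -R T ln(occ / occ_bulk), GFE_max )

where occ is the mean per-frame count of selected lipid carbons in the
cell, occ_bulk is the average occupancy of membrane-slab cells lying at
least ``bulk_min_protein_distance`` (10 Å default) from every protein
atom, R is the ideal gas constant and T the simulation temperature
(310 K default).  The cap GFE_max (3 kcal/mol default) absorbs the +inf
that zero occupancy inside the protein medium would otherwise produce.
Maps are visualized at an isovalue of −1.2 kcal/mol by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Grid3D, Selection, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "GfeParams",
    "occupancy_grid",
    "bulk_reference",
    "gfe_from_occupancy",
    "average_replica_gfe",
    "region_mean_gfe",
]

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)


@dataclass(frozen=True)
class GfeParams:
    temperature: float = 310.0           # K
    gfe_max: float = 3.0                 # kcal/mol cap
    spacing: float = 1.0                 # grid spacing, A
    bulk_min_protein_distance: float = 10.0  # A
    iso_default: float = -1.2            # kcal/mol, viewer isovalue
    R: float = GAS_CONSTANT_KCAL

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.gfe_max <= 0:
            raise ValueError("gfe_max must be > 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def rt(self) -> float:
        return self.R * self.temperature


def occupancy_grid(
    traj: Trajectory,
    sel: Selection,
    region_lo: np.ndarray,
    region_hi: np.ndarray,
    params: GfeParams = GfeParams(),
) -> Grid3D:
    """Mean per-frame count of selected atoms per cell over ``region``.

    Binning is half-open: a point belongs to cell i along an axis iff
    origin + i*s <= x < origin + (i+1)*s, so boundary atoms land in
    exactly one cell and counts are conserved.
    """
    if len(sel) == 0:
        raise ValueError("empty selection for occupancy grid")
    lo = np.asarray(region_lo, dtype=float)
    hi = np.asarray(region_hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("region_hi must exceed region_lo on every axis")
    s = params.spacing
    dims = np.maximum(np.ceil((hi - lo) / s - 1e-9).astype(int), 1)
    idx = sel.as_array()
    pts = traj.coordinates[:, idx, :].reshape(-1, 3)
    rel = np.floor((pts - lo) / s).astype(int)
    inside = np.all((rel >= 0) & (rel < dims), axis=1)
    rel = rel[inside]
    counts = np.zeros(tuple(dims), dtype=float)
    if len(rel):
        flat = np.ravel_multi_index((rel[:, 0], rel[:, 1], rel[:, 2]), tuple(dims))
        counts.ravel()[:] = np.bincount(flat, minlength=counts.size)
    counts /= traj.n_frames
    return Grid3D(lo, s, counts, units_label="mean atoms per cell per frame")


def bulk_reference(
    occ: Grid3D,
    protein_coords: np.ndarray | None,
    params: GfeParams = GfeParams(),
    slab_z: tuple[float, float] | None = None,
    exclude_region: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Average occupancy over cells far from the protein.

    Qualifying cells have centers at least ``bulk_min_protein_distance``
    from every protein atom (protein positions taken from a static
    snapshot, usually the first frame) and, when ``slab_z`` is given,
    lie inside the membrane slab z-range.  ``exclude_region`` (lo, hi)
    removes the analysis site itself from the reference — around a real
    receptor the protein-distance criterion does this implicitly, but a
    site region can extend past that distance.  With no protein the
    global mean over the remaining cells is returned.
    """
    centers = occ.cell_centers().reshape(-1, 3)
    vals = occ.values.ravel()
    keep = np.ones(len(vals), dtype=bool)
    if slab_z is not None:
        keep &= (centers[:, 2] >= slab_z[0]) & (centers[:, 2] < slab_z[1])
    if exclude_region is not None:
        lo, hi = (np.asarray(x, dtype=float) for x in exclude_region)
        keep &= ~np.all((centers >= lo) & (centers < hi), axis=1)
    if protein_coords is not None and len(protein_coords):
        from scipy.spatial import cKDTree

        tree = cKDTree(np.asarray(protein_coords, dtype=float))
        dmin, _ = tree.query(centers, k=1)
        keep &= dmin >= params.bulk_min_protein_distance
    if not np.any(keep):
        raise ValueError(
            "no grid cells qualify as bulk (all within "
            f"{params.bulk_min_protein_distance} A of the protein); "
            "enlarge the analysis region"
        )
    ref = float(np.mean(vals[keep]))
    logger.info("bulk reference occupancy %.4g from %d cells", ref, int(keep.sum()))
    return ref


def gfe_from_occupancy(
    occ: Grid3D,
    reference: float,
    params: GfeParams = GfeParams(),
) -> Grid3D:
    """Convert an occupancy grid to free energies, capped at GFE_max.

    Zero-occupancy cells map to exactly the cap value.
    """
    if reference <= 0:
        raise ValueError("bulk reference occupancy must be > 0")
    rt = params.rt
    vals = occ.values
    with np.errstate(divide="ignore"):
        gfe = np.where(
            vals > 0,
            -rt * np.log(vals / reference),
            np.inf,
        )
    gfe = np.minimum(gfe, params.gfe_max)
    return occ.copy_with(gfe, units_label="kcal/mol")


def average_replica_gfe(grids: list[Grid3D]) -> Grid3D:
    """Cell-wise arithmetic mean of replica GFE grids (capped inputs
    are averaged as-is)."""
    if not grids:
        raise ValueError("need at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise ValueError("replica grids have mismatched geometry")
    mean = np.mean([g.values for g in grids], axis=0)
    return first.copy_with(mean)


def region_mean_gfe(
    gfe: Grid3D,
    region_lo: np.ndarray,
    region_hi: np.ndarray,
) -> float:
    """Mean GFE over cells whose centers fall inside the box."""
    lo = np.asarray(region_lo, dtype=float)
    hi = np.asarray(region_hi, dtype=float)
    centers = gfe.cell_centers().reshape(-1, 3)
    inside = np.all((centers >= lo) & (centers < hi), axis=1)
    if not np.any(inside):
        raise ValueError("no grid cells inside the requested region")
    return float(np.mean(gfe.values.ravel()[inside]))
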