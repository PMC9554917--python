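"""Readers and writers for the formats the pipeline touches.

Coordinates travel as PDB (single or multi-model) and DCD, handled by
MDAnalysis.  Partial charges and Lennard-Jones parameters, which PDB
cannot carry, live in a TSV sidecar table keyed by atom_id.  Scalar
grids are exchanged as OpenDX regular scalar fields.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtomRecord, Grid3D, SegmentClass, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_dcd",
    "write_dcd",
    "read_topology_table",
    "write_topology_table",
    "read_bonds_table",
    "write_bonds_table",
    "write_grid_dx",
    "read_grid_dx",
    "infer_element",
]


class ParseError(ValueError):
    """A file failed validation; the message names the offending line."""


# Residue-name buckets for segment-class inference when only a PDB is
# available.  The TSV topology table is authoritative when present.
_WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SPC", "SOL"}
_ION_RESNAMES = {"NA", "CL", "K", "MG", "ZN", "CA2", "SOD", "CLA", "POT"}
_LIPID_RESNAMES = {"POPC", "DMPC", "DPPC", "POPE", "CHL1", "LIP"}
_LIGAND_RESNAMES = {"LIG", "UNK", "UNL", "DRG"}

# Single-letter fallbacks for atom-name -> element inference.
_ELEMENT_PREFIXES = (
    "CL", "BR", "NA", "MG", "ZN", "FE",
    "C", "N", "O", "S", "P", "H", "F", "I", "K",
)


def infer_element(name: str, residue_name: str = "", segment: str = "") -> str:
    """Best-effort element from an atom name.

    Ambiguous names like "CA" resolve by context: a calcium ion only in
    an ion residue, alpha-carbon everywhere else.  The decision is
    logged at debug level so provenance is recoverable.
    """
    stripped = "".join(c for c in name.upper() if c.isalpha())
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    if stripped == "CA":
        if residue_name.upper() in _ION_RESNAMES or segment == "ion":
            logger.debug("atom %r in %r resolved to calcium", name, residue_name)
            return "Ca"
        return "C"
    for pref in _ELEMENT_PREFIXES:
        if stripped.startswith(pref):
            return pref.capitalize() if len(pref) == 2 else pref
    return stripped[0]


def _infer_segment_class(residue_name: str, is_hetatm: bool) -> SegmentClass:
    rn = residue_name.upper()
    if rn in _WATER_RESNAMES:
        return SegmentClass.WATER
    if rn in _ION_RESNAMES:
        return SegmentClass.ION
    if rn in _LIPID_RESNAMES:
        return SegmentClass.LIPID
    if rn in _LIGAND_RESNAMES or is_hetatm:
        return SegmentClass.LIGAND
    return SegmentClass.PROTEIN


def _prevalidate_pdb(path: Path) -> None:
    """Cheap line scan so malformed coordinate records fail with a
    message naming the line, before the heavyweight parser runs."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_atoms += 1
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable coordinates in {rec} record"
                ) from None
    if n_atoms == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records (empty input)")


def read_structure(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a topology skeleton plus coordinates.

    Atom order is preserved from the file.  A multi-model PDB yields a
    multi-frame :class:`Trajectory`.  Charges and LJ parameters are left
    at zero; merge a topology table for those.  CONECT records become
    symmetric, duplicate-free bonds.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)

    hetatm_flags = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                hetatm_flags.append(rec == "HETATM")
    # flags repeat per model; keep the first model's worth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n = len(u.atoms)
    hetatm_flags = hetatm_flags[:n]

    atoms = []
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        seg = _infer_segment_class(resname, hetatm_flags[i] if i < len(hetatm_flags) else False)
        try:
            element = str(a.element).strip()
        except (AttributeError, Exception):
            element = ""
        if not element:
            element = infer_element(str(a.name), resname, seg.value)
        chain = ""
        for attr in ("chainID", "segid"):
            try:
                chain = str(getattr(a, attr)).strip()
            except Exception:
                chain = ""
            if chain:
                break
        atoms.append(
            AtomRecord(
                atom_id=i,
                name=str(a.name).strip(),
                element=element.capitalize() if len(element) > 1 else element.upper(),
                residue_id=int(a.resid),
                residue_name=resname,
                chain=chain,
                segment_class=seg,
            )
        )

    bonds: set[tuple[int, int]] = set()
    if hasattr(u, "bonds"):
        for b in u.bonds:
            i, j = int(b.atoms[0].index), int(b.atoms[1].index)
            bonds.add((min(i, j), max(i, j)))

    frames = []
    boxes = []
    have_box = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                have_box = False
            else:
                boxes.append(dims[:3].astype(float).copy())
    coords = np.stack(frames)
    box = np.stack(boxes) if (have_box and boxes) else None
    topo = Topology(atoms=atoms, bonds=bonds)
    return topo, Trajectory(coords, box)


def write_structure(
    path: str | Path,
    topology: Topology,
    trajectory: Trajectory,
    frames: list[int] | None = None,
) -> None:
    """Write coordinates as PDB; multiple frames become MODEL records."""
    import MDAnalysis as mda

    path = Path(path)
    u = _as_universe(topology, trajectory)
    frame_ids = list(range(trajectory.n_frames)) if frames is None else frames
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        multiframe = len(frame_ids) > 1
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=multiframe) as w:
            for f in frame_ids:
                u.atoms.positions = trajectory.frame(f)
                if trajectory.box is not None:
                    u.dimensions = [*trajectory.box[f], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def _as_universe(topology: Topology, trajectory: Trajectory):
    import MDAnalysis as mda

    resids_seq = []
    seen = {}
    atom_resindex = []
    for a in topology.atoms:
        key = (a.chain, a.residue_id, a.residue_name)
        if key not in seen:
            seen[key] = len(seen)
            resids_seq.append(key)
        atom_resindex.append(seen[key])
    n_res = len(resids_seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            topology.n_atoms,
            n_residues=n_res,
            atom_resindex=np.array(atom_resindex),
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
        u.add_TopologyAttr("resids", [k[1] for k in resids_seq])
        u.add_TopologyAttr("resnames", [k[2] for k in resids_seq])
        u.add_TopologyAttr("chainIDs", [a.chain or "X" for a in topology.atoms])
        u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))
        if topology.bonds:
            u.add_TopologyAttr("bonds", sorted(topology.bonds))
        u.atoms.positions = trajectory.frame(0)
        if trajectory.box is not None:
            u.dimensions = [*trajectory.box[0], 90.0, 90.0, 90.0]
    return u


def write_dcd(path: str | Path, topology: Topology, trajectory: Trajectory) -> None:
    import MDAnalysis as mda

    u = _as_universe(topology, trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.DCD.DCDWriter(str(path), n_atoms=topology.n_atoms) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.frame(f)
                if trajectory.box is not None:
                    u.dimensions = [*trajectory.box[f], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def read_dcd(path: str | Path, structure_path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a DCD trajectory on top of a PDB structure."""
    import MDAnalysis as mda

    topo, _ = read_structure(structure_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(structure_path), str(path))
        frames, boxes, have_box = [], [], True
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                have_box = False
            else:
                boxes.append(dims[:3].astype(float).copy())
    coords = np.stack(frames)
    box = np.stack(boxes) if (have_box and boxes) else None
    return topo, Trajectory(coords, box)


# ---------------------------------------------------------------------
# Topology TSV sidecar

_TOPOLOGY_COLUMNS = [
    "atom_id", "name", "element", "residue_id", "residue_name",
    "chain", "segment_class", "charge", "rmin_half", "epsilon",
]


def write_topology_table(path: str | Path, topology: Topology) -> None:
    rows = [
        {
            "atom_id": a.atom_id,
            "name": a.name,
            "element": a.element,
            "residue_id": a.residue_id,
            "residue_name": a.residue_name,
            "chain": a.chain,
            "segment_class": a.segment_class.value,
            "charge": a.charge,
            "rmin_half": a.lj_rmin_half,
            "epsilon": a.lj_epsilon,
        }
        for a in topology.atoms
    ]
    pd.DataFrame(rows, columns=_TOPOLOGY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_bonds_table(path: str | Path, topology: Topology) -> None:
    rows = sorted(topology.bonds)
    pd.DataFrame(rows, columns=["i", "j"]).to_csv(path, sep="\t", index=False)


def read_bonds_table(path: str | Path) -> set[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (min(int(r.i), int(r.j)), max(int(r.i), int(r.j)))
        for r in df.itertuples()
    }


def read_topology_table(
    path: str | Path,
    structure: Topology | None = None,
    bonds_path: str | Path | None = None,
) -> Topology:
    """Read the TSV topology sidecar carrying charges and LJ parameters.

    When ``structure`` (a skeleton from :func:`read_structure`) is
    supplied, the table is merged onto it by atom_id — counts must
    match.  Bonds come from ``bonds_path`` if given, else from the
    structure skeleton.  Heavy atoms without LJ Rmin/2 are a hard error.
    Net charges per segment class are reported in the log.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    dupes = df["atom_id"][df["atom_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate atom_id(s): {sorted(set(dupes))}")
    if structure is not None and len(df) != structure.n_atoms:
        raise ParseError(
            f"{path}: atom count {len(df)} does not match structure "
            f"({structure.n_atoms} atoms)"
        )
    df = df.sort_values("atom_id").reset_index(drop=True)
    atoms = []
    for _, r in df.iterrows():
        atoms.append(
            AtomRecord(
                atom_id=int(r["atom_id"]),
                name=str(r["name"]),
                element=str(r["element"]),
                residue_id=int(r["residue_id"]),
                residue_name=str(r["residue_name"]),
                chain="" if pd.isna(r["chain"]) else str(r["chain"]),
                segment_class=SegmentClass(str(r["segment_class"])),
                charge=float(r["charge"]),
                lj_rmin_half=float(r["rmin_half"]),
                lj_epsilon=float(r["epsilon"]),
            )
        )
    bonds: set[tuple[int, int]] = set()
    if bonds_path is not None:
        bonds = read_bonds_table(bonds_path)
    elif structure is not None:
        bonds = set(structure.bonds)
    topo = Topology(atoms=atoms, bonds=bonds)
    topo.validate_lj()
    for seg in SegmentClass:
        idx = topo.segment_indices(seg)
        if len(idx):
            logger.info(
                "net charge of %s block: %+.4f e", seg.value, topo.net_charge(idx)
            )
    return topo


# ---------------------------------------------------------------------
# OpenDX scalar fields

def write_grid_dx(grid: Grid3D, path: str | Path) -> None:
    """Write a grid as an OpenDX regular scalar field.

    The dialect written here (regularpositions / regularconnections,
    three data values per line) is the one molecular viewers and
    gridDataFormats read.  NaN cells are refused with their index.
    """
    bad = np.argwhere(~np.isfinite(grid.values))
    if len(bad):
        raise ValueError(
            f"grid contains non-finite values, first at cell "
            f"{tuple(int(x) for x in bad[0])}"
        )
    nx, ny, nz = grid.dims
    s = grid.spacing
    # DX positions are grid-point origins; we store cell values on the
    # lattice of cell centers so the round-trip is exact.
    ox, oy, oz = grid.origin + 0.5 * s
    vals = grid.values.ravel(order="C")
    lines = [
        f"# OpenDX density written by lipsite; units: {grid.units_label}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.10g} {oy:.10g} {oz:.10g}",
        f"delta {s:.10g} 0 0",
        f"delta 0 {s:.10g} 0",
        f"delta 0 0 {s:.10g}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} data follows",
    ]
    for start in range(0, vals.size, 3):
        chunk = vals[start:start + 3]
        lines.append(" ".join(f"{v:.10g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid_dx(path: str | Path, units_label: str = "") -> Grid3D:
    """Read an OpenDX scalar field back into a :class:`Grid3D`.

    Only uniform, axis-aligned spacing is supported; anything else is
    an unsupported dialect here.
    """
    from gridData import Grid as _GDGrid

    g = _GDGrid(str(path))
    deltas = np.asarray(g.delta, dtype=float)
    if deltas.ndim == 2:
        off = deltas - np.diag(np.diag(deltas))
        if np.any(np.abs(off) > 1e-12):
            raise ValueError(f"{path}: non-axis-aligned DX deltas unsupported")
        deltas = np.diag(deltas)
    if not np.allclose(deltas, deltas[0], atol=1e-9):
        raise ValueError(f"{path}: non-uniform DX spacing unsupported")
    spacing = float(deltas[0])
    origin = np.asarray(g.origin, dtype=float) - 0.5 * spacing
    return Grid3D(origin, spacing, np.asarray(g.grid, dtype=float), units_label)
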