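"""Core domain types shared by every analysis stage.

Units follow the membrane-simulation conventions used throughout the
package: lengths in Å, energies in kcal/mol, partial charges in units of
the elementary charge e.  Boxes, where present, are orthorhombic and
distance-based analyses apply the minimum-image convention.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SegmentClass",
    "AtomRecord",
    "Topology",
    "Trajectory",
    "Selection",
    "Grid3D",
    "minimum_image_displacement",
    "pairwise_distances",
]


class SegmentClass(str, enum.Enum):
    """Coarse classification of every atom in the system."""

    PROTEIN = "protein"
    LIPID = "lipid"
    WATER = "water"
    LIGAND = "ligand"
    ION = "ion"


@dataclass(frozen=True)
class AtomRecord:
    """One atom with the per-atom inputs required by the nonbonded
    energy decomposition (partial charge and 12-6 Lennard-Jones
    parameters in the Rmin/2–epsilon convention)."""

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    segment_class: SegmentClass
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self):
        if self.atom_id < 0:
            raise ValueError(f"atom_id must be >= 0, got {self.atom_id}")
        if self.lj_epsilon < 0:
            raise ValueError(
                f"atom {self.atom_id} ({self.name}): lj_epsilon must be >= 0"
            )


@dataclass
class Topology:
    """Ordered atom list plus a symmetric bond set.

    atom_ids must be unique and dense (0..n_atoms-1) so that atom_id can
    double as an array index everywhere downstream.
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if sorted(ids) != list(range(len(ids))):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValueError(f"duplicate atom_id(s): {sorted(dupes)}")
            raise ValueError("atom_ids must be dense 0..n_atoms-1")
        n = len(ids)
        norm = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom")
            norm.add((min(i, j), max(i, j)))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _adjacency(self) -> dict[int, list[int]]:
        # cached; Topology bonds are treated as immutable after init
        adj = getattr(self, "_adj_cache", None)
        if adj is None or getattr(self, "_adj_nbonds", -1) != len(self.bonds):
            adj = {}
            for i, j in self.bonds:
                adj.setdefault(i, []).append(j)
                adj.setdefault(j, []).append(i)
            for v in adj.values():
                v.sort()
            self._adj_cache = adj
            self._adj_nbonds = len(self.bonds)
        return adj

    def bonded_to(self, atom_id: int) -> list[int]:
        return self._adjacency().get(atom_id, [])

    def bonded_hydrogens(self, atom_id: int) -> list[int]:
        return [
            j for j in self.bonded_to(atom_id)
            if self.atoms[j].element.upper() == "H"
        ]

    # -- convenience vector views -------------------------------------
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms], dtype=float)

    def epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def segment_indices(self, segment: SegmentClass | str) -> np.ndarray:
        segment = SegmentClass(segment)
        return np.array(
            [a.atom_id for a in self.atoms if a.segment_class is segment],
            dtype=int,
        )

    def net_charge(self, indices: Iterable[int] | None = None) -> float:
        if indices is None:
            return float(sum(a.charge for a in self.atoms))
        return float(sum(self.atoms[i].charge for i in indices))

    def validate_lj(self) -> None:
        """Heavy atoms that enter vdW terms need Rmin/2 > 0."""
        bad = [
            a.atom_id for a in self.atoms
            if a.is_heavy and not a.lj_rmin_half > 0
        ]
        if bad:
            raise ValueError(
                f"missing/invalid LJ Rmin/2 for heavy atoms: {bad}"
            )


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å), optionally with per-frame
    orthorhombic box lengths (Å)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (n_frames, 3) or None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, n_atoms, 3); "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError(
                    f"box must have shape ({self.n_frames}, 3); "
                    f"got {self.box.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]

    @classmethod
    def single_frame(cls, coords: np.ndarray, box=None) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)[None, :, :]
        if box is not None:
            box = np.asarray(box, dtype=float)[None, :]
        return cls(coords, box)


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free set of atom ids with a provenance
    string recording how it was built."""

    indices: tuple[int, ...]
    expression: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("selection contains duplicate atom ids")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    def validate(self, topology: Topology) -> None:
        bad = [i for i in self.indices if not 0 <= i < topology.n_atoms]
        if bad:
            raise ValueError(f"selection references missing atoms: {bad}")

    @classmethod
    def from_indices(cls, indices: Sequence[int], expression: str = "") -> "Selection":
        return cls(tuple(int(i) for i in indices), expression)


def select(
    topology: Topology,
    segment: SegmentClass | str | None = None,
    residue_ids: Iterable[int] | None = None,
    names: Iterable[str] | None = None,
    elements: Iterable[str] | None = None,
    heavy_only: bool = False,
) -> Selection:
    """Deterministic attribute-based atom selection.

    All supplied filters are ANDed; atom order follows the topology.
    """
    seg = None if segment is None else SegmentClass(segment)
    rid = None if residue_ids is None else set(int(r) for r in residue_ids)
    nm = None if names is None else set(names)
    el = None if elements is None else {e.upper() for e in elements}
    out = []
    for a in topology.atoms:
        if seg is not None and a.segment_class is not seg:
            continue
        if rid is not None and a.residue_id not in rid:
            continue
        if nm is not None and a.name not in nm:
            continue
        if el is not None and a.element.upper() not in el:
            continue
        if heavy_only and not a.is_heavy:
            continue
        out.append(a.atom_id)
    parts = []
    if seg is not None:
        parts.append(f"segment={seg.value}")
    if rid is not None:
        parts.append(f"residue_ids={sorted(rid)}")
    if nm is not None:
        parts.append(f"names={sorted(nm)}")
    if el is not None:
        parts.append(f"elements={sorted(el)}")
    if heavy_only:
        parts.append("heavy_only")
    return Selection(tuple(out), " and ".join(parts) or "all")


@dataclass
class Grid3D:
    """Regular scalar grid with uniform spacing.

    Cell (i,j,k) covers the half-open box
    [origin + i*s, origin + (i+1)*s) along each axis; ``values[i,j,k]``
    is the scalar for that cell (occupancy counts or kcal/mol).
    """

    origin: np.ndarray  # (3,)
    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    units_label: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.dims))

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-center coordinates."""
        axes = [
            self.origin[d] + (np.arange(self.dims[d]) + 0.5) * self.spacing
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def same_geometry(self, other: "Grid3D", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )

    def copy_with(self, values: np.ndarray, units_label: str | None = None) -> "Grid3D":
        return Grid3D(
            self.origin.copy(),
            self.spacing,
            np.asarray(values, dtype=float),
            self.units_label if units_label is None else units_label,
        )


# ---------------------------------------------------------------------
# Geometry helpers

def minimum_image_displacement(
    d: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Wrap displacement vectors into the primary orthorhombic image.

    ``d`` has shape (..., 3); ``box`` is the (3,) box-length vector or
    None for non-periodic distances.
    """
    d = np.asarray(d, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float).reshape(3)
    return d - box * np.round(d / box)


def pairwise_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """(len(a), len(b)) distance matrix, minimum image when box given."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))
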