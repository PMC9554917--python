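"""Post-processing of fragment interaction-energy decompositions and
orbital charge-transfer descriptors.

This module consumes *tabulated* outputs of quantum-chemistry runs — a
fragment-wise symmetry-adapted perturbation theory (SAPT) decomposition
into electrostatics / exchange / induction / dispersion, and natural
population analysis charge-transfer values (Q_CT, atomic units) — and
performs the reporting arithmetic on them: fragment efficiency per
heavy atom, grouped electrostatic ratios against a reference fragment,
and classification of contacts against reference Q_CT values for each
bond class.  No wavefunctions are touched here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SaptFragmentRecord",
    "QctRecord",
    "load_fragment_table",
    "load_qct_table",
    "fragment_efficiency",
    "efficiency_table",
    "electrostatic_ratio",
    "qct_classify",
    "DEFAULT_QCT_REFERENCES",
]

COMPONENT_SUM_TOLERANCE = 0.02  # kcal/mol


@dataclass(frozen=True)
class SaptFragmentRecord:
    """One residue fragment (side chain or backbone amide) with its
    interaction-energy components in kcal/mol."""

    label: str
    part: str  # "side_chain" | "backbone_amide"
    electrostatics: float
    exchange: float
    induction: float
    dispersion: float
    total: float
    n_heavy_atoms: int

    def __post_init__(self):
        if self.n_heavy_atoms <= 0:
            raise ValueError(
                f"{self.label}: n_heavy_atoms must be > 0 "
                "(fragment efficiency is undefined otherwise)"
            )

    def component_sum(self) -> float:
        return self.electrostatics + self.exchange + self.induction + self.dispersion


@dataclass(frozen=True)
class QctRecord:
    """A donor-orbital → acceptor-orbital charge-transfer value (au)."""

    label: str
    q_ct: float
    bond_class: str  # classical_hbond | nonclassical_hbond | halogen_bond

    def __post_init__(self):
        if self.q_ct < 0:
            raise ValueError(f"{self.label}: q_ct must be >= 0")
        if self.bond_class not in (
            "classical_hbond", "nonclassical_hbond", "halogen_bond"
        ):
            raise ValueError(f"{self.label}: unknown bond_class {self.bond_class!r}")


_FRAGMENT_COLUMNS = [
    "label", "part", "electrostatics", "exchange",
    "induction", "dispersion", "total", "n_heavy_atoms",
]


def load_fragment_table(path: str | Path) -> list[SaptFragmentRecord]:
    """Load fragment records from TSV or JSON.

    The component-sum invariant (total == elec + exch + ind + disp
    within 0.02 kcal/mol) is checked; violations are warned with the
    delta but the record is kept — published tables are often rounded.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        rows = df.to_dict("records")
    records = []
    for row in rows:
        rec = SaptFragmentRecord(
            label=str(row["label"]),
            part=str(row["part"]),
            electrostatics=float(row["electrostatics"]),
            exchange=float(row["exchange"]),
            induction=float(row["induction"]),
            dispersion=float(row["dispersion"]),
            total=float(row["total"]),
            n_heavy_atoms=int(row["n_heavy_atoms"]),
        )
        delta = rec.total - rec.component_sum()
        if abs(delta) > COMPONENT_SUM_TOLERANCE:
            logger.warning(
                "%s (%s): total deviates from component sum by %+.3f kcal/mol",
                rec.label, rec.part, delta,
            )
        records.append(rec)
    return records


def load_qct_table(path: str | Path) -> list[QctRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t")
        rows = df.to_dict("records")
    return [
        QctRecord(str(r["label"]), float(r["q_ct"]), str(r["bond_class"]))
        for r in rows
    ]


def fragment_efficiency(record: SaptFragmentRecord) -> float:
    """Per-non-hydrogen-atom average energy contribution of the
    fragment: total interaction energy / heavy-atom count."""
    return record.total / record.n_heavy_atoms


def efficiency_table(records: list[SaptFragmentRecord]) -> pd.DataFrame:
    """All fragments with their efficiencies, strongest (most negative)
    first."""
    rows = [
        {
            "label": r.label,
            "part": r.part,
            "total": r.total,
            "n_heavy_atoms": r.n_heavy_atoms,
            "efficiency": fragment_efficiency(r),
        }
        for r in records
    ]
    return pd.DataFrame(rows).sort_values("efficiency").reset_index(drop=True)


def electrostatic_ratio(
    group: list[SaptFragmentRecord] | list[float],
    reference: SaptFragmentRecord | float,
) -> tuple[float, int]:
    """Electrostatics of a fragment group as a percentage of a
    reference fragment's electrostatics.

    Absolute values are used (all quantities of interest here are
    attractive, so signed and absolute sums agree on real tables).
    Returns (unrounded percentage, nearest-integer percentage).
    """
    vals = [
        g.electrostatics if isinstance(g, SaptFragmentRecord) else float(g)
        for g in group
    ]
    ref = (
        reference.electrostatics
        if isinstance(reference, SaptFragmentRecord)
        else float(reference)
    )
    if ref == 0:
        raise ValueError("reference electrostatic component is zero")
    pct = 100.0 * abs(sum(vals)) / abs(ref)
    return pct, int(round(pct))


# Reference Q_CT per bond class, atomic units.  The classical value is
# the optimal-geometry charge transfer of a conventional N/O-H...N/O
# hydrogen bond; the nonclassical (C-H donor) reference is ten times
# smaller.  No published reference exists for the O-Br halogen bond, so
# that class ships unset and must be user-supplied.
DEFAULT_QCT_REFERENCES: dict[str, float] = {
    "classical_hbond": 0.05,
    "nonclassical_hbond": 0.005,
}

_STRENGTH_THRESHOLDS = (0.8, 0.2)  # optimal >= 0.8 > weak >= 0.2 > very_weak


def qct_classify(
    record: QctRecord,
    references: dict[str, float] | None = None,
    thresholds: tuple[float, float] = _STRENGTH_THRESHOLDS,
) -> tuple[float, str]:
    """Ratio of a contact's Q_CT to its bond class reference plus a
    strength label.

    Labels (reporting conveniences, configurable): ratio >= 0.8 is
    "optimal", 0.2 <= ratio < 0.8 "weak", below 0.2 "very_weak".
    """
    refs = dict(DEFAULT_QCT_REFERENCES)
    if references:
        refs.update(references)
    if record.bond_class not in refs:
        raise ValueError(
            f"no reference Q_CT for bond class {record.bond_class!r}; "
            "supply one via `references`"
        )
    hi, lo = thresholds
    ratio = record.q_ct / refs[record.bond_class]
    if ratio >= hi:
        label = "optimal"
    elif ratio >= lo:
        label = "weak"
    else:
        label = "very_weak"
    logger.info(
        "%s: Q_CT ratio %.3f vs %s reference -> %s",
        record.label, ratio, record.bond_class, label,
    )
    return ratio, label
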