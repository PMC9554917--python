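"""Superposition-based stability metrics: RMSD series and per-atom RMSF.

Conventions: RMSD is computed per frame after a least-squares (Kabsch)
fit of a *fit selection* (receptor Cα by default) onto the reference
frame, then measured over a possibly different *measure selection*
(Cα for the receptor, heavy atoms for the ligand).  RMSF is the
fluctuation of each atom about its time-averaged position after
superposing all frames on the fit selection.  Fits are unweighted
unless explicit weights are given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, Trajectory

__all__ = [
    "MetricSeries",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "fragment_rmsf",
]


@dataclass
class MetricSeries:
    """Scalar per frame (RMSD) or per atom (RMSF), in Å."""

    values: np.ndarray
    kind: str  # "rmsd" | "rmsf"
    fit_selection: Selection | None = None
    measure_selection: Selection | None = None
    reference: str = "frame 0"

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "mean": self.mean,
            "sd": self.sd,
            "n": int(len(self.values)),
            "reference": self.reference,
        }


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted)`` with
    ``fitted = mobile @ rotation.T + translation`` minimizing the
    weighted squared deviation; the rotation is proper (det = +1).

    Degenerate (collinear or coincident) point sets are rejected: the
    rotation about the degenerate axis is not determined by the data.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    # rank < 2 leaves a rotational degree of freedom undetermined
    if np.sum(s > 1e-10 * max(s[0], 1e-300)) < 2:
        raise ValueError("degenerate (collinear) point set; fit is rank-deficient")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + trans
    return rot, trans, fitted


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def rmsd_series(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
    reference_frame: int = 0,
) -> MetricSeries:
    """Per-frame RMSD after fitting ``fit_sel`` onto the reference frame.

    ``measure_sel`` defaults to the fit selection.
    """
    if len(fit_sel) == 0:
        raise ValueError("empty fit selection")
    measure_sel = measure_sel or fit_sel
    if len(measure_sel) == 0:
        raise ValueError("empty measure selection")
    fit_idx = fit_sel.as_array()
    mea_idx = measure_sel.as_array()
    ref = traj.frame(reference_frame)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.frame(f)
        rot, trans, _ = kabsch_superpose(x[fit_idx], ref[fit_idx])
        moved = x[mea_idx] @ rot.T + trans
        out[f] = _rmsd(moved, ref[mea_idx])
    return MetricSeries(out, "rmsd", fit_sel, measure_sel,
                        reference=f"frame {reference_frame}")


def _superposed_coordinates(
    traj: Trajectory, fit_sel: Selection, measure_idx: np.ndarray
) -> np.ndarray:
    """All frames fitted on fit_sel against frame 0; returns the
    measured atoms' coordinates, shape (n_frames, n_measure, 3)."""
    fit_idx = fit_sel.as_array()
    ref = traj.frame(0)
    out = np.empty((traj.n_frames, len(measure_idx), 3))
    for f in range(traj.n_frames):
        x = traj.frame(f)
        rot, trans, _ = kabsch_superpose(x[fit_idx], ref[fit_idx])
        out[f] = x[measure_idx] @ rot.T + trans
    return out


def rmsf(
    traj: Trajectory,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
) -> MetricSeries:
    """Per-atom RMSF about the time-averaged position after fitting
    every frame on ``fit_sel``."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if len(fit_sel) == 0:
        raise ValueError("empty fit selection")
    measure_sel = measure_sel or fit_sel
    mea_idx = measure_sel.as_array()
    coords = _superposed_coordinates(traj, fit_sel, mea_idx)
    mean_pos = coords.mean(axis=0)
    d = coords - mean_pos[None, :, :]
    vals = np.sqrt(np.mean(np.einsum("fij,fij->fi", d, d), axis=0))
    return MetricSeries(vals, "rmsf", fit_sel, measure_sel,
                        reference="time-average")


def fragment_rmsf(
    traj: Trajectory,
    fit_sel: Selection,
    fragment: Selection,
    aggregate: str = "mean",
) -> float:
    """One number per ligand fragment: the mean (or max) of its
    per-atom RMSF values.  Callers pass heavy-atom selections."""
    series = rmsf(traj, fit_sel, fragment)
    if aggregate == "mean":
        return float(np.mean(series.values))
    if aggregate == "max":
        return float(np.max(series.values))
    raise ValueError(f"unknown aggregate {aggregate!r} (use 'mean' or 'max')")
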