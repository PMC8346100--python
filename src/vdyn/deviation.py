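"""Least-squares superposition and structural deviation metrics.

``superpose`` finds the closed-form least-squares rigid transform (Kabsch,
with reflection correction so the rotation is always proper) between two
frames over a fit selection, then applies it to all atoms.  ``rmsd_series``
and ``rmsf_profile`` implement the standard unweighted deviation and
fluctuation observables over Calpha/backbone selections; no mass weighting
is used anywhere.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "DeviationSeries",
    "FluctuationProfile",
    "DegenerateFitError",
    "superpose",
    "superpose_trajectory",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
    "rmsf_difference",
]

ANGSTROM_PER_NM = 10.0


class DegenerateFitError(ValueError):
    """Raised when a fit selection cannot define a unique rotation."""


@dataclasses.dataclass(frozen=True)
class DeviationSeries:
    """Per-frame RMSD against a fixed reference, with explicit unit."""

    times: np.ndarray
    values: np.ndarray
    unit: str
    reference: str
    selection: str

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("RMSD values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times, f"rmsd_{self.unit}": self.values}
        )

    def in_unit(self, unit: str) -> "DeviationSeries":
        if unit == self.unit:
            return self
        if (self.unit, unit) == ("angstrom", "nm"):
            factor = 1.0 / ANGSTROM_PER_NM
        elif (self.unit, unit) == ("nm", "angstrom"):
            factor = ANGSTROM_PER_NM
        else:
            raise ValueError(f"cannot convert {self.unit} to {unit}")
        return dataclasses.replace(self, values=self.values * factor, unit=unit)


@dataclasses.dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue RMSF (Angstrom) keyed by sequence position."""

    values: pd.Series  # index: sequence position, values: RMSF in Angstrom
    selection: str
    about: str = "mean"  # "mean" or "reference"

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("RMSF values must be non-negative")


def _check_fit_points(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError(
            f"superposition needs >= 3 fit atoms, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear; rotation is degenerate")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit ``mobile`` onto ``reference``.

    The rotation/translation minimizing the RMSD over the fit atoms is found
    in closed form and applied to *all* atoms of ``mobile``.  Returns
    ``(transformed, rotation, translation)`` such that
    ``transformed = mobile @ rotation.T + translation`` and the rotation is
    proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = slice(None) if fit_indices is None else np.asarray(fit_indices, dtype=int)
    mob_fit, ref_fit = mobile[idx], reference[idx]
    if mob_fit.shape != ref_fit.shape:
        raise ValueError("mobile and reference fit selections differ in shape")
    _check_fit_points(mob_fit)
    mob_center = mob_fit.mean(axis=0)
    ref_center = ref_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_fit - ref_center, mob_fit - mob_center)
    rotation = rot.as_matrix()
    translation = ref_center - mob_center @ rotation.T
    return mobile @ rotation.T + translation, rotation, translation


def superpose_trajectory(
    traj: TrajectoryEnsemble,
    reference: np.ndarray,
    fit_selection: AtomSelection,
) -> TrajectoryEnsemble:
    """Fit every frame onto reference coordinates over a fit selection."""
    fitted = np.empty_like(traj.xyz)
    for t in range(traj.n_frames):
        fitted[t], _, _ = superpose(traj.xyz[t], reference, fit_selection.indices)
    return dataclasses.replace(traj, xyz=fitted)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equal-shape frames (no fitting)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have identical shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    traj: TrajectoryEnsemble,
    reference: StructureModel | np.ndarray,
    calc_selection: AtomSelection,
    fit_selection: Optional[AtomSelection] = None,
    unit: str = "angstrom",
    reference_label: str = "reference",
) -> DeviationSeries:
    """Per-frame RMSD of ``calc_selection`` atoms against a reference.

    Each frame is first least-squares fitted to the reference over
    ``fit_selection`` (defaults to ``calc_selection``); passing
    ``fit_selection=False`` disables fitting.  The whole trajectory is used:
    deviation series are typically inspected over the full production run.
    """
    ref_xyz = reference.xyz if isinstance(reference, StructureModel) else np.asarray(reference)
    if ref_xyz.shape[0] != traj.n_atoms:
        raise ValueError(
            f"reference has {ref_xyz.shape[0]} atoms but trajectory has {traj.n_atoms}"
        )
    calc = calc_selection.indices
    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.xyz[t]
        if fit_selection is not False:
            fit = (fit_selection or calc_selection).indices
            frame, _, _ = superpose(frame, ref_xyz, fit)
        values[t] = rmsd(frame[calc], ref_xyz[calc])
    series = DeviationSeries(
        times=traj.times,
        values=values,
        unit="angstrom",
        reference=reference_label,
        selection=calc_selection.expression,
    )
    return series.in_unit(unit)


def rmsf_profile(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    fit: bool = True,
    about: str = "mean",
    reference: Optional[np.ndarray] = None,
) -> FluctuationProfile:
    """Per-atom root-mean-square fluctuation over the equilibrated frames.

    RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>).  By default fluctuations are taken
    about the ensemble mean after internally fitting every frame to the mean
    structure (iterated once from the raw mean); ``about="reference"`` uses a
    supplied reference frame instead.
    """
    xyz = traj.retained_xyz
    if xyz.shape[0] < 2:
        raise ValueError("RMSF is undefined for fewer than two frames")
    if about not in ("mean", "reference"):
        raise ValueError("about must be 'mean' or 'reference'")
    if about == "reference":
        if reference is None:
            raise ValueError("about='reference' requires reference coordinates")
        center = np.asarray(reference, dtype=float)
    else:
        center = xyz.mean(axis=0)
    if fit:
        fitted = np.empty_like(xyz)
        for t in range(xyz.shape[0]):
            fitted[t], _, _ = superpose(xyz[t], center, selection.indices)
        xyz = fitted
        if about == "mean":
            center = xyz.mean(axis=0)
    sub = xyz[:, selection.indices]
    dev = sub - center[selection.indices]
    rmsf = np.sqrt(np.mean(np.sum(dev**2, axis=-1), axis=0))
    values = pd.Series(rmsf, index=pd.Index(selection.resids, name="residue"))
    return FluctuationProfile(values=values, selection=selection.expression, about=about)


def rmsf_difference(
    variant: FluctuationProfile, wildtype: FluctuationProfile
) -> pd.Series:
    """Per-residue RMSF difference, variant minus wild type (sign preserved)."""
    vi, wi = set(variant.values.index), set(wildtype.values.index)
    if vi != wi:
        missing = sorted(vi.symmetric_difference(wi))
        raise ValueError(f"residue keys differ between profiles: {missing}")
    return variant.values - wildtype.values
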