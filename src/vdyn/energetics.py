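"""Binding energetics: interaction entropy, MM-GBSA term assembly,
pocket-volume/affinity regression, pocket shrinkage, and docking-pose
selection metrics.

The binding free energy follows the interaction-entropy formalism:

    dG_binding = dG_gas + dG_solv,   dG_gas = <E_int> - T*dS,
    -T*dS = kb*T * ln <exp(beta * dE_int)>,   dE_int = E_int - <E_int>.

Per-frame interaction and solvation energies are consumed from delimited
text (e.g. MMPBSA-style per-frame decompositions); no solvation solver or
force-field evaluation happens here.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .constants import (
    BOLTZMANN_KCAL,
    DEFAULT_TEMPERATURE,
    NATIVE_CONTACT_CUTOFF,
)
from .io import StructureModel

__all__ = [
    "EnergySeries",
    "BindingEnergyResult",
    "QuadraticFit",
    "PoseMetrics",
    "read_energy_series",
    "interaction_entropy",
    "combine_terms",
    "binding_energy",
    "QuadraticVolumeAffinity",
    "quadratic_fit",
    "shrinkage",
    "pose_metrics",
]


@dataclasses.dataclass
class EnergySeries:
    """Per-frame protein-ligand energy decomposition for one complex.

    ``e_int`` holds the interaction energy E_pl^int per frame (kcal/mol);
    ``g_solv`` the matching solvation term, if available.  ``replica``
    labels frames from independent trajectories; replicas are pooled with
    equal weight after any upstream equilibration filtering.
    """

    e_int: np.ndarray
    g_solv: Optional[np.ndarray] = None
    frames: Optional[np.ndarray] = None
    temperature: float = DEFAULT_TEMPERATURE
    replica: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.e_int = np.asarray(self.e_int, dtype=float)
        if self.e_int.ndim != 1 or self.e_int.size < 1:
            raise ValueError("e_int must be a non-empty 1D array")
        if not np.all(np.isfinite(self.e_int)):
            raise ValueError("interaction energies must be finite")
        if self.g_solv is not None:
            self.g_solv = np.asarray(self.g_solv, dtype=float)
            if self.g_solv.shape != self.e_int.shape:
                raise ValueError("g_solv must match e_int in length")
            if not np.all(np.isfinite(self.g_solv)):
                raise ValueError("solvation energies must be finite")
        if self.frames is None:
            self.frames = np.arange(self.e_int.size)

    @property
    def n_frames(self) -> int:
        return self.e_int.size


@dataclasses.dataclass(frozen=True)
class BindingEnergyResult:
    """The five Table-style columns of one complex (kcal/mol)."""

    e_int_mean: float
    minus_tds: float
    g_gas: float
    g_solv_mean: Optional[float]
    g_binding: Optional[float]
    n_frames: int
    complete: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class QuadraticFit:
    """Least-squares fit of y = a*x^2 + b*x + c with its R^2."""

    a: float
    b: float
    c: float
    r_squared: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


@dataclasses.dataclass(frozen=True)
class PoseMetrics:
    """Docking-pose selection metrics for one candidate pose."""

    fnat: Optional[float]  # fraction of native contacts; None if undefined
    com_iron_distance: float  # ligand heavy-atom centroid to heme Fe (Angstrom)
    ligand_rmsd: float  # all-ligand-atom RMSD vs the reference pose (Angstrom)


def read_energy_series(
    path: str | os.PathLike,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnergySeries:
    """Read a per-frame energy table from delimited text.

    Accepts comma- or whitespace-delimited files with columns ``frame``,
    ``e_int`` and optionally ``g_solv`` and ``replica`` (header names are
    matched case-insensitively; MMPBSA-style ``DELTA G gas``/``DELTA G
    solv`` aliases are recognized).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    aliases = {
        "e_int": ("e_int", "eint", "interaction", "delta_e", "delta_g_gas"),
        "g_solv": ("g_solv", "gsolv", "solvation", "delta_g_solv"),
        "frame": ("frame", "frame_#", "frames", "t"),
        "replica": ("replica", "run", "traj"),
    }
    cols = {}
    for target, names in aliases.items():
        for name in names:
            if name in df.columns:
                cols[target] = name
                break
    if "e_int" not in cols:
        raise ValueError(
            f"{path} has no interaction-energy column (found {list(df.columns)})"
        )
    return EnergySeries(
        e_int=df[cols["e_int"]].to_numpy(float),
        g_solv=df[cols["g_solv"]].to_numpy(float) if "g_solv" in cols else None,
        frames=df[cols["frame"]].to_numpy() if "frame" in cols else None,
        replica=df[cols["replica"]].to_numpy() if "replica" in cols else None,
        temperature=temperature,
    )


def interaction_entropy(
    series: EnergySeries | np.ndarray,
    temperature: Optional[float] = None,
) -> float:
    """Interaction-entropy term -T*dS = kb*T*ln <exp(beta*dE)> (kcal/mol).

    dE is the per-frame deviation of the interaction energy from its mean.
    The exponential average is evaluated with log-sum-exp, so only the
    *spread* of the series (not its absolute scale) limits the numerics.
    Non-negative for every series (Jensen), exactly zero for a constant one.
    """
    if isinstance(series, EnergySeries):
        energies = series.e_int
        temperature = temperature or series.temperature
    else:
        energies = np.asarray(series, dtype=float)
        temperature = temperature or DEFAULT_TEMPERATURE
    if energies.size < 2:
        raise ValueError("interaction entropy needs at least two frames")
    if np.ptp(energies) == 0.0:  # Jensen equality, exactly
        return 0.0
    kbt = BOLTZMANN_KCAL * temperature
    beta_de = (energies - energies.mean()) / kbt
    log_avg = logsumexp(beta_de) - np.log(beta_de.size)
    value = kbt * log_avg
    if not np.isfinite(value):
        raise OverflowError(
            f"interaction entropy overflow: max beta*dE = {beta_de.max():.3g}"
        )
    return float(max(value, 0.0))


def combine_terms(e_int_mean: float, minus_tds: float, g_solv: float) -> float:
    """dG_binding = <E_int> + (-T*dS) + dG_solv, the exact term sum."""
    terms = (e_int_mean, minus_tds, g_solv)
    if not all(np.isfinite(terms)):
        raise ValueError(f"binding-energy terms must be finite, got {terms}")
    return float(sum(terms))


def binding_energy(
    series: EnergySeries,
    temperature: Optional[float] = None,
) -> BindingEnergyResult:
    """Assemble the interaction-entropy binding free energy for one complex.

    Frames from multiple replicas are pooled with equal weight (the caller
    applies any per-replica equilibration filter before constructing the
    series).  Without a solvation column the result is flagged incomplete
    and carries gas-phase terms only.
    """
    temperature = temperature or series.temperature
    e_mean = float(series.e_int.mean())
    minus_tds = interaction_entropy(series, temperature)
    g_gas = e_mean + minus_tds
    if series.g_solv is None:
        return BindingEnergyResult(
            e_int_mean=e_mean,
            minus_tds=minus_tds,
            g_gas=g_gas,
            g_solv_mean=None,
            g_binding=None,
            n_frames=series.n_frames,
            complete=False,
        )
    g_solv = float(series.g_solv.mean())
    return BindingEnergyResult(
        e_int_mean=e_mean,
        minus_tds=minus_tds,
        g_gas=g_gas,
        g_solv_mean=g_solv,
        g_binding=combine_terms(e_mean, minus_tds, g_solv),
        n_frames=series.n_frames,
    )


class QuadraticVolumeAffinity:
    """Ordinary least-squares quadratic regression of affinity on volume.

    Fits y = a*x^2 + b*x + c (x: pocket volume in Angstrom^3, y: binding
    free energy in kcal/mol) on the design (x^2, x, 1).  Fitted attributes:
    ``coef_`` (a, b, c), ``r_squared_``, ``n_``.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "QuadraticVolumeAffinity":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, x, y) -> "QuadraticVolumeAffinity":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 3:
            raise ValueError("quadratic fit needs at least 3 points")
        if np.ptp(x) == 0:
            raise ValueError("design is rank deficient: all x values equal")
        design = np.column_stack([x**2, x, np.ones_like(x)])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("design is rank deficient")
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.coef_ = coef
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_ = int(x.size)
        return self

    def predict(self, x) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("QuadraticVolumeAffinity is not fitted yet")
        x = np.asarray(x, dtype=float)
        a, b, c = self.coef_
        return a * x**2 + b * x + c

    def score(self, x=None, y=None) -> float:
        return float(self.r_squared_)


def quadratic_fit(volumes: Sequence[float], energies: Sequence[float]) -> QuadraticFit:
    """Fit y = a*x^2 + b*x + c by OLS; returns coefficients and R^2."""
    est = QuadraticVolumeAffinity().fit(volumes, energies)
    a, b, c = est.coef_
    return QuadraticFit(a=float(a), b=float(b), c=float(c),
                        r_squared=est.r_squared_, n=est.n_)


def shrinkage(v_variant: float, v_reference: float) -> float:
    """Percent pocket-volume reduction relative to a reference volume.

    100 * (v_ref - v_variant) / v_ref; a variant pocket *larger* than the
    reference gives a negative shrinkage (growth).
    """
    if v_reference <= 0:
        raise ValueError(f"reference volume must be positive, got {v_reference}")
    return float(100.0 * (v_reference - v_variant) / v_reference)


def _heavy_xyz(structure: StructureModel, hetero: bool) -> np.ndarray:
    mask = (structure.hetero == hetero) & ~structure.is_hydrogen()
    return structure.xyz[mask]


def pose_metrics(
    candidate_ligand: np.ndarray,
    reference_ligand: np.ndarray,
    receptor: StructureModel,
    iron_xyz: np.ndarray,
    contact_cutoff: float = NATIVE_CONTACT_CUTOFF,
) -> PoseMetrics:
    """Docking-pose selection metrics against a reference pose.

    ``candidate_ligand`` and ``reference_ligand`` are (n, 3) heavy-atom
    coordinate arrays over the same atoms (receptor frame already
    superposed; the ligand is *not* refitted).  Native contacts are
    receptor-heavy-atom / ligand-heavy-atom pairs within ``contact_cutoff``
    (4.5 Angstrom by default) in the reference pose; fnat is the fraction of
    those pairs preserved in the candidate.  If the reference pose makes no
    contacts, fnat is undefined (None).
    """
    cand = np.asarray(candidate_ligand, dtype=float)
    ref = np.asarray(reference_ligand, dtype=float)
    if cand.shape != ref.shape:
        raise ValueError("candidate and reference must cover the same ligand atoms")
    iron = np.asarray(iron_xyz, dtype=float).reshape(3)
    receptor_xyz = _heavy_xyz(receptor, hetero=False)

    ref_contacts = cdist(ref, receptor_xyz) <= contact_cutoff
    n_native = int(ref_contacts.sum())
    if n_native == 0:
        fnat = None
    else:
        cand_contacts = cdist(cand, receptor_xyz) <= contact_cutoff
        fnat = float((ref_contacts & cand_contacts).sum() / n_native)

    com = cand.mean(axis=0)
    com_distance = float(np.linalg.norm(com - iron))
    ligand_rmsd = float(np.sqrt(np.mean(np.sum((cand - ref) ** 2, axis=1))))
    return PoseMetrics(
        fnat=fnat, com_iron_distance=com_distance, ligand_rmsd=ligand_rmsd
    )
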