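"""Seeded synthetic generators for every input the pipeline consumes.

Each generator is a pure function of its arguments: the same seed yields the
same output, byte for byte, with a private ``numpy.random.Generator`` per
call (never global state).  Planted ground truth (mode directions and
eigenvalues, state probabilities, energy mean/sigma, quadratic coefficients)
is available either directly or through :class:`GeneratorSpec` sidecars, so
recovery tests can compare estimates against what was planted.

What these emulate — and what they do not: Gaussian fluctuations about a
reference with a prescribed low-rank covariance stand in for an equilibrated
harmonic ensemble; two-state hopping along one direction emulates a
double-well landscape; i.i.d. Gaussian energy series emulate converged
interaction-energy fluctuations.  None of them carry the kinetics,
anharmonicity, or frame-to-frame correlation of a real MD trajectory.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional

import numpy as np

from .constants import DEFAULT_FRAME_INTERVAL_NS, DEFAULT_TEMPERATURE
from .energetics import EnergySeries
from .io import StructureModel, TrajectoryEnsemble

__all__ = [
    "GeneratorSpec",
    "make_toy_chain",
    "random_orthonormal_modes",
    "sample_gaussian_trajectory",
    "make_two_state_trajectory",
    "make_energy_series",
    "make_quadratic_dataset",
    "apply_rigid_transform",
]

#: helix-like Calpha trace geometry (Angstrom, degrees per residue)
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0

#: isotropic positional jitter on two-state frames (Angstrom)
TWO_STATE_JITTER = 0.1


@dataclasses.dataclass
class GeneratorSpec:
    """Serializable record of a generator call and its planted truth."""

    generator: str
    seed: int
    size: dict
    planted: dict

    def to_json(self, path: str | os.PathLike) -> None:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"cannot serialize {type(obj)}")

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_default)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GeneratorSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_toy_chain(
    n_residues: int,
    seed: int = 0,
    start_resid: int = 1,
    backbone: bool = False,
    chain_id: str = "A",
) -> StructureModel:
    """Idealized helix-like Calpha trace (rise 1.5 A, radius 2.3 A, 100 deg/residue).

    With ``backbone=True`` each residue additionally carries N, C and O atoms
    placed near the Calpha so backbone selections have their four atoms.
    Deterministic for a given argument set; ``seed`` is recorded for sidecar
    provenance but the geometry itself is analytic.
    """
    if n_residues < 3:
        raise ValueError(f"toy chain needs >= 3 residues, got {n_residues}")
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    ca = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    names, resids, elements, xyz = [], [], [], []
    offsets = {
        "N": np.array([-0.8, 0.6, -0.7]),
        "CA": np.zeros(3),
        "C": np.array([0.9, 0.4, 0.6]),
        "O": np.array([1.1, 1.3, 0.8]),
    }
    atom_order = ("N", "CA", "C", "O") if backbone else ("CA",)
    for r in range(n_residues):
        for name in atom_order:
            names.append(name)
            resids.append(start_resid + r)
            elements.append(name[0])
            xyz.append(ca[r] + offsets[name])
    n = len(names)
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(names),
        resname=np.full(n, "ALA"),
        resid=np.array(resids),
        chain=np.full(n, chain_id),
        element=np.array(elements),
        xyz=np.array(xyz),
        hetero=np.zeros(n, dtype=bool),
    )


def random_orthonormal_modes(dim: int, k: int, seed: int) -> np.ndarray:
    """``k`` orthonormal vectors in ``dim`` dimensions (rows), Haar-uniform."""
    if k > dim:
        raise ValueError(f"cannot draw {k} orthonormal vectors in dimension {dim}")
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((dim, k)))
    return (q * np.sign(np.diag(r))).T


def _check_orthonormal(modes: np.ndarray, tol: float = 1e-8) -> None:
    gram = modes @ modes.T
    if np.max(np.abs(gram - np.eye(modes.shape[0]))) > tol:
        raise ValueError("planted modes must be orthonormal (Gram deviation > 1e-8)")


def sample_gaussian_trajectory(
    structure: StructureModel,
    modes: np.ndarray,
    eigenvalues: np.ndarray,
    n_frames: int,
    seed: int,
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS,
) -> TrajectoryEnsemble:
    """Gaussian ensemble about a reference with a planted low-rank covariance.

    frame_t = reference + sum_k sqrt(lambda_k) * z_tk * mode_k, with z i.i.d.
    standard normal, so the population covariance of the flattened
    coordinates is exactly ``sum_k lambda_k * v_k v_k^T``.
    """
    modes = np.asarray(modes, dtype=float)
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if modes.ndim != 2 or modes.shape[1] != 3 * structure.n_atoms:
        raise ValueError(
            f"modes must have shape (k, {3 * structure.n_atoms})"
        )
    if np.any(eigenvalues < 0):
        raise ValueError("eigenvalues must be non-negative")
    _check_orthonormal(modes)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, modes.shape[0]))
    flat = structure.xyz.ravel() + (z * np.sqrt(eigenvalues)) @ modes
    return TrajectoryEnsemble(
        xyz=flat.reshape(n_frames, structure.n_atoms, 3),
        times=np.arange(n_frames) * frame_interval_ns,
        topology=structure,
    )


def make_two_state_trajectory(
    structure: StructureModel,
    displacement: np.ndarray,
    p_state1: float,
    n_frames: int,
    seed: int,
    jitter: float = TWO_STATE_JITTER,
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS,
) -> tuple[TrajectoryEnsemble, np.ndarray]:
    """Two-state hopping ensemble: a double-well fixture for FEL recovery.

    Each frame sits (independently) at the reference with probability
    ``p_state1``, or at reference + displacement otherwise, plus small
    isotropic Gaussian jitter (sigma 0.1 A) so histogram bins are occupied
    realistically.  Returns the trajectory and the per-frame state labels
    (0 = reference well, 1 = displaced well).
    """
    displacement = np.asarray(displacement, dtype=float).ravel()
    if displacement.size != 3 * structure.n_atoms:
        raise ValueError("displacement must be a 3N vector")
    if np.linalg.norm(displacement) == 0:
        raise ValueError("two-state generator needs a nonzero displacement")
    if not 0 < p_state1 < 1:
        raise ValueError(f"p_state1 must lie in (0, 1), got {p_state1}")
    rng = np.random.default_rng(seed)
    states = (rng.random(n_frames) >= p_state1).astype(int)
    flat = (
        structure.xyz.ravel()
        + states[:, np.newaxis] * displacement
        + rng.normal(0.0, jitter, size=(n_frames, displacement.size))
    )
    traj = TrajectoryEnsemble(
        xyz=flat.reshape(n_frames, structure.n_atoms, 3),
        times=np.arange(n_frames) * frame_interval_ns,
        topology=structure,
    )
    return traj, states


def make_energy_series(
    mean: float,
    sigma: float,
    n: int,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnergySeries:
    """i.i.d. Gaussian interaction-energy series with planted mean and sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    return EnergySeries(
        e_int=rng.normal(mean, sigma, size=n), temperature=temperature
    )


def make_quadratic_dataset(
    a: float,
    b: float,
    c: float,
    noise_sigma: float,
    n: int,
    x_range: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy samples of y = a*x^2 + b*x + c with x uniform on ``x_range``."""
    if n < 3:
        raise ValueError("need at least 3 points for a quadratic dataset")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    y = a * x**2 + b * x + c + rng.normal(0.0, noise_sigma, size=n)
    return x, y


def apply_rigid_transform(
    traj: TrajectoryEnsemble,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> TrajectoryEnsemble:
    """Apply one proper rigid motion to every frame of a trajectory."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float).reshape(3)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(rotation), 1.0, atol=1e-8
    ):
        raise ValueError("rotation must be proper (orthogonal, determinant +1)")
    xyz = traj.xyz @ rotation.T + translation
    return dataclasses.replace(traj, xyz=xyz)
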