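"""Essential dynamics: Cartesian PCA of an MD ensemble and derived metrics.

The coordinate covariance of the (already superposed) Calpha ensemble is
diagonalized via an SVD of the centered frame matrix; the leading
eigenvectors are the collective-motion modes, and their eigenvalues (in
Angstrom^2, sample variance with ddof=1) give the explained-variance
fractions.  On top of the decomposition the module provides subspace overlap
(RMSIP), per-atom mode vectors for porcupine plots, and cross-projection of
arbitrary conformations onto a reference (wild-type) eigenbasis.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "CartesianPCA",
    "fit_pca",
    "explained_variance",
    "project",
    "cross_project",
    "rmsip",
    "porcupine_vectors",
    "export_nmd",
]


def _as_frame_matrix(frames, selection: Optional[AtomSelection]) -> np.ndarray:
    """Coerce a trajectory/frame(s) to a (n_frames, 3N) matrix in Angstrom."""
    if isinstance(frames, TrajectoryEnsemble):
        xyz = frames.retained_xyz
        if selection is not None:
            xyz = xyz[:, selection.indices]
        return xyz.reshape(xyz.shape[0], -1)
    xyz = np.asarray(frames, dtype=float)
    if xyz.ndim == 1:
        return xyz[np.newaxis]
    if xyz.ndim == 2 and xyz.shape[1] == 3:
        if selection is not None:
            xyz = xyz[selection.indices]
        return xyz.reshape(1, -1)
    if xyz.ndim == 3:
        if selection is not None:
            xyz = xyz[:, selection.indices]
        return xyz.reshape(xyz.shape[0], -1)
    return xyz


class CartesianPCA:
    """Principal component analysis of Cartesian MD coordinates.

    scikit-learn style estimator: ``fit`` on a trajectory (or a
    ``(n_frames, 3N)`` matrix), then ``transform`` projects conformations
    onto the modes.  Fitted attributes:

    ``mean_`` : (3N,) mean coordinates (Angstrom)
    ``components_`` : (n_modes, 3N) orthonormal eigenvectors, eigenvalue-descending
    ``eigenvalues_`` : (n_modes,) covariance eigenvalues (Angstrom^2, ddof=1)
    ``explained_variance_ratio_`` : eigenvalue fractions of the total variance

    The eigenvector sign convention flips each mode so its largest-magnitude
    component is positive, making outputs deterministic across linear-algebra
    backends.
    """

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "CartesianPCA":
        for key, value in params.items():
            if key != "n_components":
                raise ValueError(f"unknown parameter {key!r}")
            self.n_components = value
        return self

    def fit(self, frames, selection: Optional[AtomSelection] = None) -> "CartesianPCA":
        X = _as_frame_matrix(frames, selection)
        if X.shape[0] < 2:
            raise ValueError("PCA requires at least two frames")
        if not np.all(np.isfinite(X)):
            raise ValueError("coordinates must be finite")
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        # SVD of the centered frame matrix: eigvals of the covariance are
        # s^2/(n-1); numerically stabler than forming the 3N x 3N covariance.
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = s**2 / (X.shape[0] - 1)
        total = eigenvalues.sum()
        # deterministic sign: largest-magnitude component positive
        flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, np.newaxis]
        k = self.n_components or vt.shape[0]
        self.components_ = vt[:k]
        self.eigenvalues_ = eigenvalues[:k]
        self.total_variance_ = float(total)
        self.explained_variance_ratio_ = (
            eigenvalues[:k] / total if total > 0 else np.zeros(k)
        )
        self.n_frames_ = X.shape[0]
        self.selection_ = selection.expression if selection is not None else None
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "components_"):
            raise AttributeError("CartesianPCA instance is not fitted yet")

    def transform(
        self,
        frames,
        selection: Optional[AtomSelection] = None,
        pcs: Optional[Sequence[int]] = None,
    ) -> np.ndarray:
        """Project conformations onto the modes: score = (x - mean) . eigvec.

        ``pcs`` selects 1-based mode indices (default: all fitted modes).
        Returns a ``(n_frames, len(pcs))`` score array in Angstrom.
        """
        self._check_fitted()
        X = _as_frame_matrix(frames, selection)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"frames have dimension {X.shape[1]} but decomposition has "
                f"{self.mean_.shape[0]}"
            )
        comp = self.components_
        if pcs is not None:
            idx = np.asarray(pcs, dtype=int) - 1
            if np.any(idx < 0) or np.any(idx >= comp.shape[0]):
                raise ValueError(f"PC indices {list(pcs)} out of range")
            comp = comp[idx]
        return (X - self.mean_) @ comp.T

    def fit_transform(self, frames, selection=None, pcs=None) -> np.ndarray:
        return self.fit(frames, selection).transform(frames, selection, pcs)

    def cumulative_explained_variance(self, k: int) -> float:
        """Fraction of total variance captured by the first ``k`` modes."""
        self._check_fitted()
        if not 1 <= k <= self.eigenvalues_.shape[0]:
            raise ValueError(
                f"k must be in [1, {self.eigenvalues_.shape[0]}], got {k}"
            )
        return float(self.eigenvalues_[:k].sum() / self.total_variance_)


def fit_pca(
    traj: TrajectoryEnsemble | np.ndarray,
    selection: Optional[AtomSelection] = None,
    n_components: Optional[int] = None,
) -> CartesianPCA:
    """Fit a :class:`CartesianPCA` on the equilibrated frames of a trajectory."""
    return CartesianPCA(n_components=n_components).fit(traj, selection)


def explained_variance(decomp: CartesianPCA, k: int) -> float:
    """Cumulative explained-variance fraction of the first ``k`` modes."""
    return decomp.cumulative_explained_variance(k)


def project(
    frames,
    decomp: CartesianPCA,
    pcs: Sequence[int] = (1, 2),
    selection: Optional[AtomSelection] = None,
) -> pd.DataFrame:
    """Mode projection as a tidy frame (columns ``pc1, pc2, ...`` in Angstrom)."""
    scores = decomp.transform(frames, selection=selection, pcs=pcs)
    return pd.DataFrame(scores, columns=[f"pc{i}" for i in pcs])


def cross_project(
    frame,
    reference_decomp: CartesianPCA,
    pcs: Sequence[int] = (1, 2),
    selection: Optional[AtomSelection] = None,
) -> np.ndarray:
    """Project a conformation onto a *reference* eigenbasis.

    Scores are computed against the reference decomposition's mean and
    eigenvectors (e.g. a variant's global-minimum conformation on the
    wild-type PC1/PC2 subspace); the frame must already be superposed to the
    reference fitting frame.
    """
    scores = reference_decomp.transform(frame, selection=selection, pcs=pcs)
    return scores[0] if scores.shape[0] == 1 else scores


def rmsip(
    decomp_a: CartesianPCA | np.ndarray,
    decomp_b: CartesianPCA | np.ndarray,
    n_modes: int = 20,
    sqrt: bool = True,
) -> float:
    """Root mean square inner product between two mode subspaces.

    RMSIP = sqrt( (1/n) sum_i sum_j (u_i . v_j)^2 ) over the first ``n_modes``
    eigenvectors of each decomposition; symmetric, bounded by [0, 1], equal to
    1 when the subspaces coincide.  ``sqrt=False`` returns the un-rooted mean
    squared inner product, provided for comparison with conventions that skip
    the square root.
    """
    a = decomp_a.components_ if isinstance(decomp_a, CartesianPCA) else np.asarray(decomp_a)
    b = decomp_b.components_ if isinstance(decomp_b, CartesianPCA) else np.asarray(decomp_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"subspace dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    if a.shape[0] < n_modes or b.shape[0] < n_modes:
        raise ValueError(
            f"need >= {n_modes} modes, got {a.shape[0]} and {b.shape[0]}"
        )
    overlap = a[:n_modes] @ b[:n_modes].T
    msip = float(np.sum(overlap**2) / n_modes)
    return float(np.sqrt(min(msip, 1.0 + 1e-12))) if sqrt else msip


def porcupine_vectors(
    decomp: CartesianPCA, mode: int = 1, scale: float = 1.0
) -> np.ndarray:
    """Per-atom displacement vectors of one mode, scaled, for porcupine plots.

    Returns an ``(n_atoms, 3)`` array ``scale * eigvec[3i:3i+3]`` anchored at
    the mean structure; the summed squared amplitude equals ``scale**2`` for a
    unit eigenvector.
    """
    decomp._check_fitted()
    if not 1 <= mode <= decomp.components_.shape[0]:
        raise ValueError(f"mode {mode} out of range")
    vec = decomp.components_[mode - 1]
    if np.linalg.norm(vec) == 0:
        raise ValueError(f"mode {mode} has zero norm")
    return scale * vec.reshape(-1, 3)


def export_nmd(
    path,
    structure: StructureModel,
    selection: AtomSelection,
    decomp: CartesianPCA,
    modes: Sequence[int] = (1, 2, 3),
    name: str = "vdyn-modes",
) -> None:
    """Write modes in NMD-style text for molecular viewers.

    The file carries atom names, residue numbers, the mean coordinates and
    one ``mode`` line per requested mode (index, eigenvalue, 3N vector).
    """
    decomp._check_fitted()
    idx = selection.indices
    with open(path, "w") as fh:
        fh.write(f"nmwiz_load {path}\n")
        fh.write(f"name {name}\n")
        fh.write("atomnames " + " ".join(structure.name[idx]) + "\n")
        fh.write("resnames " + " ".join(structure.resname[idx]) + "\n")
        fh.write("resids " + " ".join(map(str, structure.resid[idx])) + "\n")
        fh.write(
            "coordinates " + " ".join(f"{v:.3f}" for v in decomp.mean_) + "\n"
        )
        for m in modes:
            if not 1 <= m <= decomp.components_.shape[0]:
                raise ValueError(f"mode {m} out of range")
            vec = decomp.components_[m - 1]
            fh.write(
                f"mode {m} {decomp.eigenvalues_[m - 1]:.6f} "
                + " ".join(f"{v:.6f}" for v in vec)
                + "\n"
            )
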