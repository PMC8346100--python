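"""Free-energy landscapes over principal-component reaction coordinates.

The landscape is the Boltzmann inversion of the 2D occupancy histogram of
the (PC1, PC2) projections: dG(bin) = -kb*T*ln P(bin), with P the fraction
of frames in the bin.  Empty bins are masked (left undefined) rather than
set to infinity.  By default energies are shifted so the global minimum sits
at zero; ``shift=False`` keeps the absolute -kb*T*ln P values.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE

__all__ = ["FreeEnergyLandscape", "fel", "global_minimum", "representative_frame"]

#: fractional padding applied to the data range on each axis
RANGE_PADDING = 0.01


class FreeEnergyLandscape:
    """2D free-energy surface estimator over two reaction coordinates.

    Parameters
    ----------
    bins : int or (int, int)
        Histogram bins per axis (default 50).
    temperature : float
        Absolute temperature in K for the Boltzmann inversion.
    shift : bool
        Shift energies so the global minimum is 0 (default).  With
        ``shift=False`` the landscape reports the unshifted -kb*T*ln P.

    Fitted attributes
    -----------------
    ``edges_`` : (x_edges, y_edges) bin edges in Angstrom
    ``counts_`` : (nx, ny) occupancy counts
    ``probability_`` : counts / total
    ``free_energy_`` : masked array of dG (kcal/mol); empty bins masked
    ``minimum_bin_`` : (i, j) indices of the global-minimum bin
    ``minimum_value_`` : dG at the global minimum
    """

    def __init__(
        self,
        bins: int | tuple[int, int] = 50,
        temperature: float = DEFAULT_TEMPERATURE,
        shift: bool = True,
    ):
        self.bins = bins
        self.temperature = temperature
        self.shift = shift

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bins": self.bins,
            "temperature": self.temperature,
            "shift": self.shift,
        }

    def set_params(self, **params) -> "FreeEnergyLandscape":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, scores) -> "FreeEnergyLandscape":
        """Estimate the landscape from an (n_frames, 2) score array."""
        X = np.asarray(
            scores[["pc1", "pc2"]] if isinstance(scores, pd.DataFrame) else scores,
            dtype=float,
        )
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("scores must have shape (n_frames, 2)")
        if X.shape[0] < 1:
            raise ValueError("landscape requires at least one frame")
        bins = self.bins if np.iterable(self.bins) else (self.bins, self.bins)
        if min(bins) < 2:
            raise ValueError("need at least 2 bins per axis")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

        edges = []
        for axis, nb in enumerate(bins):
            lo, hi = X[:, axis].min(), X[:, axis].max()
            pad = (hi - lo) * RANGE_PADDING or 0.5  # degenerate axis: fixed pad
            edges.append(np.linspace(lo - pad, hi + pad, nb + 1))
        counts, _, _ = np.histogram2d(X[:, 0], X[:, 1], bins=edges)
        prob = counts / counts.sum()
        kbt = BOLTZMANN_KCAL * self.temperature
        with np.errstate(divide="ignore"):
            dg = -kbt * np.log(prob)
        occupied = counts > 0
        dg_masked = np.ma.masked_array(dg, mask=~occupied)
        if self.shift:
            dg_masked = dg_masked - dg_masked.min()

        self.edges_ = tuple(edges)
        self.counts_ = counts
        self.probability_ = prob
        self.free_energy_ = dg_masked
        self.n_frames_ = X.shape[0]
        self.minimum_bin_, self.minimum_value_ = self._locate_minimum()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "free_energy_"):
            raise AttributeError("FreeEnergyLandscape instance is not fitted yet")

    def _locate_minimum(self) -> tuple[tuple[int, int], float]:
        dg = self.free_energy_
        best = dg.min()
        # ties: highest count first, then lowest (row, col) index
        candidates = np.argwhere(
            ~dg.mask & (dg.filled(np.inf) <= best + 1e-12)
        )
        order = sorted(
            (tuple(rc) for rc in candidates),
            key=lambda rc: (-self.counts_[rc], rc),
        )
        bin_idx = order[0]
        return bin_idx, float(dg[bin_idx])

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        self._check_fitted()
        return tuple((e[:-1] + e[1:]) / 2.0 for e in self.edges_)

    def bin_of(self, scores: np.ndarray) -> np.ndarray:
        """Bin indices (i, j) of each score pair; -1 marks out-of-range."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(scores, dtype=float))
        out = np.full((X.shape[0], 2), -1, dtype=int)
        for axis in (0, 1):
            e = self.edges_[axis]
            idx = np.searchsorted(e, X[:, axis], side="right") - 1
            idx[np.isclose(X[:, axis], e[-1])] = len(e) - 2
            inside = (idx >= 0) & (idx <= len(e) - 2)
            out[inside, axis] = idx[inside]
        out[np.any(out < 0, axis=1)] = -1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: pc1_center, pc2_center, count, prob, dg."""
        self._check_fitted()
        cx, cy = self.bin_centers()
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        dg = self.free_energy_
        return pd.DataFrame(
            {
                "pc1_center": gx.ravel(),
                "pc2_center": gy.ravel(),
                "count": self.counts_.ravel().astype(int),
                "prob": self.probability_.ravel(),
                "dg": dg.filled(np.nan).ravel(),
            }
        )


def fel(
    projection,
    bins: int | tuple[int, int] = 50,
    temperature: float = DEFAULT_TEMPERATURE,
    shift: bool = True,
) -> FreeEnergyLandscape:
    """Fit a :class:`FreeEnergyLandscape` on (PC1, PC2) projections."""
    return FreeEnergyLandscape(bins=bins, temperature=temperature, shift=shift).fit(
        projection
    )


def global_minimum(landscape: FreeEnergyLandscape) -> tuple[tuple[int, int], float]:
    """Global-minimum bin indices and its dG value."""
    landscape._check_fitted()
    return landscape.minimum_bin_, landscape.minimum_value_


def representative_frame(
    projection, landscape: FreeEnergyLandscape
) -> int:
    """Frame whose scores fall in the global-minimum bin, closest to its center.

    Ties (equal distance) keep the earliest frame.  The projection must be the
    one the landscape was fitted on, aligned with trajectory frame order.
    """
    landscape._check_fitted()
    X = np.asarray(
        projection[["pc1", "pc2"]]
        if isinstance(projection, pd.DataFrame)
        else projection,
        dtype=float,
    )
    bins = landscape.bin_of(X)
    (bi, bj) = landscape.minimum_bin_
    members = np.flatnonzero((bins[:, 0] == bi) & (bins[:, 1] == bj))
    assert members.size > 0, "global-minimum bin has no member frames"
    cx, cy = landscape.bin_centers()
    center = np.array([cx[bi], cy[bj]])
    dist = np.linalg.norm(X[members] - center, axis=1)
    return int(members[np.argmin(dist)])
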