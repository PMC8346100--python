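"""Dynamic cross-correlation matrices and residue link networks.

DCC(i,j) = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>), where dr is the per-frame
displacement of an atom from its ensemble-average position.  Values of +1
mark fully correlated (in-phase) motion, -1 fully anticorrelated motion.
Link networks keep the residue pairs whose |DCC| clears a threshold (0.5 by
default), labeled with sequence positions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .io import AtomSelection, TrajectoryEnsemble

__all__ = ["CorrelationMatrix", "dccm", "correlation_links"]

#: |i - j| at or below which a link is flagged as a trivial sequential neighbor
NEIGHBOR_SEPARATION = 2


@dataclasses.dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric per-atom-pair normalized cross-correlations in [-1, 1]."""

    values: np.ndarray
    resids: np.ndarray
    selection: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "resids", np.asarray(self.resids, dtype=int))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dccm(
    traj: TrajectoryEnsemble | np.ndarray,
    selection: Optional[AtomSelection] = None,
    stride: int = 1,
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the equilibrated frames.

    The trajectory must already be superposed to a common reference.  An atom
    with zero fluctuation gets zero off-diagonal correlations (with a
    warning) rather than raising; its diagonal stays 1 by convention.  All
    retained frames are used unless a ``stride`` is given.
    """
    if isinstance(traj, TrajectoryEnsemble):
        xyz = traj.retained_xyz
        resids = traj.topology.resid
        if selection is not None:
            xyz = xyz[:, selection.indices]
            resids = selection.resids
        label = selection.expression if selection is not None else "all"
    else:
        xyz = np.asarray(traj, dtype=float)
        resids = np.arange(xyz.shape[1])
        label = "array"
    xyz = xyz[::stride]
    if xyz.shape[0] < 2:
        raise ValueError("DCCM requires at least two frames")

    disp = xyz - xyz.mean(axis=0)  # (frames, atoms, 3)
    # <dr_i . dr_j> via a single tensor contraction over frames and xyz
    cov = np.einsum("tix,tjx->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-12  # numerically frozen atoms
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} atom(s) have zero fluctuation; their "
            "correlations are set to 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    matrix = cov / norm
    matrix[zero, :] = 0.0
    matrix[:, zero] = 0.0
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip((matrix + matrix.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(values=matrix, resids=resids, selection=label)


def correlation_links(
    matrix: CorrelationMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Residue pairs whose |DCC| meets the threshold (inclusive).

    Returns a tidy frame with columns ``res_i``, ``res_j`` (sequence
    positions, ``res_i < res_j``), ``dcc``, ``sign`` ("correlated" /
    "anticorrelated") and ``neighbor`` flagging trivially correlated
    sequential pairs (|i - j| <= 2 in chain order).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    v = matrix.values
    iu, ju = np.triu_indices(matrix.n, k=1)
    keep = np.abs(v[iu, ju]) >= threshold
    iu, ju = iu[keep], ju[keep]
    dcc = v[iu, ju]
    return pd.DataFrame(
        {
            "res_i": matrix.resids[iu],
            "res_j": matrix.resids[ju],
            "dcc": dcc,
            "sign": np.where(dcc >= 0, "correlated", "anticorrelated"),
            "neighbor": (ju - iu) <= NEIGHBOR_SEPARATION,
        }
    )
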