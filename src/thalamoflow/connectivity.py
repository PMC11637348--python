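"""Background connectivity by principal-component regression.

Task-state functional connectivity between seed voxels and cortical targets
is estimated on GLM residuals ("background connectivity": the stimulus-
evoked signal has been regressed out). A PCA is run across seed voxels,
all available components (min(V, T-1) by default) are entered as predictors
of each target series, and the component-space coefficients are projected
back to voxel space, giving one weight per (seed voxel, target) pair.

With the full component set this is algebraically the minimum-norm
multivariate least-squares solution, which equals ordinary multivariate OLS
whenever the seed data have full row rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class ConnectivityWeights:
    """Seed-voxel x target regression coefficients (W_FC)."""

    matrix: np.ndarray                 # (V, P)
    n_components: int
    seed_ids: list[str] | None = None
    target_ids: list[str] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_tsv(self, path: str | Path) -> None:
        """Dense matrix with row/column identifiers as a TSV file."""
        V, P = self.matrix.shape
        rows = self.seed_ids or [f"seed{i}" for i in range(V)]
        cols = self.target_ids or [f"target{j}" for j in range(P)]
        pd.DataFrame(self.matrix, index=rows, columns=cols).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConnectivityWeights":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            matrix=df.to_numpy(float),
            n_components=min(df.shape[0], df.shape[1]),
            seed_ids=list(df.index),
            target_ids=list(df.columns),
        )


def pc_regression_fc(
    seed_resid: np.ndarray,
    target_resid: np.ndarray,
    n_components: int | str = "max",
    is_residual: bool = True,
    force_raw: bool = False,
    seed_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> ConnectivityWeights:
    """Principal-component regression of targets on seed voxel series.

    Parameters
    ----------
    seed_resid, target_resid
        GLM residual series, shaped (V, T) and (P, T). Frames censored in
        the GLM should already be excluded. Declare raw (non-residual)
        series with ``is_residual=False``; they are refused unless
        ``force_raw=True``, since background connectivity is defined on
        task-regressed residuals.
    n_components
        Number of principal components, or ``"max"`` for min(V, T-1) —
        the maximum available (e.g. 199 components for 200 time points).
    """
    if not is_residual and not force_raw:
        raise ValidationError(
            "background connectivity expects GLM residuals; pass force_raw=True "
            "to regress raw series anyway"
        )
    seed_resid = np.atleast_2d(np.asarray(seed_resid, dtype=float))
    target_resid = np.atleast_2d(np.asarray(target_resid, dtype=float))
    V, T = seed_resid.shape
    P, T2 = target_resid.shape
    if T != T2:
        raise ValidationError("seed and target series must share the time axis")
    if T < 3:
        raise ValidationError("need at least 3 timepoints")
    k_max = min(V, T - 1)
    k = k_max if n_components == "max" else int(n_components)
    if not 1 <= k <= k_max:
        raise ValidationError(f"n_components must be in [1, {k_max}]")

    S = seed_resid - seed_resid.mean(axis=1, keepdims=True)  # center per voxel
    Yt = target_resid - target_resid.mean(axis=1, keepdims=True)
    # PCA across seed voxels: rows of S are voxel series; components via SVD
    U, sv, Vt = np.linalg.svd(S.T, full_matrices=False)  # S.T is T x V
    nz = sv > sv[0] * 1e-12 if sv.size else np.array([], bool)
    k_eff = int(min(k, nz.sum()))
    scores = U[:, :k_eff] * sv[:k_eff]                    # T x k component scores
    # regress each (centered) target on component scores
    coef, *_ = np.linalg.lstsq(scores, Yt.T, rcond=None)  # k x P
    weights = Vt[:k_eff].T @ coef                          # back to voxel space: V x P
    return ConnectivityWeights(
        matrix=weights, n_components=k_eff, seed_ids=seed_ids, target_ids=target_ids
    )
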