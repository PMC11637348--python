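"""Representational similarity analysis over the 8 task cues.

Neural dissimilarity between the voxel patterns of each cue pair is the
spatial Mahalanobis distance, with the voxel covariance estimated from GLM
residuals (optionally Ledoit-Wolf shrunk toward the diagonal, which keeps
the estimate invertible when voxels outnumber residual frames). The lower
triangle of the 8x8 neural RDM is regressed onto an intercept plus binary
model RDMs encoding hypothesized representations: Context, the
context-gated features (Context x Color, Context x Shape), the Task rule,
an integrated Decision representation, and control factors/interactions.
Group inference is a one-sample t per region and model with
Benjamini-Hochberg FDR across regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, ValidationError
from .task import ALL_CUES, Cue, TaskMapping, relevant_dimension, response_rule

#: The five representational models of interest, in reporting order.
PRIMARY_MODELS = ("Context", "Context x Color", "Context x Shape", "Task", "Decision")

#: Control regressors: remaining main effects and interactions.
CONTROL_MODELS = (
    "Shape", "Color", "Shape x Task", "Color x Task", "Color x Shape",
    "Context x Task", "Context x Shape x Task", "Context x Color x Task",
)

ALL_MODELS = PRIMARY_MODELS + CONTROL_MODELS


@dataclass
class RDM:
    """8x8 cue dissimilarity matrix."""

    matrix: np.ndarray
    cues: tuple[Cue, ...] = ALL_CUES
    estimator: str = "mahalanobis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValidationError("RDM must be square")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0) or (m < -1e-12).any():
            raise ValidationError("RDM must be symmetric, non-negative, zero-diagonal")
        self.matrix = m

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.matrix.shape[0], k=-1)
        return self.matrix[i, j]


@dataclass
class ModelRDM(RDM):
    """Binary (same/different) model dissimilarity matrix."""

    name: str = ""
    estimator: str = "model"


def _shrunk_covariance(residuals: np.ndarray) -> np.ndarray:
    from sklearn.covariance import LedoitWolf

    lw = LedoitWolf().fit(residuals)
    return lw.covariance_


def mahalanobis_rdm(
    cue_patterns: np.ndarray,
    residuals: np.ndarray | None = None,
    shrinkage: bool = True,
    cues: Sequence[Cue] = ALL_CUES,
) -> RDM:
    """Mahalanobis-distance RDM over cue patterns.

    Parameters
    ----------
    cue_patterns
        (n_cues, V) evoked pattern per cue (knot-mean betas).
    residuals
        (V, T) GLM residual series used to estimate the voxel covariance.
        ``None`` uses the identity (Euclidean distances).
    shrinkage
        Ledoit-Wolf shrinkage toward the diagonal. Without shrinkage the
        sample covariance is used when frames > voxels and must be
        invertible; with fewer frames than voxels a diagonal (per-voxel
        variance) estimate is the fallback.
    """
    X = np.atleast_2d(np.asarray(cue_patterns, dtype=float))
    n, V = X.shape
    if residuals is None:
        cov = np.eye(V)
        estimator = "euclidean"
    else:
        R = np.atleast_2d(np.asarray(residuals, dtype=float))
        if R.shape[0] == V and R.shape[1] != V:
            R = R.T  # frames x voxels
        if R.shape[0] < 2:
            raise ValidationError("need at least 2 residual frames")
        if shrinkage:
            cov = _shrunk_covariance(R)
            estimator = "mahalanobis-ledoitwolf"
        elif R.shape[0] <= V:
            cov = np.diag(np.var(R, axis=0, ddof=1))
            estimator = "mahalanobis-diagonal"
        else:
            cov = np.cov(R, rowvar=False)
            estimator = "mahalanobis-sample"
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise EstimationError(
            "residual covariance is singular; enable shrinkage"
        ) from err
    # whiten patterns: distance in whitened space is Mahalanobis distance
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X.T, lower=True).T
    d = np.zeros((n, n))
    for i in range(n):
        diff = Xw - Xw[i]
        d[i] = np.sqrt(np.sum(diff * diff, axis=1))
    return RDM(matrix=d, cues=tuple(cues), estimator=estimator)


# ---------------------------------------------------------------------------
# Model RDMs
# ---------------------------------------------------------------------------

def _factor_codes(mapping: TaskMapping) -> dict[str, np.ndarray]:
    """±1 codes per cue for the three stimulus factors and the task rule."""
    ctx = np.array([1.0 if c.texture == "solid" else -1.0 for c in ALL_CUES])
    shp = np.array([1.0 if c.shape == "circle" else -1.0 for c in ALL_CUES])
    col = np.array([1.0 if c.color == "blue" else -1.0 for c in ALL_CUES])
    tsk = np.array([1.0 if response_rule(c, mapping) == "face" else -1.0 for c in ALL_CUES])
    return {"Context": ctx, "Shape": shp, "Color": col, "Task": tsk}


def _binary_rdm_from_code(code: np.ndarray) -> np.ndarray:
    return (code[:, None] != code[None, :]).astype(float)


def model_rdms(mapping: TaskMapping | None = None) -> dict[str, ModelRDM]:
    """The 13 binary model/control RDMs for a task mapping.

    Factors are coded ±1 per cue; interaction models use elementwise
    products of factor codes; a pair is dissimilar (1) when the (product)
    codes differ. The Decision model encodes the integrated task identity:
    two cues are identical only if they share the context *and* the value
    on the context-relevant dimension (four equivalence classes of two
    cues), the representation that fully determines the response mapping.
    """
    mapping = mapping or TaskMapping()
    mapping.validate()
    codes = _factor_codes(mapping)
    prods = {
        "Context x Color": codes["Context"] * codes["Color"],
        "Context x Shape": codes["Context"] * codes["Shape"],
        "Shape x Task": codes["Shape"] * codes["Task"],
        "Color x Task": codes["Color"] * codes["Task"],
        "Color x Shape": codes["Color"] * codes["Shape"],
        "Context x Task": codes["Context"] * codes["Task"],
        "Context x Shape x Task": codes["Context"] * codes["Shape"] * codes["Task"],
        "Context x Color x Task": codes["Context"] * codes["Color"] * codes["Task"],
    }
    out: dict[str, ModelRDM] = {}
    for name in ALL_MODELS:
        if name == "Decision":
            classes = [
                (c.texture, c.value(relevant_dimension(c, mapping))) for c in ALL_CUES
            ]
            m = np.array(
                [[0.0 if a == b else 1.0 for b in classes] for a in classes]
            )
        else:
            code = codes.get(name, prods.get(name))
            m = _binary_rdm_from_code(code)
        out[name] = ModelRDM(matrix=m, name=name)
    return out


def full_rank_models(mapping: TaskMapping | None = None) -> dict[str, ModelRDM]:
    """Maximal subset of model RDMs jointly estimable with an intercept.

    The complete set of 13 binary model/control RDMs is rank deficient
    (the Decision model ties two interaction controls to the rest), so
    simultaneous fits use this greedy subset: models are added in the
    canonical order (primary models first) while the design stays full
    rank.
    """
    models = model_rdms(mapping)
    keep: dict[str, ModelRDM] = {}
    y_len = next(iter(models.values())).lower_triangle().size
    X = np.ones((y_len, 1))
    for name, m in models.items():
        cand = np.hstack([X, m.lower_triangle()[:, None]])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            keep[name] = m
            X = cand
    return keep


def fit_rdm_regression(
    neural: RDM,
    models: Mapping[str, ModelRDM] | Sequence[ModelRDM],
) -> pd.Series:
    """OLS of the neural RDM's lower triangle on intercept + model triangles."""
    if isinstance(models, Mapping):
        names = list(models)
        mats = [models[n] for n in names]
    else:
        mats = list(models)
        names = [m.name or f"model{i}" for i, m in enumerate(mats)]
    y = neural.lower_triangle()
    X = np.column_stack([np.ones_like(y)] + [m.lower_triangle() for m in mats])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dep = [(["intercept"] + names)[i] for i in sorted(piv[rank:])]
        raise EstimationError(f"collinear model RDMs: {dep}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[1:], index=names, name="beta")


@dataclass
class RSAResult:
    """Group inference for one region x model cell."""

    region: str
    model: str
    beta: float
    t: float
    p: float
    q: float
    significant: bool


def group_rsa(
    betas: pd.DataFrame,
    q: float = 0.05,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """One-sample t per region x model with BH-FDR across regions.

    ``betas`` is long-format with columns ``subject``, ``region``,
    ``model``, ``beta``. FDR correction is applied across regions within
    each model; the returned table includes the significant flag used to
    mask downstream voxel-to-voxel activity-flow analyses.
    """
    from statsmodels.stats.multitest import multipletests

    required = {"subject", "region", "model", "beta"}
    if not required <= set(betas.columns):
        raise ValidationError(f"betas table needs columns {sorted(required)}")
    rows = []
    for model, sub in betas.groupby("model"):
        regions, tvals, pvals, means = [], [], [], []
        for region, cell in sub.groupby("region"):
            v = cell["beta"].to_numpy(float)
            if v.size < 2:
                raise ValidationError("need >= 2 subjects per region")
            t, p = stats.ttest_1samp(v, 0.0, alternative=alternative)
            regions.append(region)
            tvals.append(float(t))
            pvals.append(float(p))
            means.append(float(v.mean()))
        reject, qvals, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
        for r, t, p, qq, sig, m in zip(regions, tvals, pvals, qvals, reject, means):
            rows.append(
                {"region": r, "model": model, "beta": m, "t": t, "p": p,
                 "q": float(qq), "significant": bool(sig)}
            )
    return pd.DataFrame(rows)
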