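"""Voxel-wise GLM estimation with an FIR (tent) basis.

Evoked responses are deconvolved with 9 piecewise-linear tent functions
spanning 0-14.4 s post cue (knots every TR = 1.8 s), one set per condition,
so no hemodynamic shape is assumed. Frames with high motion (FD > 0.4 mm)
are censored before fitting; residuals on the retained frames feed the
background-connectivity stage. Fitting is ordinary least squares with an
optional one-step AR(1) (Cochrane-Orcutt) prewhitening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import EstimationError, QCWarning, ValidationError
from .synth import FIR_KNOTS, TR, hrf_on_knots

CENSOR_FRACTION_LIMIT = 1.0 / 3.0  # subject-exclusion rule


@dataclass
class DesignSpec:
    """Parameters of the FIR design."""

    tr: float = TR
    n_basis: int = 9
    window: tuple[float, float] = (0.0, 14.4)
    conditions: Sequence[str] | None = None  # None -> infer from events
    censor_threshold: float = 0.4            # FD units (mm)
    drift_order: int = 2                     # per-run Legendre drift

    def __post_init__(self) -> None:
        if self.n_basis < 1:
            raise ValidationError("n_basis must be >= 1")

    @property
    def knots(self) -> np.ndarray:
        if self.n_basis == 1:
            return np.array([self.window[0]])
        return np.linspace(self.window[0], self.window[1], self.n_basis)


@dataclass
class GLMResult:
    """Betas, retained-frame residuals and censoring bookkeeping."""

    betas: pd.DataFrame            # voxel x regressor
    residuals: np.ndarray          # voxel x retained frame
    censor_mask: np.ndarray        # True where the frame was censored
    design_columns: list[str] = field(default_factory=list)

    @property
    def fraction_censored(self) -> float:
        return float(np.mean(self.censor_mask))


@dataclass
class EvokedVector:
    """Per-voxel evoked amplitude for one condition (O_seed / O_ctx)."""

    condition: str
    values: np.ndarray
    summary: str = "mean"

    def __len__(self) -> int:
        return len(self.values)


def _tent_column(frame_times: np.ndarray, onsets: np.ndarray, knot: float, tr: float,
                 window: tuple[float, float]) -> np.ndarray:
    col = np.zeros_like(frame_times)
    for onset in onsets:
        tau = frame_times - onset
        v = np.maximum(0.0, 1.0 - np.abs(tau - knot) / tr)
        v[(tau < window[0]) | (tau > window[1])] = 0.0
        col += v
    return col


def _legendre_drift(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(d)(x) for d in range(order + 1)])


def build_fir_design(
    events: pd.DataFrame,
    spec: DesignSpec,
    run_frames: Sequence[int],
) -> pd.DataFrame:
    """Tent-basis design matrix with per-run drift columns.

    One column per (condition, knot), named ``"<condition>@k<j>"``, plus
    per-run Legendre drift columns ``"run<r>:drift<d>"``. Event onsets are
    run-relative; runs are laid out consecutively with ``run_frames`` frames
    each.
    """
    runs = sorted(events["run"].unique())
    if len(runs) > len(run_frames):
        raise ValidationError("events reference more runs than run_frames provides")
    conditions = list(spec.conditions) if spec.conditions is not None else sorted(
        events["condition"].unique()
    )
    T = int(sum(run_frames))
    offsets = np.concatenate([[0], np.cumsum(run_frames)])
    cols: dict[str, np.ndarray] = {
        f"{cond}@k{j}": np.zeros(T) for cond in conditions for j in range(spec.n_basis)
    }
    for run in runs:
        i = runs.index(run)
        nf = run_frames[i]
        frame_times = np.arange(nf) * spec.tr
        ev = events[events["run"] == run]
        if (ev["onset"] < 0).any() or (ev["onset"] >= nf * spec.tr).any():
            raise ValidationError(f"run {run}: event onsets outside run time bounds")
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        for cond in conditions:
            onsets = ev.loc[ev["condition"] == cond, "onset"].to_numpy(float)
            if onsets.size == 0:
                continue
            for j, knot in enumerate(spec.knots):
                cols[f"{cond}@k{j}"][sl] += _tent_column(
                    frame_times, onsets, knot, spec.tr, spec.window
                )
    for i, nf in enumerate(run_frames):
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        drift = _legendre_drift(nf, spec.drift_order)
        for d in range(drift.shape[1]):
            col = np.zeros(T)
            col[sl] = drift[:, d]
            cols[f"run{i + 1}:drift{d}"] = col
    return pd.DataFrame(cols)


def _name_collinear(X: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [names[i] for i in sorted(piv[rank:])]


def fit_glm(
    Y: np.ndarray,
    X: pd.DataFrame,
    nuisance: np.ndarray | None = None,
    censor: np.ndarray | None = None,
    prewhiten: bool = False,
) -> GLMResult:
    """OLS fit of ``Y`` (voxel x time) on the design, on retained frames.

    ``censor`` is a boolean mask, True for frames to drop. Censoring more
    than a third of the frames raises a :class:`QCWarning` (the
    subject-exclusion rule). ``prewhiten=True`` applies one Cochrane-Orcutt
    AR(1) iteration with a pooled lag-1 autocorrelation estimate.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    if nuisance is not None and np.asarray(nuisance).size:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != Xm.shape[0]:
            nuis = nuis.T
        names += [f"nuisance{i}" for i in range(nuis.shape[1])]
        Xm = np.hstack([Xm, nuis])
    if censor is None:
        censor = np.zeros(Xm.shape[0], dtype=bool)
    censor = np.asarray(censor, dtype=bool)
    keep = ~censor
    if np.mean(censor) > CENSOR_FRACTION_LIMIT:
        warnings.warn(
            f"{np.mean(censor):.1%} of frames censored (> 33.3%): subject "
            "would be excluded by the motion QC rule",
            QCWarning,
            stacklevel=2,
        )
    Xk, Yk = Xm[keep], Y[:, keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        bad = _name_collinear(Xk, names)
        raise EstimationError(f"design is rank deficient; collinear columns: {bad}")

    def _ols(A, B):
        return np.linalg.lstsq(A, B.T, rcond=None)[0].T

    betas = _ols(Xk, Yk)
    resid = Yk - betas @ Xk.T
    if prewhiten:
        r = resid - resid.mean(axis=1, keepdims=True)
        num = np.sum(r[:, 1:] * r[:, :-1])
        den = np.sum(r[:, :-1] ** 2)
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
        Xw = Xk[1:] - rho * Xk[:-1]
        Yw = Yk[:, 1:] - rho * Yk[:, :-1]
        betas = _ols(Xw, Yw)
        resid = Yk - betas @ Xk.T
    return GLMResult(
        betas=pd.DataFrame(betas, columns=names),
        residuals=resid,
        censor_mask=censor,
        design_columns=names,
    )


def censor_from_fd(fd: np.ndarray, threshold: float = 0.4) -> np.ndarray:
    """Boolean censor mask from a framewise-displacement series."""
    return np.asarray(fd, dtype=float) > threshold


def lss_trial_betas(
    Y: np.ndarray,
    events: pd.DataFrame,
    spec: DesignSpec,
    run_frames: Sequence[int],
    nuisance: np.ndarray | None = None,
    censor: np.ndarray | None = None,
    hrf: np.ndarray | None = None,
    include_baseline: bool = True,
) -> np.ndarray:
    """Trial-wise betas by the least-squares-sum (LSS) scheme.

    For each target trial the design holds (a) that trial's own regressor
    and (b) a single regressor summing all remaining trials, plus drift and
    nuisance columns (drop the drift columns with
    ``include_baseline=False``); the returned beta is the target trial's.
    Each trial's regressor is a fixed response shape (default: canonical
    double-gamma on the tent knots) placed at the trial onset.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if hrf is None:
        hrf = hrf_on_knots(1.0)
    runs = sorted(events["run"].unique())
    T = int(sum(run_frames))
    offsets = np.concatenate([[0], np.cumsum(run_frames)])
    n_trials = len(events)
    if n_trials < 1:
        raise ValidationError("no trials")

    trial_cols = np.zeros((T, n_trials))
    for k, (_, ev) in enumerate(events.iterrows()):
        i = runs.index(ev["run"])
        nf = run_frames[i]
        frame_times = np.arange(nf) * spec.tr
        tau = frame_times - float(ev["onset"])
        col = np.interp(tau, FIR_KNOTS, hrf, left=0.0, right=0.0)
        col[(tau < 0) | (tau > FIR_KNOTS[-1])] = 0.0
        trial_cols[int(offsets[i]):int(offsets[i + 1]), k] = col

    drift_cols = []
    if include_baseline:
        for i, nf in enumerate(run_frames):
            drift = _legendre_drift(nf, spec.drift_order)
            for d in range(drift.shape[1]):
                col = np.zeros(T)
                col[int(offsets[i]):int(offsets[i + 1])] = drift[:, d]
                drift_cols.append(col)
    base = np.column_stack(drift_cols) if drift_cols else np.zeros((T, 0))
    if nuisance is not None and np.asarray(nuisance).size:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != T:
            nuis = nuis.T
        base = np.hstack([base, nuis])
    keep = np.ones(T, dtype=bool) if censor is None else ~np.asarray(censor, dtype=bool)

    if n_trials == 1:
        warnings.warn("single trial: LSS falls back to an ordinary beta", stacklevel=2)
    betas = np.empty((n_trials, Y.shape[0]))
    total = trial_cols.sum(axis=1)
    for k in range(n_trials):
        others = total - trial_cols[:, k]
        design = [trial_cols[:, k:k + 1]]
        if n_trials > 1:
            design.append(others[:, None])
        design.append(base)
        A = np.hstack(design)[keep]
        b = np.linalg.lstsq(A, Y[:, keep].T, rcond=None)[0]
        betas[k] = b[0]
    return betas


def condition_evoked(glm: GLMResult, condition: str, summary: str = "mean") -> EvokedVector:
    """Collapse a condition's per-knot betas to one amplitude per voxel.

    ``summary`` is ``"mean"`` (default: mean over the 9 knots), ``"peak"``
    (the knot value of largest magnitude, signed) or ``"area"`` (sum over
    knots).
    """
    cols = [c for c in glm.betas.columns if c.startswith(f"{condition}@k")]
    if not cols:
        raise KeyError(f"condition {condition!r} not in the fitted design")
    B = glm.betas[cols].to_numpy()
    if summary == "mean":
        v = B.mean(axis=1)
    elif summary == "peak":
        idx = np.argmax(np.abs(B), axis=1)
        v = B[np.arange(B.shape[0]), idx]
    elif summary == "area":
        v = B.sum(axis=1)
    else:
        raise ValidationError(f"unknown summary rule {summary!r}")
    return EvokedVector(condition=condition, values=v, summary=summary)


def group_contrast(
    evoked_a: Sequence[np.ndarray | EvokedVector],
    evoked_b: Sequence[np.ndarray | EvokedVector],
) -> tuple[np.ndarray, int]:
    """Paired-difference one-sample t per voxel across subjects.

    Returns the t map and its degrees of freedom (n_subjects - 1).
    """
    a = np.stack([e.values if isinstance(e, EvokedVector) else np.asarray(e) for e in evoked_a])
    b = np.stack([e.values if isinstance(e, EvokedVector) else np.asarray(e) for e in evoked_b])
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValidationError("need matched evoked vectors from >= 2 subjects")
    d = a - b
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, d.mean(axis=0) / (sd / np.sqrt(n)), 0.0)
    return t, n - 1


def cluster_threshold(
    stat_map: np.ndarray,
    voxel_p: float = 0.05,
    min_size: int = 58,
    df: int | None = None,
    p_map: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold a statistic volume and keep face-connected clusters.

    Voxels pass if their two-sided p (from ``p_map``, or computed from the t
    values in ``stat_map`` with ``df``) is below ``voxel_p``; connected
    components share a face (6-connectivity); components smaller than
    ``min_size`` are dropped. Positive and negative voxels are clustered
    separately so opposite-signed effects never merge. Returns the labeled
    volume and a table with cluster size, sign and center of mass.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if p_map is None:
        if df is None:
            raise ValidationError("need df to convert t values to p, or pass p_map")
        p_map = 2.0 * stats.t.sf(np.abs(stat_map), df)
    supra = np.asarray(p_map) < voxel_p
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(stat_map.ndim, 1)  # face adjacency
    labeled = np.zeros(stat_map.shape, dtype=int)
    rows = []
    next_label = 1
    for sign, m in (("+", supra & (stat_map > 0)), ("-", supra & (stat_map < 0))):
        lab, n = ndimage.label(m, structure=structure)
        for i in range(1, n + 1):
            comp = lab == i
            size = int(comp.sum())
            if size < min_size:
                continue
            labeled[comp] = next_label
            com = ndimage.center_of_mass(comp)
            rows.append(
                {"cluster": next_label, "size": size, "sign": sign,
                 **{f"com_{ax}": c for ax, c in zip("xyz", com)}}
            )
            next_label += 1
    table = pd.DataFrame(rows, columns=["cluster", "size", "sign", "com_x", "com_y", "com_z"])
    return labeled, table
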