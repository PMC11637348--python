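"""Activity-flow mapping: predict cortical patterns from seed activity.

The model predicts a cortical activity pattern as the connectivity-weighted
sum of seed-region evoked responses,

    P_ctx = O_seed . W_FC,

where ``O_seed`` is the voxel-wise seed evoked pattern (from the FIR GLM)
and ``W_FC`` the seed-voxel x target background-connectivity matrix.
Accuracy is the split-half cross-validated Pearson correlation between
observed and predicted patterns (observed half 1 vs. predicted half 2 and
vice versa, averaged), optionally normalized by the split-half noise
ceiling r_nc = vU / (vU + vE). Significance comes from permutation nulls
that shuffle either the evoked vector or the connectivity matrix, and
spatial specificity from virtual lesions that zero 20%-wide windows of
voxels ranked by evoked amplitude.

:class:`ActivityFlowModel` is the statsmodels-style entry point: build it
from pattern-level arrays or from a synthetic dataset, call :meth:`fit`,
and query the returned :class:`ActivityFlowResults` for accuracies, nulls,
lesion profiles and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glm as glm_mod
from .connectivity import ConnectivityWeights, pc_regression_fc
from .exceptions import ValidationError
from .glm import EvokedVector

Pattern = np.ndarray


def _as_vector(x) -> np.ndarray:
    if isinstance(x, EvokedVector):
        x = x.values
    return np.asarray(x, dtype=float).ravel()


def _as_matrix(w) -> np.ndarray:
    if isinstance(w, ConnectivityWeights):
        w = w.matrix
    return np.asarray(w, dtype=float)


def predict_pattern(evoked, weights) -> Pattern:
    """P_ctx[j] = sum_v O[v] * W[v, j] (the activity-flow dot product)."""
    O = _as_vector(evoked)
    W = _as_matrix(weights)
    if W.shape[0] != O.size:
        raise ValidationError(f"evoked length {O.size} != weight rows {W.shape[0]}")
    return O @ W


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("correlation undefined for a constant pattern")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    return float(np.mean(az * bz))


def _safe_corr(a, b) -> float:
    try:
        return _corr(a, b)
    except ValidationError:
        return np.nan


@dataclass
class NoiseCeiling:
    r_nc: float
    vU: float
    vE: float
    degenerate: bool = False


def noise_ceiling(pred_h1: Pattern, pred_h2: Pattern) -> NoiseCeiling:
    """Split-half noise ceiling r_nc = vU / (vU + vE).

    ``vU`` is the variance of the first half's predicted pattern (the
    "true signal"), ``vE`` the variance of the difference between the two
    halves' predictions (the "noise").
    """
    p1 = np.asarray(pred_h1, float).ravel()
    p2 = np.asarray(pred_h2, float).ravel()
    if p1.size != p2.size:
        raise ValidationError("predicted halves must have equal length")
    vU = float(np.var(p1))
    vE = float(np.var(p1 - p2))
    if vU + vE == 0.0:
        return NoiseCeiling(np.nan, vU, vE, degenerate=True)
    return NoiseCeiling(vU / (vU + vE), vU, vE)


@dataclass
class ActivityFlowResult:
    """Accuracy of one split-half activity-flow evaluation."""

    predicted: tuple[Pattern, Pattern]
    observed: tuple[Pattern, Pattern]
    raw_accuracy: float
    r_nc: float
    vU: float
    vE: float
    accuracy: float                      # noise-ceiling normalized if requested
    normalized: bool
    condition: str | None = None


Halves = tuple[tuple, tuple]  # ((O1, W1, obs1), (O2, W2, obs2))


def split_half_accuracy(halves: Halves, normalize: bool = True,
                        condition: str | None = None) -> ActivityFlowResult:
    """Split-half cross-validated prediction accuracy.

    ``halves`` holds two independently estimated (evoked, weights, observed)
    triples. The raw accuracy is the mean of corr(observed_h1, predicted_h2)
    and corr(observed_h2, predicted_h1) on standardized patterns; with
    ``normalize=True`` it is divided by the noise ceiling of the two
    predicted patterns.
    """
    (o1, w1, obs1), (o2, w2, obs2) = halves
    pred1 = predict_pattern(o1, w1)
    pred2 = predict_pattern(o2, w2)
    obs1 = np.asarray(obs1, float).ravel()
    obs2 = np.asarray(obs2, float).ravel()
    raw = 0.5 * (_corr(obs1, pred2) + _corr(obs2, pred1))
    nc = noise_ceiling(pred1, pred2)
    acc = raw / nc.r_nc if normalize and np.isfinite(nc.r_nc) and nc.r_nc > 0 else raw
    return ActivityFlowResult(
        predicted=(pred1, pred2),
        observed=(obs1, obs2),
        raw_accuracy=raw,
        r_nc=nc.r_nc,
        vU=nc.vU,
        vE=nc.vE,
        accuracy=acc,
        normalized=normalize,
        condition=condition,
    )


def permutation_null(
    halves: Halves,
    kind: str = "shuffle_evoked",
    n_perm: int = 5000,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[np.ndarray, float]:
    """Permutation null for the split-half accuracy.

    ``shuffle_evoked`` permutes the entries of the seed evoked vector;
    ``shuffle_fc`` permutes all elements of the connectivity matrix jointly.
    The same permutation is applied to both halves so the two folds stay a
    consistent "subject". Returns the null accuracies and the empirical
    p-value (1 + #{null >= observed}) / (n_perm + 1).
    """
    if kind not in ("shuffle_evoked", "shuffle_fc"):
        raise ValidationError(f"unknown null kind {kind!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    (o1, w1, obs1), (o2, w2, obs2) = halves
    o1, o2 = _as_vector(o1), _as_vector(o2)
    w1, w2 = _as_matrix(w1), _as_matrix(w2)
    observed = split_half_accuracy(((o1, w1, obs1), (o2, w2, obs2)), normalize=normalize).accuracy
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        if kind == "shuffle_evoked":
            perm = rng.permutation(o1.size)
            h = ((o1[perm], w1, obs1), (o2[perm], w2, obs2))
        else:
            perm = rng.permutation(w1.size)
            h = (
                (o1, w1.ravel()[perm].reshape(w1.shape), obs1),
                (o2, w2.ravel()[perm].reshape(w2.shape), obs2),
            )
        res = split_half_accuracy(h, normalize=normalize)
        null[i] = res.accuracy
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return null, float(p)


# ---------------------------------------------------------------------------
# Virtual lesions
# ---------------------------------------------------------------------------

@dataclass
class LesionProfile:
    """Accuracy change after zeroing one 20%-wide window of seed voxels."""

    window_start: int              # percentile 1..80
    fraction: float
    removed: np.ndarray            # voxel indices zeroed
    accuracy_full: float
    accuracy_lesioned: float
    degenerate: bool = False

    @property
    def reduction(self) -> float:
        return self.accuracy_full - self.accuracy_lesioned

    @property
    def reduction_pct(self) -> float:
        if self.accuracy_full == 0:
            return np.nan
        return 100.0 * self.reduction / self.accuracy_full


def _lesion_order(o1: np.ndarray, o2: np.ndarray) -> np.ndarray:
    """Voxels sorted by mean split-half |evoked|, weakest first, stable ties."""
    amp = 0.5 * (np.abs(o1) + np.abs(o2))
    return np.argsort(amp, kind="stable")


def _lesion_window(V: int, fraction: float, window_start: int) -> tuple[int, int]:
    n_remove = int(np.ceil(fraction * V))
    if n_remove < 1:
        raise ValidationError("fraction * V must be >= 1")
    if not 1 <= window_start <= max(1, 100 - int(round(100 * fraction))):
        raise ValidationError("lesion window exceeds the [0, 100] percentile range")
    # nearest-rank start of the window's lower percentile; the last window
    # (start = 100 - 100*fraction) covers exactly the strongest voxels
    start = min(int(np.floor(window_start * V / 100.0)), V - n_remove)
    return start, n_remove


def virtual_lesion(
    halves: Halves,
    fraction: float = 0.20,
    window_start: int = 1,
    normalize: bool = True,
) -> LesionProfile:
    """Zero one window of seed voxels (ranked by |evoked|) and re-predict.

    The window covers ``fraction`` of the voxels and starts at the given
    percentile of the ascending amplitude ranking (nearest-rank rule);
    evoked entries of removed voxels are set to zero in both halves before
    recomputing the split-half accuracy.
    """
    (o1, w1, obs1), (o2, w2, obs2) = halves
    o1, o2 = _as_vector(o1), _as_vector(o2)
    order = _lesion_order(o1, o2)
    start, n_remove = _lesion_window(o1.size, fraction, window_start)
    removed = order[start:start + n_remove]
    full = split_half_accuracy(((o1, w1, obs1), (o2, w2, obs2)), normalize=normalize)
    l1, l2 = o1.copy(), o2.copy()
    l1[removed] = 0.0
    l2[removed] = 0.0
    degenerate = False
    try:
        lesioned = split_half_accuracy(((l1, w1, obs1), (l2, w2, obs2)),
                                       normalize=normalize).accuracy
    except ValidationError:
        lesioned, degenerate = 0.0, True
    return LesionProfile(
        window_start=window_start,
        fraction=fraction,
        removed=removed,
        accuracy_full=full.accuracy,
        accuracy_lesioned=lesioned,
        degenerate=degenerate,
    )


def lesion_scan(halves: Halves, fraction: float = 0.20,
                windows: Sequence[int] = range(1, 81),
                normalize: bool = True) -> list[LesionProfile]:
    """Virtual lesions stepping the window start from the 1st to 80th percentile."""
    return [virtual_lesion(halves, fraction, w, normalize) for w in windows]


def nucleus_mean_reduction(
    profiles: Sequence[LesionProfile],
    labels: Sequence[str] | np.ndarray,
) -> pd.Series:
    """Mean attributed accuracy reduction per nucleus.

    A voxel's attributed reduction is the mean reduction over the lesion
    windows containing it; nuclei average over their voxels. Voxels never
    covered by a window (the topmost percentiles) are excluded; an empty
    nucleus is reported as NaN.
    """
    labels = np.asarray(labels)
    V = labels.size
    sums = np.zeros(V)
    counts = np.zeros(V)
    for p in profiles:
        sums[p.removed] += p.reduction
        counts[p.removed] += 1
    with np.errstate(invalid="ignore"):
        per_voxel = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = {}
    for nucleus in pd.unique(labels):
        vals = per_voxel[labels == nucleus]
        out[nucleus] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
    return pd.Series(out, name="mean_reduction")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ActivityFlowModel:
    """Activity-flow model over two independently estimated data halves.

    Parameters
    ----------
    evoked
        Pair of seed evoked vectors (O_seed), one per half.
    weights
        Pair of seed-to-target connectivity estimates (W_FC), one per half.
    observed
        Pair of observed target patterns.
    seed_labels
        Optional nucleus label per seed voxel (enables per-nucleus lesion
        attribution on the results object).
    """

    def __init__(self, evoked, weights, observed, condition: str | None = None,
                 seed_labels: Sequence[str] | None = None, normalize: bool = True):
        self.evoked = tuple(_as_vector(o) for o in evoked)
        self.weights = tuple(_as_matrix(w) for w in weights)
        self.observed = tuple(np.asarray(y, float).ravel() for y in observed)
        if len(self.evoked) != 2 or len(self.weights) != 2 or len(self.observed) != 2:
            raise ValidationError("need exactly two halves")
        self.condition = condition
        self.seed_labels = None if seed_labels is None else np.asarray(seed_labels)
        self.normalize = normalize

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dataset(
        cls,
        dataset,
        condition: str = "EDS",
        halves: tuple[Sequence[int], Sequence[int]] | None = None,
        summary: str = "mean",
        spec: glm_mod.DesignSpec | None = None,
        normalize: bool = True,
        use_censoring: bool = True,
    ) -> "ActivityFlowModel":
        """Estimate both halves from a :class:`~thalamoflow.synth.SyntheticDataset`.

        Runs are split into two halves (default: first half vs. last half of
        the run list, i.e. runs 1-4 vs. 5-8 for 8 runs). Per half, a seed
        and a target FIR GLM are fitted with nuisance regressors and FD
        censoring, condition evoked vectors are summarized over knots, and
        background connectivity is estimated from the residuals.
        """
        runs = sorted(dataset.events["run"].unique())
        if halves is None:
            mid = len(runs) // 2
            if mid == 0:
                raise ValidationError("need at least 2 runs to split")
            halves = (runs[:mid], runs[mid:])
        spec = spec or glm_mod.DesignSpec(tr=dataset.tr)
        evoked, weights, observed = [], [], []
        for half_runs in halves:
            idx = np.concatenate(
                [np.arange(dataset.frames_of_run(r).start, dataset.frames_of_run(r).stop)
                 for r in half_runs]
            )
            ev = dataset.events[dataset.events["run"].isin(half_runs)]
            run_frames = [dataset.run_frames[runs.index(r)] for r in half_runs]
            X = glm_mod.build_fir_design(ev, spec, run_frames)
            nuis = dataset.nuisance[idx]
            censor = (
                glm_mod.censor_from_fd(dataset.fd[idx], spec.censor_threshold)
                if use_censoring else None
            )
            seed_fit = glm_mod.fit_glm(dataset.seed_ts[:, idx], X, nuis, censor)
            target_fit = glm_mod.fit_glm(dataset.target_ts[:, idx], X, nuis, censor)
            if condition == "All":
                conds = [c for c in ("EDS", "IDS", "Stay")
                         if any(col.startswith(f"{c}@k") for col in seed_fit.betas.columns)]
                o = np.mean([glm_mod.condition_evoked(seed_fit, c, summary).values
                             for c in conds], axis=0)
                y = np.mean([glm_mod.condition_evoked(target_fit, c, summary).values
                             for c in conds], axis=0)
            else:
                o = glm_mod.condition_evoked(seed_fit, condition, summary).values
                y = glm_mod.condition_evoked(target_fit, condition, summary).values
            W = pc_regression_fc(seed_fit.residuals, target_fit.residuals)
            evoked.append(o)
            weights.append(W.matrix)
            observed.append(y)
        return cls(evoked, weights, observed, condition=condition,
                   seed_labels=dataset.brain.seed_labels, normalize=normalize)

    def _halves(self) -> Halves:
        return (
            (self.evoked[0], self.weights[0], self.observed[0]),
            (self.evoked[1], self.weights[1], self.observed[1]),
        )

    def fit(self) -> "ActivityFlowResults":
        res = split_half_accuracy(self._halves(), normalize=self.normalize,
                                  condition=self.condition)
        return ActivityFlowResults(self, res)


class ActivityFlowResults:
    """Results of an :class:`ActivityFlowModel` fit."""

    def __init__(self, model: ActivityFlowModel, result: ActivityFlowResult):
        self.model = model
        self._result = result

    # -- point estimates -----------------------------------------------------
    @property
    def accuracy(self) -> float:
        """Reported (noise-ceiling normalized, if requested) accuracy."""
        return self._result.accuracy

    @property
    def raw_accuracy(self) -> float:
        return self._result.raw_accuracy

    @property
    def noise_ceiling(self) -> float:
        return self._result.r_nc

    @property
    def vU(self) -> float:
        return self._result.vU

    @property
    def vE(self) -> float:
        return self._result.vE

    @property
    def predicted(self) -> tuple[Pattern, Pattern]:
        return self._result.predicted

    # -- inference -----------------------------------------------------------
    def permutation_null(self, kind: str = "shuffle_evoked", n_perm: int = 5000,
                         seed: int = 0) -> tuple[np.ndarray, float]:
        return permutation_null(self.model._halves(), kind=kind, n_perm=n_perm,
                                seed=seed, normalize=self.model.normalize)

    def virtual_lesion(self, window_start: int, fraction: float = 0.20) -> LesionProfile:
        return virtual_lesion(self.model._halves(), fraction, window_start,
                              normalize=self.model.normalize)

    def lesion_scan(self, fraction: float = 0.20,
                    windows: Sequence[int] = range(1, 81)) -> list[LesionProfile]:
        return lesion_scan(self.model._halves(), fraction, windows,
                           normalize=self.model.normalize)

    def nucleus_mean_reduction(self, profiles: Sequence[LesionProfile] | None = None,
                               labels: Sequence[str] | None = None) -> pd.Series:
        if labels is None:
            labels = self.model.seed_labels
        if labels is None:
            raise ValidationError("no seed labels available")
        if profiles is None:
            profiles = self.lesion_scan()
        return nucleus_mean_reduction(profiles, labels)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Activity-flow model results",
            "===========================",
            f"condition:            {r.condition or '-'}",
            f"seed voxels:          {self.model.evoked[0].size}",
            f"targets:              {self.model.observed[0].size}",
            f"raw split-half r:     {r.raw_accuracy: .4f}",
            f"noise ceiling r_nc:   {r.r_nc: .4f}  (vU={r.vU:.4g}, vE={r.vE:.4g})",
            f"reported accuracy:    {r.accuracy: .4f}"
            + ("  (noise-ceiling normalized)" if r.normalized else "  (raw)"),
        ]
        return "\n".join(lines)
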