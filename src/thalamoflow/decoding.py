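"""Searchlight multivoxel decoding with leave-one-run-out cross-validation.

Trial-wise (LSS) betas are decoded with an L2-regularized logistic
regression inside a spherical searchlight (default radius 6 mm). Features
are standardized inside each training fold, so accuracies are invariant to
voxel-wise affine rescaling and no test information leaks into training.
Group inference tests accuracy > chance per voxel (sign-flip permutation by
default, one-sample t as fallback) and applies cluster-extent correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .glm import cluster_threshold


@dataclass
class SearchlightMap:
    """Per-center decoding accuracy for one label dimension."""

    accuracy: np.ndarray          # (n_centers,)
    centers: np.ndarray           # (n_centers,) voxel indices into the mask order
    sphere_sizes: np.ndarray      # voxels per sphere
    radius_mm: float
    dimension: str = ""


def searchlight_spheres(
    coords: np.ndarray,
    radius_mm: float = 6.0,
    voxel_size_mm: float = 2.5,
) -> list[np.ndarray]:
    """Index sets of in-mask voxels within a Euclidean radius of each voxel.

    ``coords`` are grid coordinates (voxel units) of the in-mask voxels;
    distances are computed in mm via ``voxel_size_mm``. Every in-mask voxel
    is a sphere center; spheres are clipped to the mask.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 0:
        raise ValidationError("empty mask")
    if radius_mm < voxel_size_mm / 2.0:
        raise ValidationError("radius must be at least half a voxel")
    tree = cKDTree(coords * voxel_size_mm)
    return [np.asarray(idx, dtype=int)
            for idx in tree.query_ball_point(coords * voxel_size_mm, r=radius_mm)]


def _loro_predictions(X: np.ndarray, y: np.ndarray, runs: np.ndarray,
                      C: float = 1.0) -> dict:
    """Test-fold predictions per held-out run.

    The classifier (standardizer included) is fitted on the training runs
    only, so fold predictions are a pure function of the training data —
    test labels never enter the fit.
    """
    import warnings

    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    out = {}
    for run in np.unique(runs):
        test = runs == run
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {run}: single-class training set skipped", stacklevel=2)
            continue
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=C, max_iter=1000),
        )
        clf.fit(X[train], y[train])
        out[run] = (np.where(test)[0], clf.predict(X[test]))
    return out


def _loro_accuracy(X: np.ndarray, y: np.ndarray, runs: np.ndarray,
                   C: float = 1.0) -> float:
    """Leave-one-run-out CV accuracy of a standardized logistic regression."""
    folds = _loro_predictions(X, y, runs, C=C)
    if not folds:
        raise ValidationError("no usable cross-validation fold")
    return float(np.mean([np.mean(pred == y[idx]) for idx, pred in folds.values()]))


def decode_dimension(
    trial_betas: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    spheres: list[np.ndarray],
    dimension: str = "",
    radius_mm: float = 6.0,
    C: float = 1.0,
) -> SearchlightMap:
    """Leave-one-run-out searchlight decoding of a binary label.

    ``trial_betas`` is (n_trials, V); ``labels`` a binary label per trial;
    ``runs`` the run index per trial. Returns the mean test accuracy per
    sphere.
    """
    trial_betas = np.atleast_2d(np.asarray(trial_betas, dtype=float))
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    if len(np.unique(runs)) < 2:
        raise ValidationError("need >= 2 runs for leave-one-run-out CV")
    acc = np.empty(len(spheres))
    sizes = np.empty(len(spheres), dtype=int)
    for i, sph in enumerate(spheres):
        acc[i] = _loro_accuracy(trial_betas[:, sph], labels, runs, C=C)
        sizes[i] = len(sph)
    return SearchlightMap(
        accuracy=acc,
        centers=np.arange(len(spheres)),
        sphere_sizes=sizes,
        radius_mm=radius_mm,
        dimension=dimension,
    )


def _signflip_pvalues(delta: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """One-sided sign-flip permutation p per voxel for mean(delta) > 0."""
    rng = np.random.default_rng(seed)
    n, v = delta.shape
    observed = delta.mean(axis=0)
    exceed = np.ones(v)
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        exceed += (signs @ delta) / n >= observed
    return exceed / (n_perm + 1.0)


def group_decoding_inference(
    maps: np.ndarray,
    volume_shape: tuple[int, ...] | None = None,
    coords: np.ndarray | None = None,
    chance: float = 0.5,
    voxel_p: float = 0.001,
    min_size: int = 343,
    method: str = "signflip",
    n_perm: int = 1000,
    seed: int = 0,
):
    """Group test of accuracy > chance with cluster-extent correction.

    ``maps`` is (n_subjects, n_voxels) accuracy maps on a common mask;
    ``coords``/``volume_shape`` place the mask voxels in a volume so
    face-adjacency clustering applies. Returns (labeled volume, cluster
    table, per-voxel p).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[0] < 2:
        raise ValidationError("need >= 2 subjects")
    delta = maps - chance
    if method == "signflip":
        p = _signflip_pvalues(delta, n_perm=n_perm, seed=seed)
    elif method == "ttest":
        _, p = stats.ttest_1samp(delta, 0.0, axis=0, alternative="greater")
    else:
        raise ValidationError(f"unknown group inference method {method!r}")
    mean_map = delta.mean(axis=0)
    if coords is None:
        coords = np.stack([np.arange(maps.shape[1]), np.zeros(maps.shape[1]),
                           np.zeros(maps.shape[1])], axis=1).astype(int)
    coords = np.asarray(coords, dtype=int)
    if volume_shape is None:
        volume_shape = tuple(coords.max(axis=0) + 1)
    stat_vol = np.zeros(volume_shape)
    p_vol = np.ones(volume_shape)
    ix = tuple(coords.T)
    stat_vol[ix] = mean_map
    p_vol[ix] = p
    labeled, table = cluster_threshold(
        stat_vol, voxel_p=voxel_p, min_size=min_size, p_map=p_vol
    )
    return labeled, table, p
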