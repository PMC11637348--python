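"""Synthetic thalamocortical data with known ground truth.

The generator emulates the signal model assumed by the analysis chain: each
seed (thalamic) voxel carries condition-specific evoked responses convolved
with a nucleus-specific hemodynamic response, plus latent background
fluctuations; cortical targets receive the seed signal propagated through a
ground-truth weight matrix ``W*``. Because the ground truth (weights, evoked
amplitudes, nucleus labels) travels with every dataset, recovery of the
connectivity and activity-flow estimates can be scored exactly.

Two deliberate simplifications keep the noiseless recovery identities exact:

* the hemodynamic response is piecewise-linear on the FIR knot grid (a
  double-gamma sampled at the knots and linearly interpolated), so evoked
  responses lie exactly in the span of the tent basis;
* background fluctuations are the sum of ``K`` shared low-rank latent
  sources and per-voxel private fluctuations, so the seed background is
  full rank and principal-component regression can recover ``W*`` exactly
  in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import task
from .exceptions import ValidationError

TR = 1.8  # s, repetition time of the emulated acquisition

#: Nine major thalamic nuclei (synthetic stand-in for a nucleus atlas).
DEFAULT_NUCLEI = ("AN", "VA", "VL", "VM", "MD", "IL", "LP", "PuM", "VP")

#: Nuclei given hub-like evoked amplitude and dense outgoing weights.
DEFAULT_HUBS = ("AN", "MD", "VL", "PuM")

CONDITIONS = ("EDS", "IDS", "Stay")

FIR_KNOTS = np.arange(9) * TR  # 0 .. 14.4 s post cue


def double_gamma_hrf(t: np.ndarray, undershoot_gain: float = 1.0) -> np.ndarray:
    """Canonical double-gamma HRF with a scalable undershoot.

    ``undershoot_gain`` multiplies the depth of the post-peak undershoot;
    values > 1 emulate the deep undershoots seen in medial/posterior nuclei.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    peak = gamma.pdf(t, 6)
    under = gamma.pdf(t, 16)
    h = peak - undershoot_gain * under / 6.0
    return h / np.max(np.abs(peak))


def hrf_on_knots(undershoot_gain: float = 1.0, knots: np.ndarray = FIR_KNOTS) -> np.ndarray:
    """The HRF sampled on the FIR knot grid (the generative shape)."""
    return double_gamma_hrf(knots, undershoot_gain)


def deep_undershoot_preset(nuclei: Sequence[str] = DEFAULT_NUCLEI) -> dict[str, float]:
    """Undershoot gains with deepened undershoot in medial/posterior nuclei."""
    deep = {"MD", "PuM", "VP", "LP"}
    return {n: (3.0 if n in deep else 1.0) for n in nuclei}


def _grid_coords(n: int, origin: float = 0.0) -> np.ndarray:
    """Integer coordinates filling a near-cubic grid (row-major)."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    coords = np.stack(np.meshgrid(*([np.arange(side)] * 3), indexing="ij"), axis=-1)
    return coords.reshape(-1, 3)[:n].astype(float) + origin


@dataclass
class SyntheticBrain:
    """Ground-truth generative model: atlas, weights, evoked patterns, HRFs."""

    seed_coords: np.ndarray          # (V, 3) grid coordinates
    seed_labels: np.ndarray          # (V,) nucleus name per seed voxel
    target_coords: np.ndarray        # (P, 3)
    weights: np.ndarray              # (V, P) ground-truth propagation W*
    evoked_seed: dict[str, np.ndarray]    # condition -> (V,) amplitudes O*
    evoked_cortex: dict[str, np.ndarray]  # condition -> (P,) own cortical evoked
    undershoot_gain: np.ndarray      # (V,) per-voxel HRF undershoot gain
    latent_loadings: np.ndarray      # (V, K) background latent loadings
    private_background_sd: float = 0.5
    nuclei: tuple[str, ...] = DEFAULT_NUCLEI
    hub_nuclei: tuple[str, ...] = DEFAULT_HUBS
    noise_sd: float = 1.0            # default measurement noise level

    @property
    def n_seed(self) -> int:
        return self.seed_coords.shape[0]

    @property
    def n_targets(self) -> int:
        return self.target_coords.shape[0]

    def hub_mask(self) -> np.ndarray:
        return np.isin(self.seed_labels, list(self.hub_nuclei))


def make_brain(
    n_seed: int = 200,
    n_targets: int = 100,
    nuclei: Sequence[str] = DEFAULT_NUCLEI,
    hub_profile: Mapping[str, float] | None = None,
    seed: int = 0,
    n_latents: int = 10,
    undershoot_gains: Mapping[str, float] | None = None,
    cortical_evoked_sd: float = 0.0,
    hub_weight_scale: float = 1.0,
    base_weight_scale: float = 0.3,
) -> SyntheticBrain:
    """Build a ground-truth brain with hub nuclei.

    ``hub_profile`` maps nucleus names to an evoked-amplitude gain for the
    context-switch (EDS) condition; listed nuclei also receive dense,
    larger-scale rows of ``W*``. By default the hubs are AN, MD, VL and PuM
    with gain 4. ``cortical_evoked_sd`` adds evoked responses intrinsic to
    cortical targets on top of the propagated seed signal (0 keeps cortical
    patterns exactly ``W*^T O*``).
    """
    if n_seed < len(nuclei):
        raise ValidationError("need at least one voxel per nucleus")
    rng = np.random.default_rng(seed)
    hub_profile = dict(hub_profile) if hub_profile is not None else {n: 4.0 for n in DEFAULT_HUBS}
    hubs = tuple(n for n in nuclei if n in hub_profile)

    seed_labels = np.array([nuclei[i * len(nuclei) // n_seed] for i in range(n_seed)])
    seed_coords = _grid_coords(n_seed)
    target_coords = _grid_coords(n_targets, origin=100.0)

    hub_mask = np.isin(seed_labels, list(hubs))

    evoked_seed: dict[str, np.ndarray] = {}
    base = {"EDS": 1.0, "IDS": 0.8, "Stay": 0.6}
    for cond in CONDITIONS:
        amp = rng.normal(scale=base[cond], size=n_seed)
        if cond == "EDS":
            gain = np.array([hub_profile.get(lbl, 0.0) for lbl in seed_labels])
            sign = np.sign(amp)
            sign[sign == 0] = 1.0
            # hub voxels: graded amplitudes with magnitude at least the gain
            amp = np.where(
                gain > 0,
                sign * gain * (1.0 + np.abs(rng.normal(size=n_seed))),
                amp,
            )
        evoked_seed[cond] = amp

    # hubness is joint: hub weight-row magnitude scales with hub amplitude
    gain = np.array([hub_profile.get(lbl, 1.0) for lbl in seed_labels])
    scale = np.where(
        hub_mask,
        hub_weight_scale * np.abs(evoked_seed["EDS"]) / np.maximum(gain, 1e-12),
        base_weight_scale,
    )
    weights = rng.normal(size=(n_seed, n_targets)) * scale[:, None] / np.sqrt(n_seed)

    evoked_cortex = {
        cond: weights.T @ evoked_seed[cond]
        + cortical_evoked_sd * rng.normal(size=n_targets)
        for cond in CONDITIONS
    }

    gains = dict(undershoot_gains or {})
    undershoot = np.array([gains.get(lbl, 1.0) for lbl in seed_labels])
    loadings = rng.normal(size=(n_seed, max(n_latents, 0))) / np.sqrt(max(n_latents, 1))
    return SyntheticBrain(
        seed_coords=seed_coords,
        seed_labels=seed_labels,
        target_coords=target_coords,
        weights=weights,
        evoked_seed=evoked_seed,
        evoked_cortex=evoked_cortex,
        undershoot_gain=undershoot,
        latent_loadings=loadings,
        nuclei=tuple(nuclei),
        hub_nuclei=hubs,
    )


@dataclass
class SyntheticDataset:
    """Simulated voxel x time data with its generative brain attached."""

    seed_ts: np.ndarray        # (V, T)
    target_ts: np.ndarray      # (P, T)
    tr: float
    run_frames: list[int]      # frames per run; sum = T
    events: pd.DataFrame       # trial table (run-relative onsets)
    fd: np.ndarray             # (T,) framewise-displacement-like QC series
    nuisance: np.ndarray       # (T, Q) known nuisance regressors
    brain: SyntheticBrain

    @property
    def n_frames(self) -> int:
        return int(sum(self.run_frames))

    def frames_of_run(self, run: int) -> slice:
        """Slice of global frame indices for a 1-based run index."""
        offsets = np.concatenate([[0], np.cumsum(self.run_frames)])
        return slice(int(offsets[run - 1]), int(offsets[run]))


def _tent_interp(tau: np.ndarray, knot_values: np.ndarray) -> np.ndarray:
    """Piecewise-linear response at lags ``tau`` given values on FIR_KNOTS."""
    out = np.interp(tau, FIR_KNOTS, knot_values, left=0.0, right=0.0)
    out[(tau < 0) | (tau > FIR_KNOTS[-1])] = 0.0
    return out


def _evoked_run(
    onsets: np.ndarray,
    conditions: np.ndarray,
    frame_times: np.ndarray,
    amplitudes: Mapping[str, float],
    knot_hrf: np.ndarray,
) -> np.ndarray:
    sig = np.zeros_like(frame_times)
    for onset, cond in zip(onsets, conditions):
        amp = amplitudes.get(cond, amplitudes.get("Stay", 0.0))
        if amp == 0.0:
            continue
        sig += amp * _tent_interp(frame_times - onset, knot_hrf)
    return sig


def simulate_timeseries(
    brain: SyntheticBrain,
    events: pd.DataFrame,
    noise_sd: float | None = None,
    seed: int = 0,
    tr: float = TR,
    background_sd: float = 1.0,
    n_nuisance: int = 6,
    nuisance_sd: float = 0.5,
    fd_spike_rate: float = 0.02,
) -> SyntheticDataset:
    """Simulate seed and cortical target time series from the ground truth.

    Seed series = evoked (condition sticks x nucleus HRF) + low-rank latents
    + private background + nuisance + white noise. Target series =
    ``W*^T (seed evoked + seed background)`` + own cortical evoked +
    nuisance + noise. Unlabeled first trials of each run reuse the Stay
    amplitudes but keep their own condition label for the design matrix.
    """
    if noise_sd is None:
        noise_sd = brain.noise_sd
    rng = np.random.default_rng(seed)
    V, P = brain.n_seed, brain.n_targets
    runs = sorted(events["run"].unique())

    run_frames: list[int] = []
    seed_parts, target_parts = [], []
    # distinct HRF shapes present among seed voxels
    gains = np.unique(brain.undershoot_gain)
    knot_hrfs = {g: hrf_on_knots(g) for g in gains}

    for run in runs:
        ev = events[events["run"] == run]
        t_end = float(ev["probe_onset"].max()) + task.PROBE_DURATION + float(ev["iti"].iloc[-1])
        n_frames = int(np.ceil((t_end + FIR_KNOTS[-1]) / tr)) + 1
        frame_times = np.arange(n_frames) * tr
        run_frames.append(n_frames)

        onsets = ev["onset"].to_numpy(float)
        conds = ev["condition"].to_numpy()

        seed_evoked = np.zeros((V, n_frames))
        for g in gains:
            vox = np.where(brain.undershoot_gain == g)[0]
            for cond in CONDITIONS:
                amps = {cond: 1.0}
                mask = np.isin(conds, [cond]) | (
                    (conds == task.UNLABELED) & (cond == "Stay")
                )
                if not mask.any():
                    continue
                base = _evoked_run(onsets[mask], np.full(mask.sum(), cond),
                                   frame_times, amps, knot_hrfs[g])
                seed_evoked[vox] += np.outer(brain.evoked_seed[cond][vox], base)

        K = brain.latent_loadings.shape[1]
        latents = rng.normal(size=(K, n_frames)) if K else np.zeros((0, n_frames))
        seed_bg = background_sd * (
            brain.latent_loadings @ latents
            + brain.private_background_sd * rng.normal(size=(V, n_frames))
        )

        # cortical own evoked uses the canonical (gain 1) HRF
        target_evoked = np.zeros((P, n_frames))
        h1 = knot_hrfs.get(1.0, hrf_on_knots(1.0))
        for cond in CONDITIONS:
            mask = np.isin(conds, [cond]) | ((conds == task.UNLABELED) & (cond == "Stay"))
            if not mask.any():
                continue
            base = _evoked_run(onsets[mask], np.full(mask.sum(), cond),
                               frame_times, {cond: 1.0}, h1)
            own = brain.evoked_cortex[cond] - brain.weights.T @ brain.evoked_seed[cond]
            target_evoked += np.outer(own, base)

        seed_parts.append((seed_evoked, seed_bg))
        target_parts.append((target_evoked, frame_times))

    T = int(sum(run_frames))
    nuisance = np.cumsum(rng.normal(size=(T, n_nuisance)), axis=0)
    nuisance -= nuisance.mean(axis=0)
    nuisance /= np.maximum(nuisance.std(axis=0), 1e-12)
    seed_nuis_load = nuisance_sd * rng.normal(size=(V, n_nuisance))
    target_nuis_load = nuisance_sd * rng.normal(size=(P, n_nuisance))

    seed_ts = np.empty((V, T))
    target_ts = np.empty((P, T))
    off = 0
    for (seed_evoked, seed_bg), (target_evoked, _), nf in zip(seed_parts, target_parts, run_frames):
        sl = slice(off, off + nf)
        propagated = brain.weights.T @ (seed_evoked + seed_bg)
        seed_ts[:, sl] = seed_evoked + seed_bg
        target_ts[:, sl] = propagated + target_evoked
        off += nf
    seed_ts += seed_nuis_load @ nuisance.T
    target_ts += target_nuis_load @ nuisance.T
    if noise_sd > 0:
        seed_ts += noise_sd * rng.normal(size=seed_ts.shape)
        target_ts += noise_sd * rng.normal(size=target_ts.shape)

    fd = np.abs(rng.normal(scale=0.1, size=T))
    spikes = rng.random(T) < fd_spike_rate
    fd[spikes] += rng.uniform(0.4, 0.8, size=spikes.sum())

    return SyntheticDataset(
        seed_ts=seed_ts,
        target_ts=target_ts,
        tr=tr,
        run_frames=run_frames,
        events=events.reset_index(drop=True),
        fd=fd,
        nuisance=nuisance,
        brain=brain,
    )


def simulate_behavior(
    n_subjects: int = 59,
    effects: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_rt: float = 0.99,
    base_accuracy: float = 0.97,
    subject_sd: float = 0.18,
    within_sd: float = 0.05,
    n_trials: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-subject condition means with planted RT/accuracy effects.

    RT: lognormal with a subject random intercept plus an additive
    condition shift (s). Accuracy: binomial proportion around the shifted
    per-condition probability. Defaults plant the observed ordering
    EDS > IDS > Stay for RT (shifts 0.17/0.08/0 s) and the reverse for
    accuracy (shifts -0.03/-0.02/0), with 102/102/204 trials per condition.
    """
    if effects is None:
        effects = {"EDS": (0.17, -0.03), "IDS": (0.08, -0.02), "Stay": (0.0, 0.0)}
    if n_trials is None:
        n_trials = {"EDS": 102, "IDS": 102, "Stay": 204}
    for cond, (_, acc_shift) in effects.items():
        if not 0.0 < base_accuracy + acc_shift < 1.0:
            raise ValidationError(f"accuracy shift for {cond} leaves (0,1)")
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(1, n_subjects + 1):
        mu = rng.normal(np.log(base_rt), subject_sd)
        for cond, (rt_shift, acc_shift) in effects.items():
            rt = float(np.exp(mu + rng.normal(0.0, within_sd)) + rt_shift)
            n = n_trials.get(cond, 100)
            acc = float(rng.binomial(n, base_accuracy + acc_shift) / n)
            rows.append({"subject": subj, "condition": cond, "rt": rt, "accuracy": acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI / TSV export of a synthetic dataset
# ---------------------------------------------------------------------------

def _volume_shape(brain: SyntheticBrain) -> tuple[int, ...]:
    coords = np.vstack([brain.seed_coords, brain.target_coords]).astype(int)
    return tuple(coords.max(axis=0) + 1)


def write_nifti_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as 4-D NIfTI series + label volumes + TSV sidecars.

    Seed voxels and cortical targets occupy disjoint blocks of one volume
    grid; ``atlas.nii.gz`` labels seed voxels by nucleus index (1-based in
    the order of ``brain.nuclei``) and ``parcels.nii.gz`` labels target
    units 1..P.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    brain = dataset.brain
    shape = _volume_shape(brain)
    T = dataset.n_frames

    series = np.zeros(shape + (T,), dtype=np.float32)
    atlas = np.zeros(shape, dtype=np.int16)
    parcels = np.zeros(shape, dtype=np.int16)
    sc = brain.seed_coords.astype(int)
    tc = brain.target_coords.astype(int)
    series[sc[:, 0], sc[:, 1], sc[:, 2], :] = dataset.seed_ts
    series[tc[:, 0], tc[:, 1], tc[:, 2], :] = dataset.target_ts
    nucleus_index = {n: i + 1 for i, n in enumerate(brain.nuclei)}
    atlas[sc[:, 0], sc[:, 1], sc[:, 2]] = [nucleus_index[l] for l in brain.seed_labels]
    parcels[tc[:, 0], tc[:, 1], tc[:, 2]] = np.arange(1, brain.n_targets + 1)

    affine = np.eye(4)
    paths = {
        "series": outdir / "series.nii.gz",
        "atlas": outdir / "atlas.nii.gz",
        "parcels": outdir / "parcels.nii.gz",
        "events": outdir / "events.tsv",
        "confounds": outdir / "confounds.tsv",
    }
    nib.save(nib.Nifti1Image(series, affine), paths["series"])
    nib.save(nib.Nifti1Image(atlas, affine), paths["atlas"])
    nib.save(nib.Nifti1Image(parcels, affine), paths["parcels"])
    task.write_events(dataset.events, paths["events"])
    conf = pd.DataFrame(dataset.nuisance, columns=[f"nuisance_{i}" for i in range(dataset.nuisance.shape[1])])
    conf["framewise_displacement"] = dataset.fd
    conf.to_csv(paths["confounds"], sep="\t", index=False)
    return paths


def read_nifti_bundle(paths: Mapping[str, str | Path]) -> dict:
    """Read back a bundle written by :func:`write_nifti_bundle` into arrays."""
    import nibabel as nib

    series = np.asarray(nib.load(str(paths["series"])).dataobj)
    atlas = np.asarray(nib.load(str(paths["atlas"])).dataobj)
    parcels = np.asarray(nib.load(str(paths["parcels"])).dataobj)
    events = task.read_events(paths["events"])
    conf = pd.read_csv(paths["confounds"], sep="\t")
    seed_idx = np.argwhere(atlas > 0)
    target_idx = np.argwhere(parcels > 0)
    order = np.argsort(parcels[tuple(target_idx.T)])
    target_idx = target_idx[order]
    return {
        "seed_ts": series[tuple(seed_idx.T)],
        "target_ts": series[tuple(target_idx.T)],
        "seed_labels": atlas[tuple(seed_idx.T)],
        "events": events,
        "confounds": conf,
    }
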