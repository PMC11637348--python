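"""FIR design construction, OLS identities, censoring, LSS, clustering."""

import numpy as np
import pandas as pd
import pytest

from thalamoflow import glm, synth
from thalamoflow.exceptions import EstimationError, QCWarning, ValidationError


def _event(run, onset, condition="A"):
    return {"run": run, "onset": onset, "condition": condition}


def events_df(rows):
    return pd.DataFrame(rows)


@pytest.fixture()
def spec():
    return glm.DesignSpec()


class TestBuildFirDesign:
    def test_knot_aligned_event_gives_stick_pattern(self, spec):
        ev = events_df([_event(1, 0.0)])
        X = glm.build_fir_design(ev, spec, run_frames=[20])
        for j in range(9):
            col = X[f"A@k{j}"].to_numpy()
            expected = np.zeros(20)
            expected[j] = 1.0  # frame j is exactly knot j for a 0-onset event
            assert np.allclose(col, expected)

    def test_no_events_only_baseline(self, spec):
        ev = events_df([]).reindex(columns=["run", "onset", "condition"])
        X = glm.build_fir_design(ev, spec, run_frames=[10])
        assert all(":drift" in c for c in X.columns)

    def test_nonoverlapping_events_recover_per_event_response(self, spec, rng):
        ev = events_df([_event(1, 0.0), _event(1, 36.0)])  # > 14.4 s apart
        X = glm.build_fir_design(ev, spec, run_frames=[40])
        resp = rng.normal(size=9)
        y = np.zeros(40)
        for onset_frame in (0, 20):
            y[onset_frame:onset_frame + 9] += resp
        fit = glm.fit_glm(y[None, :], X)
        got = fit.betas[[f"A@k{j}" for j in range(9)]].to_numpy().ravel()
        assert np.allclose(got, resp, atol=1e-8)

    def test_out_of_bounds_onset_rejected(self, spec):
        ev = events_df([_event(1, 100.0)])
        with pytest.raises(ValidationError):
            glm.build_fir_design(ev, spec, run_frames=[10])


class TestFitGlm:
    def test_noiseless_recovery_exact(self, spec, rng):
        ev = events_df([_event(1, t, c) for t, c in
                        [(0.0, "A"), (10.8, "B"), (27.0, "A"), (45.0, "B")]])
        X = glm.build_fir_design(ev, spec, run_frames=[40])
        b_true = rng.normal(size=X.shape[1])
        Y = (X.to_numpy() @ b_true)[None, :]
        fit = glm.fit_glm(Y, X)
        assert np.allclose(fit.betas.to_numpy().ravel(), b_true, atol=1e-9)
        # residuals orthogonal to the design on retained frames
        assert np.max(np.abs(X.to_numpy().T @ fit.residuals.ravel())) < 1e-8

    def test_censoring_equals_frame_deletion(self, spec, rng):
        ev = events_df([_event(1, 0.0), _event(1, 18.0)])
        X = glm.build_fir_design(ev, spec, run_frames=[30])
        y = X.to_numpy() @ rng.normal(size=X.shape[1]) + 0.1 * rng.normal(size=30)
        spiky = y.copy()
        censor = np.zeros(30, dtype=bool)
        censor[[5, 17]] = True
        spiky[censor] += 50.0
        fit_censored = glm.fit_glm(spiky[None, :], X, censor=censor)
        # oracle: physically delete the frames and refit
        keep = ~censor
        oracle = np.linalg.lstsq(X.to_numpy()[keep], y[keep], rcond=None)[0]
        assert np.allclose(fit_censored.betas.to_numpy().ravel(), oracle, atol=1e-9)

    def test_duplicated_nuisance_raises_named_error(self, spec, rng):
        ev = events_df([_event(1, 0.0)])
        X = glm.build_fir_design(ev, spec, run_frames=[30])
        nuis = rng.normal(size=(30, 1))
        nuis = np.hstack([nuis, nuis])  # duplicate column
        with pytest.raises(EstimationError, match="nuisance"):
            glm.fit_glm(rng.normal(size=(1, 30)), X, nuisance=nuis)

    def test_excess_censoring_warns(self, spec, rng):
        ev = events_df([_event(1, 0.0)])
        X = glm.build_fir_design(ev, spec, run_frames=[60])
        censor = np.zeros(60, dtype=bool)
        censor[20:42] = True  # 36.7% of frames, away from the event response
        with pytest.warns(QCWarning):
            glm.fit_glm(rng.normal(size=(2, 60)), X, censor=censor)


class TestLssTrialBetas:
    def test_equals_per_trial_ls_when_nonoverlapping(self, spec, rng):
        onsets = [0.0, 40.0, 80.0]
        ev = events_df([_event(1, t) for t in onsets])
        amps = np.array([1.5, -2.0, 0.7])
        nf = 70
        t_frames = np.arange(nf) * spec.tr
        h = synth.hrf_on_knots(1.0)
        y = np.zeros(nf)
        cols = []
        for onset, a in zip(onsets, amps):
            tau = t_frames - onset
            c = np.interp(tau, synth.FIR_KNOTS, h, left=0, right=0)
            c[(tau < 0) | (tau > synth.FIR_KNOTS[-1])] = 0
            cols.append(c)
            y += a * c
        betas = glm.lss_trial_betas(y[None, :], ev, spec, run_frames=[nf],
                                    include_baseline=False)
        # oracle: single-trial least squares, one trial at a time; exact
        # because non-overlapping trial regressors have disjoint support
        for k, c in enumerate(cols):
            oracle = float(c @ y / (c @ c))
            assert np.isclose(betas[k, 0], oracle, atol=1e-8)
        assert np.allclose(betas[:, 0], amps, atol=1e-8)

    def test_overlapping_trials_recovered_noiseless(self, spec):
        """Overlapping trials generated from the LSS model itself (target
        amplitude + common amplitude for the rest) are recovered exactly."""
        rng = np.random.default_rng(3)
        onsets = np.cumsum(rng.uniform(3.6, 6.0, size=8))
        ev = events_df([_event(1, float(t)) for t in onsets])
        nf = int(onsets[-1] / spec.tr) + 12
        t_frames = np.arange(nf) * spec.tr
        h = synth.hrf_on_knots(1.0)
        cols = []
        for onset in onsets:
            tau = t_frames - onset
            c = np.interp(tau, synth.FIR_KNOTS, h, left=0, right=0)
            c[(tau < 0) | (tau > synth.FIR_KNOTS[-1])] = 0
            cols.append(c)
        cols = np.array(cols)
        target, common = 3, 0.5
        a_target = 2.0
        y = a_target * cols[target] + common * (cols.sum(axis=0) - cols[target])
        betas = glm.lss_trial_betas(y[None, :], ev, spec, run_frames=[nf])
        assert np.isclose(betas[target, 0], a_target, atol=1e-6)
        # all-equal amplitudes: every trial's beta is exact
        y_eq = 1.3 * cols.sum(axis=0)
        betas_eq = glm.lss_trial_betas(y_eq[None, :], ev, spec, run_frames=[nf])
        assert np.allclose(betas_eq[:, 0], 1.3, atol=1e-6)

    def test_zero_series_zero_betas(self, spec):
        ev = events_df([_event(1, 0.0), _event(1, 9.0)])
        betas = glm.lss_trial_betas(np.zeros((3, 30)), ev, spec, run_frames=[30])
        assert np.allclose(betas, 0.0)

    def test_single_trial_warns(self, spec):
        ev = events_df([_event(1, 0.0)])
        with pytest.warns(UserWarning, match="single trial"):
            glm.lss_trial_betas(np.zeros((1, 20)), ev, spec, run_frames=[20])


class TestConditionEvoked:
    def _fit(self, knot_values):
        betas = pd.DataFrame([np.concatenate([knot_values, [0.0]])],
                             columns=[f"A@k{j}" for j in range(9)] + ["run1:drift0"])
        return glm.GLMResult(betas=betas, residuals=np.zeros((1, 1)),
                             censor_mask=np.zeros(1, bool))

    def test_constant_knots_mean_is_constant(self):
        fit = self._fit(np.full(9, 2.5))
        assert glm.condition_evoked(fit, "A").values[0] == pytest.approx(2.5)

    def test_peak_vs_mean_differ_on_asymmetric_profile(self):
        prof = np.array([0, 1, 5, 1, 0, -1, -1, 0, 0.0])
        fit = self._fit(prof)
        mean = glm.condition_evoked(fit, "A", "mean").values[0]
        peak = glm.condition_evoked(fit, "A", "peak").values[0]
        area = glm.condition_evoked(fit, "A", "area").values[0]
        assert peak == pytest.approx(5.0)
        assert mean == pytest.approx(prof.mean())
        assert area == pytest.approx(prof.sum())
        assert peak != mean

    def test_linear_in_betas(self, rng):
        prof = rng.normal(size=9)
        v1 = glm.condition_evoked(self._fit(prof), "A").values[0]
        v2 = glm.condition_evoked(self._fit(3.0 * prof), "A").values[0]
        assert v2 == pytest.approx(3.0 * v1)

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError):
            glm.condition_evoked(self._fit(np.zeros(9)), "missing")


class TestGroupContrast:
    def test_identical_conditions_give_zero_t(self, rng):
        e = [rng.normal(size=10) for _ in range(6)]
        t, df = glm.group_contrast(e, e)
        assert np.allclose(t, 0.0)
        assert df == 5

    def test_antisymmetry(self, rng):
        a = [rng.normal(size=8) for _ in range(5)]
        b = [rng.normal(size=8) for _ in range(5)]
        t_ab, _ = glm.group_contrast(a, b)
        t_ba, _ = glm.group_contrast(b, a)
        assert np.allclose(t_ab, -t_ba)

    def test_planted_hub_effect_detected(self):
        rng = np.random.default_rng(0)
        n_sub, V = 30, 50
        hub = np.zeros(V, bool)
        hub[:10] = True
        eds = [rng.normal(size=V) + 1.5 * hub for _ in range(n_sub)]
        stay = [rng.normal(size=V) for _ in range(n_sub)]
        t, df = glm.group_contrast(eds, stay)
        from scipy import stats
        crit = stats.t.ppf(0.999, df)
        assert (t[hub] > crit).mean() > 0.8
        assert (t[~hub] > crit).mean() < 0.2


class TestClusterThreshold:
    def _volume_with_cube(self, corner, size, value=10.0, shape=(12, 12, 12)):
        vol = np.zeros(shape)
        x, y, z = corner
        vol[x:x + size, y:y + size, z:z + size] = value
        return vol

    def test_min_size_arithmetic(self):
        vol = self._volume_with_cube((0, 0, 0), 4)  # 64 voxels
        _, table = glm.cluster_threshold(vol, voxel_p=0.05, min_size=58, df=30)
        assert len(table) == 1 and table["size"].iloc[0] == 64
        vol = self._volume_with_cube((0, 0, 0), 3)  # 27 voxels
        _, table = glm.cluster_threshold(vol, voxel_p=0.05, min_size=58, df=30)
        assert table.empty

    def test_corner_touching_cubes_are_separate(self):
        vol = self._volume_with_cube((0, 0, 0), 3)
        vol += self._volume_with_cube((3, 3, 3), 3)
        labeled, table = glm.cluster_threshold(vol, voxel_p=0.05, min_size=1, df=30)
        assert len(table) == 2

    def test_noise_maps_rarely_survive(self):
        rng = np.random.default_rng(1)
        survived = 0
        for _ in range(60):
            t_map = rng.standard_t(df=30, size=(12, 12, 12))
            _, table = glm.cluster_threshold(t_map, voxel_p=0.05, min_size=58, df=30)
            survived += len(table) > 0
        assert survived == 0
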