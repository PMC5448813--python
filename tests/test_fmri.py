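"""Model-based fMRI designs, GLM fitting and voxel-wise model comparison."""

import numpy as np
import pytest

from bistablepc import fmri
from bistablepc.cohort import build_session, simulate_subject
from bistablepc.exceptions import DataError, InvalidParameterError
from bistablepc.model import AMBIGUOUS, ModelParams, filter_responses


@pytest.fixture(scope="module")
def subject_trajectory():
    session = build_session(0.30, runs=1, pairs_per_run=4)
    params = ModelParams(3.5, 5.0)
    responses, filled = simulate_subject(params, session, seed=17)
    traj = filter_responses(responses, filled, params)
    return filled, traj


@pytest.fixture(scope="module")
def designs(subject_trajectory):
    session, traj = subject_trajectory
    return {
        kind: fmri.build_design(fmri.build_events(session, traj, kind), tr=2.0)
        for kind in fmri.MODEL_KINDS
    }


class TestBuildEvents:
    def test_pe_modulator_covers_every_overlap(self, subject_trajectory):
        session, traj = subject_trajectory
        ev = fmri.build_events(session, traj, "PE")
        run = ev.runs[0]
        onsets, values = run.modulators["overlaps_x_pe"]
        assert len(onsets) == len(traj)
        assert np.all(values >= 0)

    def test_block_modulator_is_condition_indicator(self, subject_trajectory):
        session, traj = subject_trajectory
        ev = fmri.build_events(session, traj, "Block")
        _, values = ev.runs[0].modulators["overlaps_x_ambiguous"]
        expected = (traj["condition"] == AMBIGUOUS).to_numpy(dtype=float)
        np.testing.assert_array_equal(values, expected)

    def test_conventional_sticks_partition_transitions(self, subject_trajectory):
        session, traj = subject_trajectory
        conv = fmri.build_events(session, traj, "Conventional")
        pe = fmri.build_events(session, traj, "PE")
        split = np.sort(
            np.concatenate(
                [
                    conv.runs[0].onsets["transitions_ambiguous"],
                    conv.runs[0].onsets["transitions_replay"],
                ]
            )
        )
        np.testing.assert_array_equal(split, np.sort(pe.runs[0].onsets["transitions"]))

    def test_unknown_kind(self, subject_trajectory):
        session, traj = subject_trajectory
        with pytest.raises(InvalidParameterError):
            fmri.build_events(session, traj, "GLM7")


class TestHrfKernel:
    def test_shape_contract(self):
        k = fmri.hrf_kernel(0.125)
        assert k.max() == pytest.approx(1.0)
        assert k.min() < 0  # undershoot lobe
        assert k.sum() * 0.125 > 0  # net positive response

    def test_peak_near_five_seconds(self):
        dt = 0.01
        k = fmri.hrf_kernel(dt)
        assert np.argmax(k) * dt == pytest.approx(5.0, abs=0.1)

    def test_resampling_invariance(self):
        k1 = fmri.hrf_kernel(0.25)
        k2 = fmri.hrf_kernel(0.125)
        np.testing.assert_allclose(k2[::2], k1, atol=1e-6)

    def test_matches_reference_canonical_hrf(self):
        """Shape agrees with nilearn's canonical double-gamma (up to its
        sum-normalisation convention)."""
        from nilearn.glm.first_level import spm_hrf

        tr = 1.0
        ours = fmri.hrf_kernel(tr / 16)
        ref = spm_hrf(tr, oversampling=16, time_length=32 + tr / 16)
        n = min(len(ours), len(ref))
        np.testing.assert_allclose(
            ours[:n] / np.linalg.norm(ours[:n]),
            ref[:n] / np.linalg.norm(ref[:n]),
            atol=5e-3,
        )


class TestBuildDesign:
    def test_single_stick_reproduces_kernel(self):
        ev = fmri.EventList(
            "PE",
            [fmri.RunEvents(1, 80.0, {"overlaps": np.array([0.0]), "transitions": np.array([])})],
        )
        dm = fmri.build_design(ev, tr=2.0, oversample=16)
        col = dm.X[:, dm.names.index("overlaps")]
        kernel = fmri.hrf_kernel(2.0 / 16)
        np.testing.assert_allclose(col[:16], kernel[::16][:16], atol=1e-12)

    def test_two_far_sticks_superpose(self):
        ev1 = fmri.EventList(
            "PE", [fmri.RunEvents(1, 160.0, {"overlaps": np.array([0.0, 80.0])})]
        )
        ev2 = fmri.EventList(
            "PE", [fmri.RunEvents(1, 160.0, {"overlaps": np.array([0.0])})]
        )
        ev3 = fmri.EventList(
            "PE", [fmri.RunEvents(1, 160.0, {"overlaps": np.array([80.0])})]
        )
        d1 = fmri.build_design(ev1, tr=2.0)
        d2 = fmri.build_design(ev2, tr=2.0)
        d3 = fmri.build_design(ev3, tr=2.0)
        np.testing.assert_allclose(
            d1.X[:, 0], d2.X[:, 0] + d3.X[:, 0], atol=1e-12
        )

    def test_constant_modulator_centres_to_zero(self):
        onsets = np.arange(0.0, 60.0, 3.0)
        ev = fmri.EventList(
            "Block",
            [
                fmri.RunEvents(
                    1,
                    80.0,
                    {"overlaps": onsets},
                    {"overlaps_x_ambiguous": (onsets, np.ones_like(onsets))},
                )
            ],
        )
        dm = fmri.build_design(ev, tr=2.0)
        col = dm.X[:, dm.names.index("overlaps_x_ambiguous")]
        np.testing.assert_allclose(col, 0.0, atol=1e-12)


class TestHighpass:
    def test_projection_idempotent(self, designs):
        dm = designs["PE"]
        once = fmri.highpass_project(dm.X, dm.dct)
        twice = fmri.highpass_project(once, dm.dct)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_slow_drift_removed(self, designs):
        dm = designs["PE"]
        t = np.arange(dm.n_scans) * dm.tr
        # components inside the drift basis vanish to machine precision
        basis_col = dm.dct[:, 2]
        resid = fmri.highpass_project(basis_col[:, None], dm.dct)
        assert np.abs(resid).max() < 1e-12
        # a generic slow confound (linear trend) is strongly attenuated
        lin = (t / t.max())[:, None]
        resid = fmri.highpass_project(lin, dm.dct)
        assert resid.var() < 1e-3 * lin.var()


class TestGlmContrast:
    def test_recovers_betas_without_noise(self, designs):
        dm = designs["PE"]
        beta = fmri.default_generating_betas(dm)
        Y = fmri.simulate_bold(dm, beta, noise_sd=0.0, n_voxels=3)
        est, _ = fmri.glm_contrast(Y, dm, np.eye(dm.X.shape[1])[dm.names.index("overlaps_x_pe")])
        assert np.allclose(est[:, dm.names.index("overlaps_x_pe")], 1.0, atol=1e-8)

    def test_beta_estimates_match_closed_form_distribution(self, designs, rng):
        """With unit noise, OLS contrast variance follows c'(X'X)^-1 c."""
        dm = designs["PE"]
        idx = dm.names.index("overlaps_x_pe")
        contrast = np.eye(dm.X.shape[1])[idx]
        Y = rng.normal(size=(400, dm.n_scans))
        betas, t = fmri.glm_contrast(Y, dm, contrast)
        # null t-values: roughly standard normal
        assert abs(np.mean(t)) < 0.15
        assert np.std(t) == pytest.approx(1.0, abs=0.12)
        frac = np.mean(np.abs(t) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.035)

    def test_null_contrast_centred_at_zero(self, designs, rng):
        dm = designs["Conventional"]
        i = dm.names.index("transitions_ambiguous")
        j = dm.names.index("transitions_replay")
        beta = np.zeros(dm.X.shape[1])
        beta[i] = beta[j] = 1.0
        Y = fmri.simulate_bold(dm, beta, noise_sd=1.0, n_voxels=300, seed=8)
        contrast = np.zeros(dm.X.shape[1])
        contrast[i], contrast[j] = 1.0, -1.0
        _, t = fmri.glm_contrast(Y, dm, contrast)
        assert abs(np.mean(t)) < 0.2

    def test_duplicated_regressor_raises(self, designs):
        dm = designs["PE"]
        X = np.hstack([dm.X, dm.X[:, [0]]])
        bad = fmri.DesignMatrix(
            X, dm.names + ["overlaps_copy"], dm.tr, dm.run_index, dm.dct
        )
        with pytest.raises(DataError, match="collinear"):
            fmri.glm_contrast(
                np.zeros((2, dm.n_scans)), bad, np.eye(X.shape[1])[0]
            )


class TestVoxelEvidence:
    def test_matches_quadrature_on_two_regressor_toy(self, rng):
        """Closed-form marginal likelihood equals brute-force integration
        over the weights on a small problem."""
        n = 24
        X = rng.normal(size=(n, 2))
        X /= np.linalg.norm(X, axis=0)
        y = rng.normal(size=n)
        y /= y.std()
        dm = fmri.DesignMatrix(
            X, ["a", "b"], 2.0, np.zeros(n, dtype=int), np.zeros((n, 0))
        )
        got = fmri.voxel_evidence(y[None, :], dm)[0]
        # quadrature over w1, w2 ~ N(0, 1)
        w = np.linspace(-8, 8, 401)
        W1, W2 = np.meshgrid(w, w)
        log_lik = np.zeros_like(W1)
        for i, xi in enumerate(X):
            resid = y[i] - W1 * xi[0] - W2 * xi[1]
            log_lik += -0.5 * (resid**2 + np.log(2 * np.pi))
        log_prior = -0.5 * (W1**2 + W2**2) - np.log(2 * np.pi)
        integrand = np.exp(log_lik + log_prior)
        z = np.trapezoid(np.trapezoid(integrand, w, axis=1), w)
        assert got == pytest.approx(np.log(z), abs=1e-3)

    def test_zero_data_ties_same_width_models(self, designs):
        Y = np.zeros((2, designs["PE"].n_scans))
        e1 = fmri.voxel_evidence(Y, designs["PE"])
        e2 = fmri.voxel_evidence(Y, designs["Block"])
        # all-zero voxels are standardised identically; only the design
        # volume term differs, and both designs have equal width
        assert e1 == pytest.approx(e2, abs=2.0)

    def test_occam_prefers_generating_nested_model(self, rng):
        n = 200
        X_small = rng.normal(size=(n, 1))
        X_big = np.hstack([X_small, rng.normal(size=(n, 3))])
        dm_small = fmri.DesignMatrix(
            X_small, ["x0"], 2.0, np.zeros(n, dtype=int), np.zeros((n, 0))
        )
        dm_big = fmri.DesignMatrix(
            X_big, ["x0", "x1", "x2", "x3"], 2.0, np.zeros(n, dtype=int),
            np.zeros((n, 0)),
        )
        Y = (2.0 * X_small[:, 0] + rng.normal(size=(50, n))).reshape(50, n)
        e_small = fmri.voxel_evidence(Y, dm_small)
        e_big = fmri.voxel_evidence(Y, dm_big)
        assert np.mean(e_small - e_big) > 0


class TestGroupEpm:
    def test_unanimous_evidence(self):
        maps = [np.tile([5.0, 0.0, 0.0], (20, 1)) for _ in range(6)]
        res = fmri.group_epm(maps, n_samples=2000, seed=0)
        assert np.all(res["assignment"] == 0)
        assert np.all(res["xp"][:, 0] > 0.9)

    def test_model_permutation_permutes_maps(self):
        rng = np.random.default_rng(2)
        maps = [rng.normal(size=(15, 3)) for _ in range(5)]
        perm = [2, 0, 1]
        a = fmri.group_epm(maps, n_samples=4000, seed=3)
        b = fmri.group_epm([m[:, perm] for m in maps], n_samples=4000, seed=3)
        np.testing.assert_allclose(a["xp"][:, perm], b["xp"], atol=0.06)

    def test_grid_mismatch_raises(self):
        with pytest.raises(DataError):
            fmri.group_epm([np.zeros((5, 3)), np.zeros((6, 3))])


class TestThresholdEpm:
    def test_small_clusters_removed(self):
        xp = np.zeros(50)
        xp[5:30] = 0.999  # 25-voxel cluster survives
        xp[40:45] = 0.999  # 5-voxel cluster removed
        mask = fmri.threshold_epm(xp, gamma=0.99, cluster_size=10)
        assert mask[5:30].all()
        assert not mask[40:45].any()


def test_pre_transition_average_window():
    signal = np.arange(100, dtype=float)  # scans at TR = 2 -> value = t/2
    samples = np.arange(0.0, 200.0, 3.0)
    avg = fmri.pre_transition_average(signal, [60.0, 120.0], samples, 2.0, n_pre=3)
    assert avg.shape == (3,)
    assert np.all(np.diff(avg) > 0)
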