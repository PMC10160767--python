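"""Gaussian-basis design, OLS fitting, short-separation regression."""

import numpy as np
import pytest

import fnirs_skill as fsk
from fnirs_skill.hrf import (
    Design,
    GaussianBasis,
    average_hrf,
    build_design,
    estimate_session_hrf,
    fit_glm,
)

FS = 5.0


class TestBasis:
    def test_default_basis_has_125_functions(self):
        assert GaussianBasis().n_bases == 125

    def test_unit_peak(self):
        basis = GaussianBasis()
        t = np.linspace(-3, 61, 20000)
        B = basis.sample(t)
        np.testing.assert_allclose(B.max(axis=0), 1.0, atol=1e-4)


class TestDesign:
    def test_single_onset_basis_peaks_at_its_mean(self):
        basis = GaussianBasis()
        stim = fsk.StimDesign(onsets=[0.0], durations=[15.0])
        des = build_design(stim, basis, FS, 400)
        k = int(np.argmin(np.abs(basis.means - 6.0)))  # basis with mean 6 s
        assert np.argmax(des.X[:, k]) == round(6.0 * FS)

    def test_two_onsets_superpose(self):
        basis = GaussianBasis()
        one = build_design(fsk.StimDesign(onsets=[10.0], durations=[5.0]), basis, FS, 800)
        other = build_design(fsk.StimDesign(onsets=[80.0], durations=[5.0]), basis, FS, 800)
        both = build_design(
            fsk.StimDesign(onsets=[10.0, 80.0], durations=[5.0, 5.0]), basis, FS, 800
        )
        np.testing.assert_allclose(
            both.X[:, :125], one.X[:, :125] + other.X[:, :125], atol=1e-12
        )

    def test_task_columns_then_drift(self):
        des = build_design(fsk.StimDesign(onsets=[5.0], durations=[5.0]), GaussianBasis(), FS, 200)
        assert des.X.shape[1] == 125 + 2
        assert des.labels[-2:] == ["drift:const", "drift:linear"]

    def test_onset_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            build_design(
                fsk.StimDesign(onsets=[500.0], durations=[5.0]), GaussianBasis(), FS, 100
            )


class TestFitGLM:
    def _design(self, n=600):
        stim = fsk.StimDesign(onsets=[20.0, 70.0], durations=[10.0, 10.0])
        return build_design(stim, GaussianBasis(), FS, n)

    def test_noiseless_ols_identity(self, small_layout):
        des = self._design()
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.3, des.X.shape[1])
        y = des.X @ beta
        data = np.zeros((small_layout.n_channels, 2, des.X.shape[0]))
        data[small_layout.long_indices[0], 0] = y
        rec = fsk.Recording(
            sample_rate=FS, data=data, stage="concentration", layout=small_layout
        )
        est = fit_glm(rec, des, ss_mode=None, chromophores=("HbO",))[0]
        full = np.concatenate([est.beta, est.nuisance_betas])
        np.testing.assert_allclose(full, beta, atol=1e-8)

    def test_betas_match_normal_equations_oracle(self):
        """β̂ equals the brute-force (XᵀX)⁻¹Xᵀy solve on small instances."""
        rng = np.random.default_rng(1)
        layout = fsk.make_layout(n_long=1, n_short=1)
        for _ in range(20):
            X = rng.normal(size=(200, 10))
            y = rng.normal(size=200)
            data = np.zeros((2, 2, 200))
            data[0, 0] = y
            rec = fsk.Recording(
                sample_rate=FS, data=data, stage="concentration", layout=layout
            )
            des = Design(X=X, n_task=8, basis=GaussianBasis(), fs=FS)
            est = fit_glm(rec, des, ss_mode=None, chromophores=("HbO",))[0]
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            full = np.concatenate([est.beta, est.nuisance_betas])
            np.testing.assert_allclose(full, oracle, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, noisy_conc):
        rec, _ = noisy_conc
        des = build_design(rec.stim, GaussianBasis(), FS, rec.n_times)
        est = fit_glm(rec, des, ss_mode="nearest", chromophores=("HbO",))[0]
        shorts = rec.layout.short_indices
        mids = rec.layout.channel_midpoints()
        near = shorts[np.argmin(np.linalg.norm(mids[shorts] - mids[est.channel], axis=1))]
        X = np.hstack([des.X, rec.data[near, 0][:, None]])
        full = np.concatenate([est.beta, est.nuisance_betas])
        resid = rec.data[est.channel, 0] - X @ full
        scale = np.abs(X.T @ rec.data[est.channel, 0]).max()
        assert np.abs(X.T @ resid).max() < 1e-6 * scale

    def test_short_regression_never_increases_residual_variance(self, noisy_conc):
        rec, _ = noisy_conc
        des = build_design(rec.stim, GaussianBasis(), FS, rec.n_times)
        with_ss = fit_glm(rec, des, ss_mode="nearest", chromophores=("HbO",))
        without = fit_glm(rec, des, ss_mode=None, chromophores=("HbO",))
        for a, b in zip(with_ss, without):
            # compare raw SSR (dof differs by the extra column)
            assert a.residual_variance * a.dof <= b.residual_variance * b.dof + 1e-12

    def test_rank_deficient_design_reports_condition(self, small_layout):
        X = np.ones((100, 3))
        X[:, 1] = np.linspace(0, 1, 100)
        X[:, 2] = 2 * X[:, 1]  # exact collinearity
        des = Design(X=X, n_task=1, basis=GaussianBasis(), fs=FS)
        data = np.random.default_rng(0).normal(size=(small_layout.n_channels, 2, 100))
        rec = fsk.Recording(
            sample_rate=FS, data=data, stage="concentration", layout=small_layout
        )
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            fit_glm(rec, des, ss_mode=None, chromophores=("HbO",))

    def test_ss_requested_without_short_channels(self, block_stim):
        layout = fsk.make_layout(n_long=2, n_short=0)
        data = np.zeros((2, 2, 600))
        rec = fsk.Recording(
            sample_rate=FS, data=data, stage="concentration", layout=layout
        )
        des = self._design()
        with pytest.raises(ValueError, match="no short"):
            fit_glm(rec, des, ss_mode="nearest")

    def test_superficial_suppression_on_null_channel(self, small_layout, block_stim):
        """With gain-1 scalp contamination and no task response, nearest-short
        regression shrinks the windowed |effect| at least 5-fold."""
        import fnirs_skill.stats as st

        effs = {None: [], "nearest": []}
        for seed in range(4):
            truth = fsk.SimulationTruth(
                hrf_amplitude=0.0, superficial_gain=1.0, seed=100 + seed
            )
            rec, _ = fsk.simulate_hemodynamics(
                truth, block_stim, small_layout, 520.0, FS
            )
            des = build_design(block_stim, GaussianBasis(), FS, rec.n_times)
            for mode in effs:
                for e in fit_glm(rec, des, ss_mode=mode, chromophores=("HbO",)):
                    effs[mode].append(abs(st.window_effect(e)))
        assert np.mean(effs[None]) > 5 * np.mean(effs["nearest"])


class TestAverageHRF:
    def _estimate(self, hrf, subject="s1", day=1, n=1):
        from fnirs_skill.hrf import HRFEstimate

        basis = GaussianBasis()
        grid = basis.grid(FS)
        return HRFEstimate(
            channel=0, chromophore="HbO", beta=np.zeros(basis.n_bases),
            hrf=hrf, t_grid=grid, residual_variance=1.0, dof=10,
            nuisance_betas=np.zeros(0), n=n,
            meta={"subject": subject, "day": day},
        )

    def test_single_estimate_is_identity(self):
        grid = GaussianBasis().grid(FS)
        est = self._estimate(np.sin(grid))
        (avg,) = average_hrf([est])
        np.testing.assert_allclose(avg.hrf, est.hrf)
        assert avg.n == 1

    def test_opposite_estimates_cancel(self):
        grid = GaussianBasis().grid(FS)
        h = np.sin(grid)
        avg = average_hrf([self._estimate(h), self._estimate(-h)])
        assert len(avg) == 1
        np.testing.assert_allclose(avg[0].hrf, 0.0, atol=1e-14)
        assert avg[0].n == 2

    def test_grouping_by_subject_day(self):
        grid = GaussianBasis().grid(FS)
        ests = [
            self._estimate(np.ones_like(grid), "s1", 1),
            self._estimate(3 * np.ones_like(grid), "s1", 1),
            self._estimate(np.zeros_like(grid), "s1", 2),
        ]
        avg = {(e.meta["subject"], e.meta["day"]): e for e in average_hrf(ests)}
        np.testing.assert_allclose(avg[("s1", 1)].hrf, 2.0)
        np.testing.assert_allclose(avg[("s1", 2)].hrf, 0.0)

    def test_averaging_beats_single_estimates(self):
        """Monte-Carlo: the 50-estimate mean HRF has lower RMSE to truth than
        the median single-estimate RMSE."""
        rng = np.random.default_rng(5)
        grid = GaussianBasis().grid(FS)
        truth = np.exp(-((grid - 6.0) ** 2) / 18.0)
        ests = [self._estimate(truth + 0.5 * rng.standard_normal(grid.size)) for _ in range(50)]
        (avg,) = average_hrf(ests)
        rmse_avg = np.sqrt(((avg.hrf - truth) ** 2).mean())
        rmses = [np.sqrt(((e.hrf - truth) ** 2).mean()) for e in ests]
        assert rmse_avg < np.median(rmses)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            average_hrf([])


class TestSessionFit:
    def test_recovers_amplitude_from_clean_recording(self, clean_conc):
        rec, comps = clean_conc
        ests = estimate_session_hrf(rec, ss_mode=None, chromophores=("HbO",))
        for e in ests:
            window = (e.t_grid >= 0) & (e.t_grid <= 20)
            assert e.hrf[window].max() == pytest.approx(1.0, abs=0.02)

    def test_requires_stimulus(self, small_layout):
        rec = fsk.Recording(
            sample_rate=FS,
            data=np.zeros((small_layout.n_channels, 2, 100)),
            stage="concentration",
            layout=small_layout,
        )
        with pytest.raises(ValueError, match="stimulus"):
            estimate_session_hrf(rec)
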