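"""Windowed effects and channel-level activation inference."""

import numpy as np
import pandas as pd
import pytest

import fnirs_skill as fsk
from fnirs_skill.hrf import GaussianBasis, HRFEstimate
from fnirs_skill.stats import (
    day_vs_baseline,
    group_contrast,
    paired_day_contrast,
    split_by_performance,
    window_effect,
)

FS = 5.0


def _est(hrf, channel=0):
    basis = GaussianBasis()
    grid = basis.grid(FS)
    return HRFEstimate(
        channel=channel, chromophore="HbO", beta=np.zeros(basis.n_bases),
        hrf=np.asarray(hrf, dtype=float), t_grid=grid, residual_variance=1.0,
        dof=10, nuisance_betas=np.zeros(0),
    )


def _effects(values_by_channel):
    rows = []
    for ch, values in values_by_channel.items():
        for s, v in enumerate(values):
            rows.append(
                {"subject": f"s{s}", "channel": ch, "chromophore": "HbO", "effect": v}
            )
    return pd.DataFrame(rows)


class TestWindowEffect:
    def test_flat_zero_hrf(self):
        grid = GaussianBasis().grid(FS)
        assert window_effect(_est(np.zeros_like(grid))) == 0.0

    def test_unit_window_zero_baseline(self):
        grid = GaussianBasis().grid(FS)
        hrf = np.where(grid >= 0, 1.0, 0.0)
        assert window_effect(_est(hrf)) == pytest.approx(1.0)

    def test_matches_truth_windowed_mean_on_noiseless_fit(self, clean_conc):
        """The effect of a noiseless fit equals the windowed mean of the
        closed-form convolution truth aligned to one onset."""
        rec, comps = clean_conc
        ests = fsk.estimate_session_hrf(rec, ss_mode=None, chromophores=("HbO",))
        # single-block truth segment on the -2..60 s grid around onset 40 s
        i0 = int(40.0 * FS)
        grid = GaussianBasis().grid(FS)
        seg = comps["waveform"][i0 - 10 : i0 - 10 + grid.size]
        truth_eff = (
            seg[(grid >= 0) & (grid <= 20)].mean()
            - seg[(grid >= -2) & (grid <= 0)].mean()
        )
        for e in ests:
            assert window_effect(e) == pytest.approx(truth_eff, abs=0.02)

    def test_empty_window_rejected(self):
        grid = GaussianBasis().grid(FS)
        with pytest.raises(ValueError, match="empty"):
            window_effect(_est(np.zeros_like(grid)), window=(100.0, 101.0))


class TestDayVsBaseline:
    def test_identical_nonzero_effects_with_jitter_significant(self):
        rng = np.random.default_rng(0)
        eff = _effects({0: 0.5 + 1e-6 * rng.standard_normal(8)})
        (res,) = day_vs_baseline(eff)
        assert res.significant and res.effect == pytest.approx(0.5, abs=1e-5)

    def test_symmetric_effects_give_t0_p1(self):
        (res,) = day_vs_baseline(_effects({0: [-0.4, 0.4, -0.2, 0.2]}))
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged_not_nan(self):
        (res,) = day_vs_baseline(_effects({0: [0.3, 0.3, 0.3]}))
        assert res.degenerate and res.p_value == 0.0 and res.significant

    def test_matches_scipy_on_fixed_vector(self):
        from scipy import stats as sps

        x = np.array([0.1, -0.2, 0.4, 0.3, 0.05, -0.1])
        (res,) = day_vs_baseline(_effects({0: x}))
        t, p = sps.ttest_1samp(x, 0.0)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_null_calibration(self):
        """500 null draws per channel: rejection rate within the binomial
        band around α = 0.05."""
        rng = np.random.default_rng(2)
        rejections = []
        for _ in range(500):
            eff = _effects({0: rng.standard_normal(8)})
            rejections.append(day_vs_baseline(eff)[0].significant)
        assert 0.03 <= np.mean(rejections) <= 0.07

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            day_vs_baseline(_effects({0: [0.1]}))


class TestPairedContrast:
    def test_identical_days_give_t0(self):
        eff = _effects({0: [0.1, 0.2, 0.3]})
        (res,) = paired_day_contrast(eff, eff.copy())
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_swapping_days_negates_t(self):
        rng = np.random.default_rng(3)
        a = _effects({0: rng.standard_normal(10)})
        b = _effects({0: rng.standard_normal(10) + 0.4})
        (fwd,) = paired_day_contrast(a, b)
        (rev,) = paired_day_contrast(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic, abs=1e-10)
        assert fwd.effect == pytest.approx(-rev.effect, abs=1e-12)

    def test_unmatched_subjects_rejected(self):
        a = _effects({0: [0.1, 0.2]})
        b = _effects({0: [0.1, 0.2]})
        b.loc[1, "subject"] = "someone_else"
        with pytest.raises(ValueError, match="unmatched"):
            paired_day_contrast(a, b)

    def test_sign_convention_day15_minus_day1(self):
        a = _effects({0: [0.0, 0.1, -0.1, 0.05]})
        b = _effects({0: [0.5, 0.6, 0.4, 0.55]})
        (res,) = paired_day_contrast(a, b)
        assert res.effect > 0 and res.significant


class TestSplitByPerformance:
    def test_two_subject_split(self):
        above, below = split_by_performance({"a": 400.0, "b": 500.0})
        assert above == ["b"] and below == ["a"]

    def test_cohort_shape_like_emulated_study(self):
        """12 scores in 454-521 and 9 in 312-437 (mean ≈ 439) split 12/9."""
        scores = {}
        for i, v in enumerate(np.linspace(454, 521, 12)):
            scores[f"hi{i}"] = v
        for i, v in enumerate(np.linspace(312, 437, 9)):
            scores[f"lo{i}"] = v
        assert 437 < np.mean(list(scores.values())) < 454
        above, below = split_by_performance(scores)
        assert len(above) == 12 and len(below) == 9

    def test_translation_invariance(self):
        scores = {"a": 320.0, "b": 455.0, "c": 470.0}
        shifted = {k: v + 123.4 for k, v in scores.items()}
        assert split_by_performance(scores) == split_by_performance(shifted)

    def test_tie_goes_above(self):
        above, below = split_by_performance({"a": 400.0, "b": 500.0, "c": 450.0})
        assert "c" in above

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_by_performance({"a": 1.0, "b": 1.0})


class TestGroupContrast:
    def test_identical_groups_give_t0(self):
        g = _effects({0: [0.1, 0.2, 0.3, 0.15]})
        (res,) = group_contrast(g, g.copy())
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_matches_welch_oracle(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        a = rng.standard_normal(8)
        b = 0.5 + 2.0 * rng.standard_normal(12)
        (res,) = group_contrast(_effects({0: a}), _effects({0: b}))
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        rej = [
            group_contrast(
                _effects({0: rng.standard_normal(8)}),
                _effects({0: rng.standard_normal(8)}),
            )[0].significant
            for _ in range(400)
        ]
        assert 0.02 <= np.mean(rej) <= 0.08

    def test_boosted_group_detected_positive(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            a = 0.8 + 0.2 * rng.standard_normal(10)
            b = 0.2 * rng.standard_normal(10)
            (res,) = group_contrast(_effects({0: a}), _effects({0: b}))
            hits += res.significant and res.effect > 0
        assert hits >= 15  # majority of replicates


class TestPermutationEquivariance:
    def test_channel_permutation_permutes_results(self):
        rng = np.random.default_rng(7)
        vals = {ch: rng.standard_normal(6) + 0.2 * ch for ch in range(4)}
        res = {r.channel: r for r in day_vs_baseline(_effects(vals))}
        permuted = {ch: vals[ch] for ch in [2, 0, 3, 1]}
        res_p = {r.channel: r for r in day_vs_baseline(_effects(permuted))}
        for ch in range(4):
            assert res[ch].t_statistic == pytest.approx(
                res_p[ch].t_statistic, abs=1e-12
            )


def test_rm_anova_runs_on_tidy_scores():
    rng = np.random.default_rng(8)
    rows = []
    for s in range(6):
        base = rng.normal(50, 10)
        for period, shift in [("day1", 0.0), ("day15", 390.0), ("retention", 370.0)]:
            rows.append(
                {"subject": s, "period": period, "score": base + shift + rng.normal(0, 5)}
            )
    table = fsk.rm_anova_scores(pd.DataFrame(rows))
    assert table.loc["period", "Pr > F"] < 0.001
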