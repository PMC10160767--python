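"""Channel-level activation statistics and learner-subgroup contrasts.

Inference uses the first 20 s of the estimated HRF: the per-subject
effect is the mean HRF over a 0–20 s window minus the mean over a −2–0 s
pre-onset baseline.  Channels are tested with textbook t-tests — one
sample against zero (day vs baseline), paired (day 15 vs day 1) and
Welch two-sample (good vs weak learners) — each two-sided at α = 0.05 by
default and uncorrected across channels; Benjamini–Hochberg is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrf import HRFEstimate

DEFAULT_ALPHA = 0.05
EFFECT_WINDOW = (0.0, 20.0)
BASELINE_WINDOW = (-2.0, 0.0)


@dataclass(frozen=True)
class ActivationResult:
    channel: int
    chromophore: str
    contrast: str
    effect: float  # mean windowed ΔHbO (μM)
    t_statistic: float
    p_value: float
    n: int
    significant: bool
    degenerate: bool = False


def window_effect(
    est: HRFEstimate,
    window: tuple[float, float] = EFFECT_WINDOW,
    baseline: tuple[float, float] = BASELINE_WINDOW,
) -> float:
    """Mean HRF over ``window`` minus mean over ``baseline`` (μM).

    The window is closed, the baseline half-open ([−2, 0)), so the onset
    sample belongs to the response, not the baseline.
    """
    t = est.t_grid
    win = (t >= window[0]) & (t <= window[1])
    base = (t >= baseline[0]) & (t < baseline[1])
    if not win.any() or not base.any():
        raise ValueError("empty window after discretization")
    return float(est.hrf[win].mean() - est.hrf[base].mean())


def effects_frame(
    estimates: Sequence[HRFEstimate],
    window: tuple[float, float] = EFFECT_WINDOW,
    baseline: tuple[float, float] = BASELINE_WINDOW,
) -> pd.DataFrame:
    """Tidy per-estimate effects: columns subject/day/channel/chromophore/effect."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "subject": est.meta.get("subject"),
                "day": est.meta.get("day"),
                "channel": est.channel,
                "chromophore": est.chromophore,
                "effect": window_effect(est, window, baseline),
            }
        )
    return pd.DataFrame(rows)


def _finish(t: float, p: float, degenerate: bool, alpha: float):
    return t, p, degenerate, bool(p < alpha)


def _one_sample(x: np.ndarray, alpha: float) -> tuple[float, float, bool, bool]:
    sd = x.std(ddof=1)
    if sd == 0.0:
        # exactly degenerate: all effects identical
        if x.mean() == 0.0:
            return _finish(0.0, 1.0, True, alpha)
        return _finish(np.inf * np.sign(x.mean()), 0.0, True, alpha)
    t, p = sps.ttest_1samp(x, 0.0)
    return _finish(float(t), float(p), False, alpha)


def _per_channel(df: pd.DataFrame) -> dict[tuple[int, str], pd.DataFrame]:
    return {k: g for k, g in df.groupby(["channel", "chromophore"], sort=True)}


def day_vs_baseline(
    effects: pd.DataFrame,
    contrast: str = "day_vs_baseline",
    alpha: float = DEFAULT_ALPHA,
) -> list[ActivationResult]:
    """One-sample t-test of per-subject windowed effects against zero."""
    out = []
    for (ch, chrom), g in _per_channel(effects).items():
        x = g["effect"].to_numpy()
        if len(x) < 2:
            raise ValueError(f"channel {ch}: need >=2 subjects, got {len(x)}")
        t, p, degen, sig = _one_sample(x, alpha)
        out.append(
            ActivationResult(ch, chrom, contrast, float(x.mean()), t, p, len(x), sig, degen)
        )
    return out


def paired_day_contrast(
    effects_day1: pd.DataFrame,
    effects_day15: pd.DataFrame,
    contrast: str = "day15_vs_day1",
    alpha: float = DEFAULT_ALPHA,
) -> list[ActivationResult]:
    """Paired t-test on per-subject differences; positive means day 15 > day 1."""
    g1 = _per_channel(effects_day1)
    g15 = _per_channel(effects_day15)
    if set(g1) != set(g15):
        raise ValueError("day-1 and day-15 effects cover different channels")
    out = []
    for key in g1:
        a = g1[key].set_index("subject")["effect"]
        b = g15[key].set_index("subject")["effect"]
        if set(a.index) != set(b.index):
            raise ValueError(f"unmatched subject sets for channel {key[0]}")
        diff = (b - a.reindex(b.index)).to_numpy()
        t, p, degen, sig = _one_sample(diff, alpha)
        out.append(
            ActivationResult(
                key[0], key[1], contrast, float(diff.mean()), t, p, len(diff), sig, degen
            )
        )
    return out


def split_by_performance(
    final_scores: Mapping[str, float],
) -> tuple[list[str], list[str]]:
    """Split subjects at the cohort mean of final-day scores.

    Returns (above-or-equal, below); ties go to the above group.  An
    all-equal cohort has no meaningful split and raises.
    """
    if len(final_scores) < 2:
        raise ValueError("need at least two subjects to split")
    scores = np.array(list(final_scores.values()), dtype=float)
    if np.all(scores == scores[0]):
        raise ValueError("degenerate split: all final-day scores are equal")
    mean = scores.mean()
    above = [s for s, v in final_scores.items() if v >= mean]
    below = [s for s, v in final_scores.items() if v < mean]
    return above, below


def group_contrast(
    effects_a: pd.DataFrame,
    effects_b: pd.DataFrame,
    contrast: str = "groupA_vs_groupB",
    alpha: float = DEFAULT_ALPHA,
) -> list[ActivationResult]:
    """Welch two-sample t-test per channel; positive means group A > B."""
    ga = _per_channel(effects_a)
    gb = _per_channel(effects_b)
    if set(ga) != set(gb):
        raise ValueError("groups cover different channels")
    out = []
    for key in ga:
        a = ga[key]["effect"].to_numpy()
        b = gb[key]["effect"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("both groups need >=2 subjects")
        if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
            d = a.mean() - b.mean()
            t, p, degen, sig = _one_sample(np.full(2, d), alpha) if d else (
                0.0, 1.0, True, False
            )
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            t, p, degen, sig = float(t), float(p), False, bool(p < alpha)
        out.append(
            ActivationResult(
                key[0], key[1], contrast, float(a.mean() - b.mean()), t, p,
                len(a) + len(b), sig, degen,
            )
        )
    return out


def benjamini_hochberg(
    results: Sequence[ActivationResult], alpha: float = DEFAULT_ALPHA
) -> list[ActivationResult]:
    """Recompute significance with BH-FDR across the given results."""
    from statsmodels.stats.multitest import multipletests

    p = np.array([r.p_value for r in results])
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return [
        ActivationResult(
            r.channel, r.chromophore, r.contrast, r.effect, r.t_statistic,
            r.p_value, r.n, bool(rej), r.degenerate,
        )
        for r, rej in zip(results, reject)
    ]


def results_frame(results: Sequence[ActivationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def rm_anova_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures ANOVA of performance scores across time periods.

    Thin convenience over statsmodels' AnovaRM; expects tidy columns
    ``subject``, ``period``, ``score``.  The paired contrasts above are
    the tested surface — this wrapper just reports the omnibus F.
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(scores, depvar="score", subject="subject", within=["period"]).fit()
    return res.anova_table
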