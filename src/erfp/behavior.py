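"""Behavioral analyses: paired t-tests, 2x2 repeated-measures ANOVA, effects.

Cohen's d for paired data is computed on the difference scores (d_z =
mean(diff)/SD(diff)).  The 2x2 within-subject ANOVA is evaluated through
its paired-contrast formulation: every 1-df effect is a per-participant
contrast score whose one-sample t satisfies F = t^2, and partial eta
squared is SS_effect / (SS_effect + SS_error) = t^2 / (t^2 + N - 1).
Grand means are unweighted means of participant cell means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DesignError


@dataclass
class TestResult:
    """A single test statistic with df, two-sided p and effect size."""

    statistic: float
    df: tuple
    p: float
    effect_size: float
    effect_size_name: str
    kind: str  # 't' or 'F'
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            self.effect_size_name: self.effect_size,
            "degenerate": self.degenerate,
        }


def paired_t(a, b) -> TestResult:
    """Two-sided paired-samples t-test with Cohen's d_z.

    ``a`` and ``b`` are per-participant values in matching order.  Identical
    cells give t = 0, d = 0, p = 1; a nonzero mean difference with zero
    variance is flagged degenerate (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DesignError("paired cells must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise DegenerateInputError("paired t-test needs N >= 2")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.all(d == 0):
            return TestResult(0.0, (df,), 1.0, 0.0, "cohen_d", "t")
        return TestResult(np.nan, (df,), np.nan, np.nan, "cohen_d", "t", degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return TestResult(float(t), (df,), float(p), float(d.mean() / sd), "cohen_d", "t")


def _contrast_f(contrast: np.ndarray) -> TestResult:
    """F test of a per-participant 1-df contrast (F = t^2, df = (1, N-1))."""
    n = contrast.size
    df_err = n - 1
    sd = contrast.std(ddof=1)
    if sd == 0:
        if np.all(contrast == 0):
            return TestResult(0.0, (1, df_err), 1.0, 0.0, "partial_eta_sq", "F")
        return TestResult(
            np.nan, (1, df_err), np.nan, np.nan, "partial_eta_sq", "F", degenerate=True
        )
    t = contrast.mean() / (sd / np.sqrt(n))
    f = t * t
    p = stats.f.sf(f, 1, df_err)
    eta = f / (f + df_err)
    return TestResult(float(f), (1, df_err), float(p), float(eta), "partial_eta_sq", "F")


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str] = ("soa", "task_load"),
    subject: str = "participant",
) -> dict[str, TestResult]:
    """2x2 repeated-measures ANOVA from per-trial or per-cell data.

    ``data`` must contain, for every subject, observations in all four
    cells of the two 2-level within factors.  Cell means per participant
    are formed first; effects are then tested via paired contrasts:
    main effects as differences of factor-level means, the interaction as
    the difference of simple effects (A1-A2 at B1 minus A1-A2 at B2).
    Returns results keyed by factor name and ``'interaction'``.
    """
    f1, f2 = within
    cells = data.groupby([subject, f1, f2], sort=True)[dv].mean().unstack([f1, f2])
    if cells.isna().any().any():
        missing = cells.stack([0, 1], future_stack=True).isna()
        raise DesignError(
            f"incomplete design: missing cells {list(missing[missing].index)}"
        )
    l1 = sorted(data[f1].unique())
    l2 = sorted(data[f2].unique())
    if len(l1) != 2 or len(l2) != 2:
        raise DesignError("rm_anova_2x2 requires exactly 2 levels per factor")
    c11 = cells[(l1[0], l2[0])].to_numpy()
    c12 = cells[(l1[0], l2[1])].to_numpy()
    c21 = cells[(l1[1], l2[0])].to_numpy()
    c22 = cells[(l1[1], l2[1])].to_numpy()
    main1 = (c11 + c12) / 2 - (c21 + c22) / 2
    main2 = (c11 + c21) / 2 - (c12 + c22) / 2
    inter = (c11 - c21) - (c12 - c22)
    return {
        f1: _contrast_f(main1),
        f2: _contrast_f(main2),
        "interaction": _contrast_f(inter),
    }


def cell_means(
    trials: pd.DataFrame,
    dv: str = "rt_ms",
    factors: tuple[str, ...] = ("soa",),
    subject: str = "participant",
) -> pd.DataFrame:
    """Participant x condition cell means (one row per participant)."""
    return trials.groupby([subject, *factors], sort=True)[dv].mean().unstack(
        list(factors)
    )


def summarize_effects(trials: pd.DataFrame, experiment: int = 1) -> dict:
    """Condition means and dual-task effects from a cleaned trial table.

    Expects exclusions to be applied already (pass only included rows).
    Per-participant cell means are computed first; grand means are their
    unweighted averages and effects are differences of grand means, in ms.
    """
    if trials.empty:
        raise DesignError("empty trial table")
    if experiment == 1:
        cm = cell_means(trials, factors=("soa",))
        if cm.isna().any().any():
            raise DesignError("a participant is missing an SOA cell")
        gm = cm.mean(axis=0)
        return {
            "mean_rt_short_soa": float(gm[100]),
            "mean_rt_long_soa": float(gm[1000]),
            "soa_effect_ms": float(gm[100] - gm[1000]),
            "n_participants": int(cm.shape[0]),
        }
    if experiment == 2:
        cm = cell_means(trials, factors=("soa", "task_load"))
        if cm.isna().any().any():
            raise DesignError("a participant is missing an SOA x task-load cell")
        gm = cm.mean(axis=0)
        report = (gm[(100, "report")] + gm[(1000, "report")]) / 2
        ignore = (gm[(100, "ignore")] + gm[(1000, "ignore")]) / 2
        short = (gm[(100, "report")] + gm[(100, "ignore")]) / 2
        long_ = (gm[(1000, "report")] + gm[(1000, "ignore")]) / 2
        return {
            "mean_rt_report": float(report),
            "mean_rt_ignore": float(ignore),
            "mean_rt_short_soa": float(short),
            "mean_rt_long_soa": float(long_),
            "dual_task_cost_ms": float(report - ignore),
            "soa_effect_ms": float(short - long_),
            "soa_effect_report_ms": float(gm[(100, "report")] - gm[(1000, "report")]),
            "soa_effect_ignore_ms": float(gm[(100, "ignore")] - gm[(1000, "ignore")]),
            "n_participants": int(cm.shape[0]),
        }
    raise DesignError(f"experiment must be 1 or 2, got {experiment}")
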