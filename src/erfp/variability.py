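"""Sliding-window moment variability and participant x condition averaging.

Moment variability is the sample standard deviation (denominator n - 1) of
the moment signal inside a window that slides across the epoch in 1-ms
steps, reported in mN·m (1000 x the SD of the N·m signal).  Higher values
indicate a higher likelihood of an active balance adjustment within that
window.  Windows are centered by default: the value at time t summarises
the half-open interval [t - w/2, t + w/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AggregationError,
    AlignmentError,
    DegenerateInputError,
    ParameterError,
)
from .preprocess import Epoch

WINDOW_ALIGNMENTS = ("centered", "trailing")


@dataclass
class VariabilitySeries:
    """A sliding-window SD time course in mN·m."""

    times_ms: np.ndarray
    values: np.ndarray
    window_ms: float = 100.0
    step_ms: float = 1.0
    axis: str = "combined"

    def __post_init__(self):
        if len(self.times_ms) != len(self.values):
            raise ParameterError("time base and values must have equal length")

    def crop(self, t0: float, t1: float) -> "VariabilitySeries":
        """Restrict to times t0 <= t <= t1 (used to trim support padding)."""
        keep = (self.times_ms >= t0 - 1e-9) & (self.times_ms <= t1 + 1e-9)
        return replace(self, times_ms=self.times_ms[keep], values=self.values[keep])


@dataclass
class ConditionTimeCourse:
    """Mean variability series of one participant in one condition."""

    participant: object
    condition: tuple
    series: VariabilitySeries
    n_trials: int = 0


def _window_bounds(n: int, n_window: int, alignment: str) -> tuple[int, int]:
    """First and last (inclusive) center index with full window support."""
    if alignment == "centered":
        left = n_window // 2
        right = n_window - left  # half-open [i-left, i+right)
        return left, n - right
    # trailing: window ends at the current sample, [i-n_window+1, i+1)
    return n_window - 1, n - 1


def sliding_sd(
    series: np.ndarray,
    sample_rate: float,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    times_ms: np.ndarray | None = None,
    alignment: str = "centered",
) -> VariabilitySeries:
    """Sliding-window sample SD of a moment signal, in mN·m.

    Only output times whose window is fully supported by the input are
    returned; callers analysing a fixed window must supply epochs padded by
    half a window at both ends and crop afterwards.  Equivalent to a naive
    per-window recomputation (tested to 1e-9) but computed with cumulative
    sums in O(n).
    """
    x = np.asarray(series, dtype=float)
    if alignment not in WINDOW_ALIGNMENTS:
        raise ParameterError(f"alignment must be one of {WINDOW_ALIGNMENTS}")
    n_window = int(round(window_ms * sample_rate / 1000.0))
    if n_window < 2:
        raise ParameterError(
            f"window of {window_ms} ms at {sample_rate} Hz holds fewer than 2 samples"
        )
    step = step_ms * sample_rate / 1000.0
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ParameterError(
            f"step of {step_ms} ms is not a positive integer number of samples"
        )
    step = int(round(step))
    n = x.size
    if n < n_window:
        raise ParameterError(
            f"series of {n} samples shorter than the {n_window}-sample window; "
            "supply a padded epoch"
        )
    if times_ms is None:
        times_ms = np.arange(n) * 1000.0 / sample_rate
    times_ms = np.asarray(times_ms, dtype=float)

    lo, hi = _window_bounds(n, n_window, alignment)
    centers = np.arange(lo, hi + 1, step)
    # de-mean for numerical stability; the SD is translation invariant
    xc = x - x.mean()
    c1 = np.concatenate(([0.0], np.cumsum(xc)))
    c2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
    if alignment == "centered":
        starts = centers - n_window // 2
    else:
        starts = centers - n_window + 1
    ends = starts + n_window
    s1 = c1[ends] - c1[starts]
    s2 = c2[ends] - c2[starts]
    var = (s2 - s1 * s1 / n_window) / (n_window - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return VariabilitySeries(
        times_ms=times_ms[centers],
        values=1000.0 * sd,
        window_ms=window_ms,
        step_ms=step_ms,
        axis="",
    )


def combine_axes(ml: VariabilitySeries, ap: VariabilitySeries) -> VariabilitySeries:
    """Average the mediolateral and anterior-posterior variability pointwise."""
    if ml.times_ms.shape != ap.times_ms.shape or not np.allclose(
        ml.times_ms, ap.times_ms
    ):
        raise AlignmentError("ML and AP series do not share a time base")
    return VariabilitySeries(
        times_ms=ml.times_ms.copy(),
        values=(ml.values + ap.values) / 2.0,
        window_ms=ml.window_ms,
        step_ms=ml.step_ms,
        axis="combined",
    )


def epoch_variability(
    epoch: Epoch,
    sample_rate: float,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    axes: str = "combined",
    alignment: str = "centered",
    analysis_window_ms: tuple[float, float] | None = (-500.0, 3000.0),
) -> VariabilitySeries:
    """Per-trial variability: SD per axis, then axis combination.

    With the default settings the epoch is expected to be padded (e.g.
    -550..3050 ms) and the output is cropped to the analysis window.
    """
    kw = dict(
        sample_rate=sample_rate,
        window_ms=window_ms,
        step_ms=step_ms,
        times_ms=epoch.times_ms,
        alignment=alignment,
    )
    if axes == "ml":
        out = replace(sliding_sd(epoch.mx, **kw), axis="ML")
    elif axes == "ap":
        out = replace(sliding_sd(epoch.my, **kw), axis="AP")
    elif axes == "combined":
        ml = replace(sliding_sd(epoch.mx, **kw), axis="ML")
        ap = replace(sliding_sd(epoch.my, **kw), axis="AP")
        out = combine_axes(ml, ap)
    else:
        raise ParameterError("axes must be 'ml', 'ap' or 'combined'")
    if analysis_window_ms is not None:
        out = out.crop(*analysis_window_ms)
    return out


def aggregate(
    trial_series: Sequence[tuple[object, int, VariabilitySeries]],
    trials: pd.DataFrame,
    grouping: Sequence[str],
) -> list[ConditionTimeCourse]:
    """Average per-trial variability into participant x condition means.

    ``trial_series`` holds (participant, trial, series) for *included*
    trials only — exclusions must already be applied.  ``grouping`` names
    trial-table columns (e.g. ``['soa']``).  Every participant must have at
    least one trial in every observed condition cell; an empty cell raises
    :class:`~erfp.exceptions.AggregationError` naming it.
    """
    grouping = list(grouping)
    lookup = trials.set_index(["participant", "trial"])[grouping]
    if lookup.index.has_duplicates:
        raise AggregationError("trial table has duplicate (participant, trial) keys")
    base = None
    cells: dict[tuple, list[np.ndarray]] = {}
    meta: dict[tuple, VariabilitySeries] = {}
    for participant, trial, series in trial_series:
        if base is None:
            base = series.times_ms
        elif series.times_ms.shape != base.shape or not np.allclose(
            series.times_ms, base
        ):
            raise AlignmentError(
                f"trial {trial} of participant {participant} is on a different time base"
            )
        try:
            cond = tuple(np.atleast_1d(lookup.loc[(participant, trial)].to_numpy()))
        except KeyError:
            raise AggregationError(
                f"(participant={participant}, trial={trial}) absent from trial table"
            ) from None
        cells.setdefault((participant, cond), []).append(series.values)
        meta[(participant, cond)] = series
    if not cells:
        raise AggregationError("no trial series supplied")

    participants = sorted({p for p, _ in cells}, key=str)
    conditions = sorted({c for _, c in cells}, key=str)
    out = []
    for p in participants:
        for cond in conditions:
            values = cells.get((p, cond))
            if not values:
                raise AggregationError(
                    f"participant {p} has no included trials in condition {cond}"
                )
            proto = meta[(p, cond)]
            out.append(
                ConditionTimeCourse(
                    participant=p,
                    condition=cond,
                    series=VariabilitySeries(
                        times_ms=base.copy(),
                        values=np.mean(values, axis=0),
                        window_ms=proto.window_ms,
                        step_ms=proto.step_ms,
                        axis=proto.axis,
                    ),
                    n_trials=len(values),
                )
            )
    return out


def timecourses_to_frame(timecourses: Iterable[ConditionTimeCourse]) -> pd.DataFrame:
    """Long-format export: participant, condition, time_ms, value_mNm."""
    rows = []
    for tc in timecourses:
        rows.append(
            pd.DataFrame(
                {
                    "participant": tc.participant,
                    "condition": "/".join(map(str, tc.condition)),
                    "time_ms": tc.series.times_ms,
                    "value_mNm": tc.series.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def within_subject_ci(
    timecourses: Sequence[ConditionTimeCourse], level: float = 0.95
) -> dict[tuple, np.ndarray]:
    """Pointwise within-subject CI half-widths per condition.

    Cousineau-Morey procedure: each participant's data are centered on that
    participant's cross-condition mean (plus the grand mean), the pointwise
    SE across participants is corrected by sqrt(C/(C-1)) for C conditions,
    and the half-width is the two-sided t critical value times the corrected
    SE.  With identical participants the half-width is 0; ``level=0`` gives
    half-width 0.
    """
    participants = sorted({tc.participant for tc in timecourses}, key=str)
    conditions = sorted({tc.condition for tc in timecourses}, key=str)
    n, c = len(participants), len(conditions)
    if n < 2:
        raise DegenerateInputError("within-subject CI needs >= 2 participants")
    table = {(tc.participant, tc.condition): tc.series.values for tc in timecourses}
    t_len = len(next(iter(table.values())))
    data = np.empty((n, c, t_len))
    for i, p in enumerate(participants):
        for j, cond in enumerate(conditions):
            try:
                data[i, j] = table[(p, cond)]
            except KeyError:
                raise AggregationError(
                    f"participant {p} missing condition {cond}"
                ) from None
    centered = data - data.mean(axis=1, keepdims=True) + data.mean(axis=(0, 1), keepdims=True)
    se = centered.std(axis=0, ddof=1) / np.sqrt(n)
    if c > 1:
        se = se * np.sqrt(c / (c - 1.0))
    t_crit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return {cond: t_crit * se[j] for j, cond in enumerate(conditions)}
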