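"""Filtering, event-aligned epoching and behavioral trial exclusion.

The continuous moment signal is low-pass filtered (zero-phase Butterworth,
10 Hz cut-off by default) *before* segmentation so that the dual-pass edge
transients fall at the recording edges rather than inside every 3.5-s
epoch.  Epochs are aligned so that the chosen trigger (fixation-cross/cue
onset by default) defines t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import OrderingError, ParameterError, SegmentationError
from .io import EventMarker, ForcePlateRecording

FILTER_MODES = ("dual_pass_4", "dual_pass_2x2")


def butterworth_lowpass(
    x: np.ndarray,
    sample_rate: float,
    cutoff_hz: float = 10.0,
    order: int = 4,
    mode: str = "dual_pass_4",
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    ``mode='dual_pass_4'`` designs an ``order``-th order filter and applies
    it forward and backward (effective magnitude response of order
    2x``order``); ``mode='dual_pass_2x2'`` designs at half the order before
    the dual pass, reading the acquisition convention the other way.

    Output length equals input length; a constant signal passes unchanged
    (unit DC gain).
    """
    x = np.asarray(x, dtype=float)
    nyquist = sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if cutoff_hz <= 0 or order < 1:
        raise ParameterError("cutoff must be > 0 and order >= 1")
    if mode not in FILTER_MODES:
        raise ParameterError(f"mode must be one of {FILTER_MODES}")
    design_order = order if mode == "dual_pass_4" else max(order // 2, 1)
    if x.shape[-1] <= 3 * design_order:
        raise ParameterError(
            f"signal length {x.shape[-1]} too short for order-{design_order} dual-pass"
        )
    sos = signal.butter(design_order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


@dataclass
class Epoch:
    """One trial's moment signal aligned to an event (t = 0).

    ``times_ms`` runs from ``window_ms[0]`` to ``window_ms[1]`` inclusive in
    1000/sample_rate steps; the sample at t = 0 is the alignment-event
    sample, copied verbatim from the (filtered) recording.
    """

    participant: object
    trial: int
    times_ms: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.times_ms) == len(self.mx) == len(self.my)):
            raise ParameterError("epoch channels and time base must have equal length")


def segment(
    recording: ForcePlateRecording,
    events: Sequence[EventMarker] | None = None,
    align_code: str = "CUE_ONSET",
    window_ms: tuple[float, float] = (-500.0, 3000.0),
    conditions: Mapping[int, dict] | None = None,
) -> list[Epoch]:
    """Cut the continuous recording into one epoch per trial.

    The epoch spans ``window_ms`` (inclusive at both ends) around the
    alignment marker, i.e. ``(w1 - w0) * fs/1000 + 1`` samples.  A trigger
    at sample 10,000 at 1 kHz with the default window yields samples
    9,500..13,000.  Trials whose window exceeds the recording bounds raise
    :class:`~erfp.exceptions.SegmentationError` listing them.
    """
    events = recording.events if events is None else list(events)
    fs = recording.sample_rate
    w0, w1 = window_ms
    if w1 <= w0:
        raise ParameterError(f"empty epoch window {window_ms}")
    off0 = int(round(w0 * fs / 1000.0))
    off1 = int(round(w1 * fs / 1000.0))
    n = recording.n_samples
    mx = recording.channel("Mx")
    my = recording.channel("My")
    times = np.arange(off0, off1 + 1) * 1000.0 / fs

    anchors = [(e.trial, e.sample_index) for e in events if e.code == align_code]
    if not anchors:
        raise SegmentationError(f"no {align_code} markers found")
    dropped = [t for t, s in anchors if s + off0 < 0 or s + off1 >= n]
    if dropped:
        raise SegmentationError(
            f"epoch window {window_ms} ms exceeds recording bounds for trials {dropped}"
        )
    epochs = []
    for trial, s in anchors:
        sl = slice(s + off0, s + off1 + 1)
        epochs.append(
            Epoch(
                participant=recording.participant,
                trial=trial,
                times_ms=times.copy(),
                mx=mx[sl].copy(),
                my=my[sl].copy(),
                condition=dict((conditions or {}).get(trial, {})),
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# behavioral exclusions
# ---------------------------------------------------------------------------

#: Which error types disqualify a trial for each analysis.  The error rates
#: of one task are analysed after excluding error trials of the *other* task;
#: the RT analysis (and the force-plate analysis, which reuses its trial set)
#: excludes errors in either task.  Post-error trials are excluded throughout.
ANALYSES = {
    "memory_errors": ("manual_error",),
    "rt_task_errors": ("vocal_error",),
    "rt_and_forceplate": ("manual_error", "vocal_error"),
}

FLAG_COLUMNS = ("rt_outlier", "manual_error", "vocal_error", "post_error", "first_in_block")


@dataclass
class ExclusionReport:
    """Per-trial exclusion flags plus per-rule percentages.

    ``flags`` is aligned with the input trial table and carries the boolean
    columns ``rt_outlier, manual_error, vocal_error, post_error,
    first_in_block, excluded, included``.  Percentages are fractions of all
    trials, in percent.
    """

    analysis: str
    flags: pd.DataFrame
    percentages: dict

    @property
    def included(self) -> pd.Series:
        return self.flags["included"]


def apply_exclusions(
    trials: pd.DataFrame,
    analysis: str = "rt_and_forceplate",
    rt_sd_multiplier: float = 3.0,
) -> ExclusionReport:
    """Apply the behavioral trial-exclusion rules.

    Rules, in order: (1) RT outliers — responded trials deviating more than
    ``rt_sd_multiplier`` SD from that participant's mean RT, computed over
    all responded trials; (2) error trials of the task(s) relevant to
    ``analysis`` and trials immediately following any error; (3) the first
    *remaining* trial of each block (the experimenter started blocks for the
    participants).  The table must be sorted by participant, block, trial.
    """
    if analysis not in ANALYSES:
        raise ParameterError(f"analysis must be one of {sorted(ANALYSES)}")
    key = trials[["participant", "block", "trial"]]
    if not key.equals(key.sort_values(["participant", "block", "trial"])):
        raise OrderingError("trial table must be sorted by participant, block, trial")

    rt = trials["rt_ms"].astype(float)
    responded = rt.notna() & (rt > 0)
    grp = trials["participant"]
    mean = rt.where(responded).groupby(grp).transform("mean")
    sd = rt.where(responded).groupby(grp).transform("std")
    rt_outlier = responded & ((rt - mean).abs() > rt_sd_multiplier * sd)
    rt_outlier &= sd.notna() & (sd > 0)

    manual = trials["manual_error"].astype(bool)
    vocal = trials["vocal_error"].astype(bool)
    any_error = manual | vocal
    post_error = (
        any_error.groupby([trials["participant"], trials["block"]])
        .shift(1, fill_value=False)
        .astype(bool)
    )

    error_cols = {"manual_error": manual, "vocal_error": vocal}
    analysis_error = pd.Series(False, index=trials.index)
    for col in ANALYSES[analysis]:
        analysis_error |= error_cols[col]

    pre = rt_outlier | analysis_error | post_error
    first_in_block = pd.Series(False, index=trials.index)
    remaining = trials.index[~pre]
    if len(remaining):
        firsts = (
            trials.loc[remaining]
            .groupby(["participant", "block"], sort=False)
            .head(1)
            .index
        )
        first_in_block.loc[firsts] = True

    excluded = pre | first_in_block
    flags = pd.DataFrame(
        {
            "rt_outlier": rt_outlier,
            "manual_error": manual,
            "vocal_error": vocal,
            "post_error": post_error,
            "first_in_block": first_in_block,
            "excluded": excluded,
            "included": ~excluded,
        },
        index=trials.index,
    )
    n = len(trials)
    pct = {c: float(flags[c].mean() * 100.0) for c in FLAG_COLUMNS}
    pct["excluded"] = float(excluded.mean() * 100.0)
    return ExclusionReport(analysis=analysis, flags=flags, percentages=pct if n else {})
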