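"""Reading and writing force-plate exports, event tables and trial tables.

The on-disk formats are deliberately plain: delimited text for the
continuous recording (columns ``time_s, Fx, Fy, Fz, Mx, My, Mz``; forces in
N, moments in N·m) and CSV for event markers, behavioral trials and cluster
results.  Sample indices are 0-based throughout; millisecond timestamps are
``sample_index / sample_rate * 1000``.  Units on disk stay physical (N,
N·m); conversion to mN·m happens in :mod:`erfp.variability` only.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, ParameterError

#: Event codes in the order they must occur within a trial.
EVENT_CODES = ("CUE_ONSET", "VISUAL_TARGET", "AUDITORY_TARGET", "MANUAL_RESPONSE")

CHANNEL_COLUMNS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")

TRIAL_COLUMNS = (
    "participant",
    "block",
    "trial",
    "soa",
    "task_load",
    "tone",
    "orientation",
    "rt_ms",
    "manual_error",
    "vocal_error",
)

SOA_LEVELS = (100, 1000)


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect of a force-plate export."""

    delimiter: str = "\t"
    decimal: str = "."
    skip_header_lines: int = 0


@dataclass(frozen=True)
class EventMarker:
    """One trigger marker: trial id, event code and 0-based sample index."""

    trial: int
    code: str
    sample_index: int

    def __post_init__(self):
        if self.code not in EVENT_CODES:
            raise FormatError(
                f"unknown event code {self.code!r}; expected one of {EVENT_CODES}"
            )
        if self.sample_index < 0:
            raise FormatError(f"negative sample index {self.sample_index}")

    def time_ms(self, sample_rate: float) -> float:
        return self.sample_index / sample_rate * 1000.0


@dataclass
class ForcePlateRecording:
    """Continuous multi-channel force/moment signal plus trigger events.

    Parameters
    ----------
    sample_rate
        Sampling frequency in Hz (1,000 for the supported acquisition setup).
    samples
        DataFrame with the six channel columns ``Fx .. Mz``; forces in N,
        moments in N·m, one row per sample.
    events
        Trigger markers; within each trial the codes must be chronological
        (cue < visual < auditory <= response).
    participant
        Optional participant id (one recording file per participant).
    """

    sample_rate: float
    samples: pd.DataFrame
    events: list[EventMarker] = field(default_factory=list)
    participant: object = None

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        missing = [c for c in CHANNEL_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"missing channel columns: {missing}")
        n = len(self.samples)
        for ev in self.events:
            if ev.sample_index >= n:
                raise FormatError(
                    f"event {ev.code} of trial {ev.trial} at sample "
                    f"{ev.sample_index} outside recording of {n} samples"
                )
        _check_event_order(self.events)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy(dtype=float)


def _check_event_order(events: Iterable[EventMarker]) -> None:
    """Enforce CUE < VISUAL < AUDITORY <= RESPONSE within every trial."""
    per_trial: dict[int, dict[str, int]] = {}
    for ev in events:
        bucket = per_trial.setdefault(ev.trial, {})
        if ev.code in bucket:
            raise ConsistencyError(f"duplicate {ev.code} marker in trial {ev.trial}")
        bucket[ev.code] = ev.sample_index
    for trial, codes in per_trial.items():
        present = [c for c in EVENT_CODES if c in codes]
        samples = [codes[c] for c in present]
        strict = samples[: len(samples) if "MANUAL_RESPONSE" not in present else -1]
        if any(b <= a for a, b in zip(strict, strict[1:])):
            raise ConsistencyError(
                f"event markers of trial {trial} not in chronological order: {codes}"
            )
        if "MANUAL_RESPONSE" in present and "AUDITORY_TARGET" in present:
            if codes["MANUAL_RESPONSE"] < codes["AUDITORY_TARGET"]:
                raise ConsistencyError(
                    f"trial {trial}: MANUAL_RESPONSE precedes AUDITORY_TARGET"
                )


# ---------------------------------------------------------------------------
# continuous recording
# ---------------------------------------------------------------------------


def write_recording(recording: ForcePlateRecording, path, dialect: Dialect = Dialect()) -> None:
    """Write a recording as delimited text with a ``time_s`` column.

    A single comment line ``# sample_rate_hz: <rate>`` precedes the header so
    the file is self-describing.
    """
    path = Path(path)
    n = recording.n_samples
    out = pd.DataFrame({"time_s": np.arange(n) / recording.sample_rate})
    for c in CHANNEL_COLUMNS:
        out[c] = recording.samples[c].to_numpy()
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {recording.sample_rate:g}\n")
        out.to_csv(fh, sep=dialect.delimiter, index=False, float_format="%.9g")


def read_recording(
    path,
    dialect: Dialect = Dialect(),
    sample_rate: float | None = None,
    events: Sequence[EventMarker] = (),
    participant=None,
) -> ForcePlateRecording:
    """Read a delimited force-plate export.

    The sample rate is taken, in order of precedence, from the
    ``sample_rate`` argument, a ``# sample_rate_hz:`` comment line, or the
    spacing of the ``time_s`` column.  The time column must advance in
    uniform steps of one sample; a gap or reversal raises
    :class:`~erfp.exceptions.FormatError` naming the first bad line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        raw = fh.readlines()
    raw = raw[dialect.skip_header_lines :]
    header_rate = None
    data_start = 0
    for i, line in enumerate(raw):
        if line.startswith("#"):
            if "sample_rate_hz" in line:
                header_rate = float(line.split(":", 1)[1])
            data_start = i + 1
        else:
            break
    body = "".join(raw[data_start:])
    try:
        df = pd.read_csv(
            _stdio.StringIO(body), sep=dialect.delimiter, decimal=dialect.decimal
        )
    except Exception as exc:  # malformed delimiter layout
        raise FormatError(f"{path}: cannot parse delimited body: {exc}") from exc
    missing = [c for c in CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel columns {missing}")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        step = np.median(dt)
        if step <= 0:
            raise FormatError(f"{path}: non-monotone time column")
        bad = np.flatnonzero(np.abs(dt - step) > step * 1e-3)
        if bad.size:
            # +2 for the header line, +1 for 1-based numbering of the offender
            line_no = data_start + dialect.skip_header_lines + int(bad[0]) + 3
            raise FormatError(
                f"{path}: gap or irregular step in time column at line {line_no} "
                f"(dt={dt[bad[0]]:g}, expected {step:g})"
            )
        inferred_rate = 1.0 / step
    else:
        inferred_rate = None

    rate = sample_rate or header_rate or inferred_rate
    if rate is None:
        raise FormatError(f"{path}: sample rate not given and not inferrable")
    return ForcePlateRecording(
        sample_rate=float(rate),
        samples=df[list(CHANNEL_COLUMNS)].astype(float).reset_index(drop=True),
        events=list(events),
        participant=participant,
    )


# ---------------------------------------------------------------------------
# event and trial tables
# ---------------------------------------------------------------------------


def write_events(events: Sequence[EventMarker], path) -> None:
    pd.DataFrame(
        {
            "trial": [e.trial for e in events],
            "code": [e.code for e in events],
            "sample_index": [e.sample_index for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> list[EventMarker]:
    """Read an event-marker CSV (columns trial, code, sample_index)."""
    df = pd.read_csv(path)
    required = {"trial", "code", "sample_index"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: event table needs columns {sorted(required)}")
    bad = set(df["code"]) - set(EVENT_CODES)
    if bad:
        raise FormatError(f"{path}: unknown event codes {sorted(bad)}")
    events = [
        EventMarker(int(r.trial), str(r.code), int(r.sample_index))
        for r in df.itertuples()
    ]
    _check_event_order(events)
    return events


def read_trials(path) -> pd.DataFrame:
    """Read a behavioral trial table CSV and validate its schema."""
    df = pd.read_csv(path)
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials).to_csv(path, index=False)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing columns {missing}")
    bad_soa = set(trials["soa"].unique()) - set(SOA_LEVELS)
    if bad_soa:
        raise FormatError(f"soa levels {sorted(bad_soa)} outside {SOA_LEVELS}")
    responded = trials["rt_ms"].notna()
    if (trials.loc[responded, "rt_ms"] <= 0).any():
        raise FormatError("rt_ms must be > 0 where a response was given")
    out = trials.copy()
    out["manual_error"] = out["manual_error"].astype(bool)
    out["vocal_error"] = out["vocal_error"].astype(bool)
    return out


def check_events_against_trials(
    events: Sequence[EventMarker], trials: pd.DataFrame
) -> None:
    """Raise if the events reference trials absent from the trial table."""
    known = set(trials["trial"].astype(int))
    orphans = sorted({e.trial for e in events} - known)
    if orphans:
        raise ConsistencyError(
            f"events reference trials absent from the trial table: {orphans}"
        )


# ---------------------------------------------------------------------------
# cluster results
# ---------------------------------------------------------------------------


def write_clusters(results, path, contrast: str | None = None) -> None:
    """Write cluster-test results as CSV.

    ``results`` is either a list of ClusterResult or a mapping
    ``contrast -> list of ClusterResult``.
    """
    if isinstance(results, dict):
        items = [(name, c) for name, lst in results.items() for c in lst]
    else:
        items = [(contrast or "", c) for c in results]
    pd.DataFrame(
        {
            "contrast": [name for name, _ in items],
            "start_ms": [c.start_ms for _, c in items],
            "end_ms": [c.end_ms for _, c in items],
            "mass": [c.mass for _, c in items],
            "p_value": [c.p_value for _, c in items],
            "sign": [c.sign for _, c in items],
        }
    ).to_csv(path, index=False)


def read_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"contrast", "start_ms", "end_ms", "mass", "p_value", "sign"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: cluster table needs columns {sorted(required)}")
    return df
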