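"""Synthetic postural-sway recordings and PRP dual-task behavior.

Two generators with the statistical structure the analysis pipeline
assumes:

* **Behavior** — reaction times of the speeded auditory-manual task in a
  hybrid psychological-refractory-period paradigm.  Encoding the masked
  visual object occupies a central memory-consolidation bottleneck for
  ``C`` ms; the RT to the tone presented SOA ms after the visual target is
  ``base + max(0, C - SOA) + noise`` with zero-mean ex-Gaussian noise, so a
  short SOA produces the classic PRP slowing while a long SOA escapes the
  bottleneck.

* **Sway** — 1,000-Hz force-plate moment signals modelled as intermittent
  postural control: an autocorrelated (Ornstein-Uhlenbeck) baseline per
  axis plus bell-shaped corrective impulses at inhomogeneous-Poisson times.
  The impulse rate is modulated by trial phase (elevated around the
  fixation cross, suppressed between the visual target and the manual
  response, rebounding after the response) and optionally by condition, so
  condition differences in sliding-window moment variability can be
  embedded at known times and recovered by the cluster test.

All outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .exceptions import DesignError, LayoutError, ParameterError
from .io import EventMarker, ForcePlateRecording

N_OBJECTS = 5  # everyday objects shown left- or right-oriented

PHASES = ("pre_fixation", "fixation_to_target", "suppression", "rebound")

#: trial timing (ms, relative to fixation-cross/cue onset)
FIXATION_MS = 500.0
VISUAL_ONSET_MS = 1000.0
VISUAL_DURATION_MS = 50.0

#: epoch extent the sway simulator guarantees support for (padded window)
EPOCH_SPAN_MS = (-550.0, 3050.0)


@dataclass
class BehaviorParams:
    """Parameters of the PRP reaction-time model.

    ``base_rt_ms`` and ``consolidation_ms`` are keyed by task load
    (``'n.a.'`` when load is not manipulated).  The consolidation duration
    ``C`` is the time the memory-consolidation bottleneck is occupied after
    visual-target onset; tones arriving before it clears (SOA < C) are
    delayed by the residual ``C - SOA``.
    """

    base_rt_ms: Mapping[str, float]
    consolidation_ms: Mapping[str, float]
    soa_levels: tuple[int, ...] = (100, 1000)
    rt_noise_sigma_ms: float = 60.0
    rt_noise_tau_ms: float = 80.0
    p_manual_error: float = 0.02
    p_vocal_error: float = 0.02
    n_participants: int = 48
    n_blocks: int = 4
    trials_per_cell: int = 10  # per SOA x tone x orientation (x load) cell per block

    def __post_init__(self):
        for name in ("rt_noise_sigma_ms", "rt_noise_tau_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for mapping in (self.base_rt_ms, self.consolidation_ms):
            for key, v in dict(mapping).items():
                if v < 0:
                    raise ParameterError(f"duration for load {key!r} must be >= 0, got {v}")
        for name in ("p_manual_error", "p_vocal_error"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if any(s <= 0 for s in self.soa_levels):
            raise ParameterError("soa_levels must be strictly positive")
        if set(self.base_rt_ms) != set(self.consolidation_ms):
            raise ParameterError("base_rt_ms and consolidation_ms must share keys")
        if self.n_participants < 1 or self.n_blocks < 1 or self.trials_per_cell < 1:
            raise ParameterError("counts must be >= 1")

    @property
    def task_loads(self) -> tuple[str, ...]:
        return tuple(sorted(self.base_rt_ms))

    @classmethod
    def experiment1(cls, **overrides) -> "BehaviorParams":
        """Calibrated to the first experiment: 613 ms base, 338 ms bottleneck
        (851 ms expected at SOA 100), 4 blocks of 80 trials."""
        defaults = dict(
            base_rt_ms={"n.a.": 613.0},
            consolidation_ms={"n.a.": 338.0},
            n_blocks=4,
            trials_per_cell=10,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def experiment2(cls, **overrides) -> "BehaviorParams":
        """Calibrated to the second experiment (task load report vs. ignore):
        expected cell means 845/649 (report) and 718/624 ms (ignore), 6
        blocks of 80 trials."""
        defaults = dict(
            base_rt_ms={"report": 649.0, "ignore": 624.0},
            consolidation_ms={"report": 296.0, "ignore": 194.0},
            n_blocks=6,
            trials_per_cell=5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def expected_rt(self, soa: float, load: str = "n.a.") -> float:
        """Closed-form expected RT: base + max(0, C - SOA) (noise is zero-mean)."""
        return float(self.base_rt_ms[load] + max(0.0, self.consolidation_ms[load] - soa))


@dataclass
class SwayParams:
    """Parameters of the intermittent-control sway generator.

    ``impulse_rate_hz`` is the baseline corrective-impulse rate λ0 which is
    multiplied by ``phase_multipliers[phase]`` within a trial and by any
    matching entry of ``condition_multipliers`` (keyed by ``(soa, load)``,
    ``soa`` or ``load``; scalar, or mapping phase -> multiplier).
    ``condition_windows`` additionally scales the rate inside fixed windows
    (start_ms, end_ms, multiplier) relative to cue onset, for embedding
    effects at known times.
    """

    sample_rate: float = 1000.0
    baseline_sigma: float = 0.02  # N·m, stationary SD of the OU baseline
    baseline_tau_ms: float = 300.0
    impulse_rate_hz: float = 2.0  # λ0
    phase_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "pre_fixation": 1.0,
            "fixation_to_target": 1.2,
            "suppression": 0.6,
            "rebound": 1.4,
        }
    )
    impulse_amplitude: float = 0.02  # N·m
    impulse_width_ms: float = 150.0  # total width; Gaussian SD = width / 5
    condition_multipliers: Mapping = field(default_factory=dict)
    condition_windows: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")
        if self.impulse_rate_hz < 0:
            raise ParameterError("impulse_rate_hz (λ0) must be >= 0")
        if self.impulse_width_ms <= 0:
            raise ParameterError("impulse_width_ms must be > 0")
        if self.baseline_sigma < 0 or self.baseline_tau_ms <= 0:
            raise ParameterError("baseline noise needs sigma >= 0 and tau > 0")
        unknown = set(self.phase_multipliers) - set(PHASES)
        if unknown:
            raise ParameterError(f"unknown phases {sorted(unknown)}; valid: {PHASES}")
        if any(v < 0 for v in self.phase_multipliers.values()):
            raise ParameterError("phase multipliers must be >= 0")


@dataclass
class TrialEventsSpec:
    """Timing of one trial's events in recording time.

    Cue (fixation-cross) onset at ``t0_ms`` defines trial time zero; the
    visual target appears 1,000 ms later for 50 ms, the tone at
    1,000 + SOA ms, and the manual response ``rt_ms`` after the tone.
    """

    trial: int
    t0_ms: float
    soa_ms: float
    rt_ms: float
    task_load: str = "n.a."

    def __post_init__(self):
        if self.soa_ms <= VISUAL_DURATION_MS:
            raise ParameterError(
                "visual-target offset must precede auditory onset (SOA too short)"
            )
        if self.rt_ms <= 0:
            raise ParameterError("rt_ms must be > 0")

    @property
    def visual_ms(self) -> float:
        return self.t0_ms + VISUAL_ONSET_MS

    @property
    def auditory_ms(self) -> float:
        return self.visual_ms + self.soa_ms

    @property
    def response_ms(self) -> float:
        return self.auditory_ms + self.rt_ms

    def event_times(self) -> dict[str, float]:
        return {
            "CUE_ONSET": self.t0_ms,
            "VISUAL_TARGET": self.visual_ms,
            "AUDITORY_TARGET": self.auditory_ms,
            "MANUAL_RESPONSE": self.response_ms,
        }


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _no_repeat_sequence(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """Shuffle so that no label repeats in consecutive positions.

    Repair strategy: shuffle, then swap each offending position with a
    later position that breaks the repeat; reshuffle on failure.
    """
    labels = np.array(labels)
    for _ in range(200):
        seq = rng.permutation(labels)
        ok = True
        for i in range(1, len(seq)):
            if seq[i] != seq[i - 1]:
                continue
            fixed = False
            for j in range(i + 1, len(seq)):
                if seq[j] != seq[i - 1] and (i + 1 >= len(seq) or seq[j] != seq[i + 1]):
                    seq[i], seq[j] = seq[j], seq[i]
                    fixed = True
                    break
            if not fixed:
                ok = False
                break
        if ok:
            return seq
    raise DesignError("could not build a no-repeat object sequence")


def simulate_behavior(params: BehaviorParams, seed: int) -> pd.DataFrame:
    """Simulate the behavioral trial table of one study.

    One row per trial with the design factors, the simulated RT (ms) and
    manual/vocal error flags.  The expected cell mean RT is
    ``base + max(0, C - SOA)`` (the ex-Gaussian noise is shifted to zero
    mean).  Condition order is quasi-random within blocks; the same visual
    object never appears in two consecutive trials; the tone-key mapping
    alternates across participants.
    """
    rng = np.random.default_rng(seed)
    loads = params.task_loads
    cell = [
        (soa, load, tone, orient)
        for soa in params.soa_levels
        for load in loads
        for tone in ("low", "high")
        for orient in ("left", "right")
    ]
    block_size = len(cell) * params.trials_per_cell
    if block_size % N_OBJECTS:
        raise DesignError(
            f"block of {block_size} trials not divisible by {N_OBJECTS} objects"
        )
    rows = []
    for p in range(1, params.n_participants + 1):
        key_mapping = "low-left" if p % 2 else "low-right"
        for block in range(1, params.n_blocks + 1):
            conds = [c for c in cell for _ in range(params.trials_per_cell)]
            order = rng.permutation(len(conds))
            objects = _no_repeat_sequence(
                rng, np.repeat(np.arange(N_OBJECTS), block_size // N_OBJECTS)
            )
            for i, k in enumerate(order):
                soa, load, tone, orient = conds[k]
                noise = params.rt_noise_sigma_ms * rng.standard_normal()
                noise += params.rt_noise_tau_ms * (rng.exponential() - 1.0)
                rt = params.expected_rt(soa, load) + noise
                rows.append(
                    {
                        "participant": p,
                        "block": block,
                        "trial": i + 1,
                        "soa": int(soa),
                        "task_load": load,
                        "tone": tone,
                        "orientation": orient,
                        "object": int(objects[i]),
                        "key_mapping": key_mapping,
                        "rt_ms": max(rt, 1.0),
                        "manual_error": bool(rng.random() < params.p_manual_error),
                        "vocal_error": bool(
                            load != "ignore" and rng.random() < params.p_vocal_error
                        ),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sway
# ---------------------------------------------------------------------------


def ou_noise(
    n: int, sigma: float, tau_ms: float, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck (AR(1)) noise with SD ``sigma``.

    Discretised as x[k] = a x[k-1] + sigma sqrt(1-a^2) eps[k] with
    a = exp(-dt/tau); a 10-tau burn-in reaches stationarity.
    """
    if sigma == 0:
        rng.standard_normal(1)  # keep the stream layout stable
        return np.zeros(n)
    a = math.exp(-1000.0 / (sample_rate * tau_ms))
    burn = int(10 * tau_ms * sample_rate / 1000.0)
    eps = rng.standard_normal(n + burn)
    x = _signal.lfilter([sigma * math.sqrt(1.0 - a * a)], [1.0, -a], eps)
    return x[burn:]


def _condition_factor(mapping: Mapping, spec: TrialEventsSpec):
    """Look up a per-condition entry by (soa, load), soa, or load."""
    for key in ((spec.soa_ms, spec.task_load), (int(spec.soa_ms), spec.task_load),
                spec.soa_ms, int(spec.soa_ms), spec.task_load):
        if key in mapping:
            return mapping[key]
    return None


def _rate_vector(
    n: int, trial_events: Sequence[TrialEventsSpec], params: SwayParams
) -> np.ndarray:
    """Per-sample impulse rate λ(t) in events/s."""
    fs = params.sample_rate
    lam0 = params.impulse_rate_hz
    rate = np.full(n, lam0)
    idx = lambda t_ms: int(round(t_ms * fs / 1000.0))
    for spec in trial_events:
        mult = dict.fromkeys(PHASES, 1.0)
        mult.update(params.phase_multipliers)
        cond = _condition_factor(params.condition_multipliers, spec)
        if cond is not None:
            if isinstance(cond, Mapping):
                for phase, m in cond.items():
                    mult[phase] = mult[phase] * m
            else:
                mult = {ph: m * float(cond) for ph, m in mult.items()}
        bounds = [
            ("pre_fixation", spec.t0_ms + EPOCH_SPAN_MS[0], spec.t0_ms),
            ("fixation_to_target", spec.t0_ms, spec.visual_ms),
            ("suppression", spec.visual_ms, spec.response_ms),
            ("rebound", spec.response_ms, spec.t0_ms + EPOCH_SPAN_MS[1]),
        ]
        for phase, lo, hi in bounds:
            rate[idx(lo) : idx(hi)] = lam0 * mult[phase]
        windows = _condition_factor(params.condition_windows, spec)
        for lo, hi, m in windows or ():
            rate[idx(spec.t0_ms + lo) : idx(spec.t0_ms + hi)] *= m
    return rate


def simulate_sway(
    trial_events: Sequence[TrialEventsSpec],
    params: SwayParams,
    seed: int,
    participant=None,
) -> ForcePlateRecording:
    """Simulate a continuous force-plate recording for a list of trials.

    Mx and My are OU baseline noise plus Gaussian-shaped corrective
    impulses (random sign per axis, shared event times) drawn from a
    discretised inhomogeneous Poisson process with rate
    λ(t) = λ0 x phase multiplier x condition multiplier.  Trigger markers
    are embedded at cue, visual-target, auditory-target and response
    onsets.  Fz carries a constant body-weight placeholder.
    """
    if not trial_events:
        raise ParameterError("trial_events must not be empty")
    fs = params.sample_rate
    specs = sorted(trial_events, key=lambda s: s.t0_ms)
    if specs[0].t0_ms + EPOCH_SPAN_MS[0] < 0:
        raise LayoutError(
            f"first trial at {specs[0].t0_ms} ms leaves no room for the "
            f"{EPOCH_SPAN_MS[0]} ms epoch padding"
        )
    for prev, nxt in zip(specs, specs[1:]):
        if nxt.t0_ms + EPOCH_SPAN_MS[0] < prev.t0_ms + EPOCH_SPAN_MS[1]:
            raise LayoutError(
                f"trials {prev.trial} and {nxt.trial} overlap: epochs span "
                f"{EPOCH_SPAN_MS} ms around each cue onset"
            )
        if nxt.t0_ms <= prev.response_ms:
            raise LayoutError(f"trial {nxt.trial} starts before trial {prev.trial} ends")
    n = int(round((specs[-1].t0_ms + EPOCH_SPAN_MS[1] + 500.0) * fs / 1000.0)) + 1

    rng = np.random.default_rng(seed)
    mx = ou_noise(n, params.baseline_sigma, params.baseline_tau_ms, fs, rng)
    my = ou_noise(n, params.baseline_sigma, params.baseline_tau_ms, fs, rng)

    rate = _rate_vector(n, specs, params)
    hits = np.flatnonzero(rng.random(n) < rate / fs)
    if hits.size and params.impulse_amplitude != 0:
        sd = params.impulse_width_ms / 5.0 * fs / 1000.0  # samples
        half = int(round(params.impulse_width_ms / 2.0 * fs / 1000.0))
        offs = np.arange(-half, half + 1)
        kernel = params.impulse_amplitude * np.exp(-0.5 * (offs / sd) ** 2)
        signs = rng.choice([-1.0, 1.0], size=(hits.size, 2))
        for k, center in enumerate(hits):
            lo = max(center - half, 0)
            hi = min(center + half + 1, n)
            seg = kernel[lo - (center - half) : hi - (center - half)]
            mx[lo:hi] += signs[k, 0] * seg
            my[lo:hi] += signs[k, 1] * seg

    samples = pd.DataFrame(
        {
            "Fx": np.zeros(n),
            "Fy": np.zeros(n),
            "Fz": np.full(n, 686.7),  # ~70 kg standing weight
            "Mx": mx,
            "My": my,
            "Mz": np.zeros(n),
        }
    )
    events = []
    for spec in specs:
        for code, t_ms in spec.event_times().items():
            events.append(EventMarker(spec.trial, code, int(round(t_ms * fs / 1000.0))))
    return ForcePlateRecording(
        sample_rate=fs, samples=samples, events=events, participant=participant
    )


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

#: cue-onset spacing between consecutive trials in simulated recordings.
#: Must exceed the 3,600-ms padded epoch span; 4,500 ms approximates the
#: actual trial pacing (response + feedback + vocal response + ITI).
TRIAL_SPACING_MS = 4500.0


def trial_events_from_table(
    trials: pd.DataFrame, spacing_ms: float = TRIAL_SPACING_MS, start_ms: float = 1000.0
) -> list[TrialEventsSpec]:
    """Lay one participant's trials out in recording time, in table order."""
    specs = []
    for i, row in enumerate(trials.itertuples()):
        specs.append(
            TrialEventsSpec(
                trial=int(row.trial) if trials["trial"].is_unique else i + 1,
                t0_ms=start_ms + i * spacing_ms,
                soa_ms=float(row.soa),
                rt_ms=float(row.rt_ms),
                task_load=str(row.task_load),
            )
        )
    return specs


def make_study(
    experiment: int = 1,
    behavior: BehaviorParams | None = None,
    sway: SwayParams | None = None,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Simulate a full study: behavioral table plus one recording per participant.

    Within each participant's recording, trials are laid out block after
    block with :data:`TRIAL_SPACING_MS` between cue onsets and trial ids
    renumbered consecutively (unique within participant).  Returns
    ``(recordings, trials)`` where ``recordings`` maps participant id to
    :class:`~erfp.io.ForcePlateRecording`.
    """
    if experiment not in (1, 2):
        raise DesignError(f"experiment must be 1 or 2, got {experiment}")
    if behavior is None:
        behavior = (
            BehaviorParams.experiment1() if experiment == 1 else BehaviorParams.experiment2()
        )
    if experiment == 2 and set(behavior.task_loads) != {"report", "ignore"}:
        raise DesignError("experiment 2 requires task loads {'report', 'ignore'}")
    sway = sway or SwayParams()
    trials = simulate_behavior(behavior, seed=seed)
    # unique trial ids within participant for event bookkeeping
    trials["trial"] = trials.groupby("participant").cumcount() + 1
    recordings = {}
    for k, (p, sub) in enumerate(trials.groupby("participant", sort=True)):
        specs = trial_events_from_table(sub)
        recordings[p] = simulate_sway(
            specs, sway, seed=np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31),
            participant=p,
        )
    return recordings, trials
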