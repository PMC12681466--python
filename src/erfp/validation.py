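"""Simulation-based validation of the analysis chain.

Two study-level simulations exercise the full pipeline (sway generation,
zero-phase filtering, epoching, sliding-window variability, cluster
permutation test):

* :func:`null_fwer` — familywise type-I error under the null: both
  "conditions" of every participant are drawn from the identical sway
  process, so any significant cluster is a false positive.
* :func:`recovery_rate` — power/localisation: one condition carries a known
  suppression of the corrective-impulse rate inside a fixed window, and the
  significant cluster is compared with that window by temporal Jaccard
  overlap.

Both use identical trial timing in the two conditions (same SOA, same
response latency) so that condition differences can come only from the
embedded rate manipulation, never from event-time confounds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cluster import PairedDesign, PermutationConfig, permutation_test
from .preprocess import butterworth_lowpass, segment
from .synth import SwayParams, TrialEventsSpec, simulate_sway
from .variability import epoch_variability

_SPACING_MS = 4500.0
_PAD_WINDOW = (-550.0, 3050.0)
_ANALYSIS_WINDOW = (-500.0, 3000.0)


def _sub_seed(*path) -> int:
    return int(np.random.SeedSequence(list(path)).generate_state(1)[0] % (2**31))


def condition_pair_means(
    seed: int,
    sway: SwayParams,
    trials_per_condition: int,
    windows_a=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One participant's mean variability series for two interleaved conditions.

    Trials alternate between condition labels ``a`` and ``b`` with identical
    timing (SOA 1,000 ms, 650-ms response).  ``windows_a`` optionally embeds
    rate-multiplier windows ``(start_ms, end_ms, mult)`` into condition ``a``
    trials only.  Returns ``(times_ms, mean_a, mean_b)``.
    """
    specs = [
        TrialEventsSpec(
            trial=i + 1,
            t0_ms=1000.0 + i * _SPACING_MS,
            soa_ms=1000.0,
            rt_ms=650.0,
            task_load="a" if i % 2 == 0 else "b",
        )
        for i in range(2 * trials_per_condition)
    ]
    params = replace(
        sway, condition_windows={"a": list(windows_a)} if windows_a else {}
    )
    rec = simulate_sway(specs, params, seed=seed)
    fs = rec.sample_rate
    filtered = rec.samples.assign(
        Mx=butterworth_lowpass(rec.channel("Mx"), fs),
        My=butterworth_lowpass(rec.channel("My"), fs),
    )
    rec = replace_samples(rec, filtered)
    epochs = segment(rec, window_ms=_PAD_WINDOW)
    by_cond = {"a": [], "b": []}
    for ep, spec in zip(epochs, specs):
        series = epoch_variability(
            ep, sample_rate=fs, analysis_window_ms=_ANALYSIS_WINDOW
        )
        by_cond[spec.task_load].append(series.values)
        times = series.times_ms
    return times, np.mean(by_cond["a"], axis=0), np.mean(by_cond["b"], axis=0)


def replace_samples(rec, samples):
    """Recording with the same events/rate but new channel samples."""
    from .io import ForcePlateRecording

    return ForcePlateRecording(
        sample_rate=rec.sample_rate,
        samples=samples,
        events=rec.events,
        participant=rec.participant,
    )


def build_paired_design(
    dataset_seed_path, n_participants, trials_per_condition, sway, windows_a=None
) -> PairedDesign:
    rows_a, rows_b = [], []
    for p in range(n_participants):
        times, ma, mb = condition_pair_means(
            _sub_seed(*dataset_seed_path, p), sway, trials_per_condition, windows_a
        )
        rows_a.append(ma)
        rows_b.append(mb)
    return PairedDesign(times_ms=times, a=np.array(rows_a), b=np.array(rows_b))


def null_fwer(
    n_datasets: int = 200,
    n_participants: int = 24,
    trials_per_condition: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
    sway: SwayParams | None = None,
) -> dict:
    """Empirical familywise type-I error of the cluster permutation test.

    Every dataset draws both conditions of every participant from the same
    sway process; the returned ``fwer`` is the fraction of datasets whose
    smallest cluster p-value is <= ``alpha``.  Also reports the upper 95%
    binomial bound of the nominal level for the given number of datasets.
    """
    sway = sway or SwayParams()
    hits = 0
    for d in range(n_datasets):
        design = build_paired_design((seed, d), n_participants, trials_per_condition, sway)
        clusters, _ = permutation_test(
            design,
            PermutationConfig(n_perm=n_perm, seed=_sub_seed(seed, d, 9999), alpha=alpha),
        )
        if clusters and min(c.p_value for c in clusters) <= alpha:
            hits += 1
    # normal-approximation upper bound on the observed rate if the true rate
    # were the nominal alpha
    bound = alpha + 1.645 * np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {
        "fwer": hits / n_datasets,
        "n_datasets": n_datasets,
        "alpha": alpha,
        "binomial_upper_bound": float(bound),
    }


def temporal_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard overlap of two closed time intervals."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0.0, hi - lo)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def recovery_rate(
    n_replicates: int = 20,
    n_participants: int = 24,
    trials_per_condition: int = 80,
    window_ms: tuple[float, float] = (1600.0, 2000.0),
    rate_multiplier: float = 0.4,
    jaccard_threshold: float = 0.3,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 1,
    sway: SwayParams | None = None,
) -> dict:
    """Recovery of an embedded condition-specific suppression window.

    Condition ``a`` trials have their corrective-impulse rate scaled by
    ``rate_multiplier`` inside ``window_ms``; a replicate counts as a
    recovery when its most significant cluster is significant and overlaps
    the embedded window with temporal Jaccard >= ``jaccard_threshold``.
    """
    sway = sway or SwayParams()
    windows_a = [(window_ms[0], window_ms[1], rate_multiplier)]
    jaccards = []
    recovered = 0
    for r in range(n_replicates):
        design = build_paired_design(
            (seed, 7000 + r), n_participants, trials_per_condition, sway, windows_a
        )
        clusters, _ = permutation_test(
            design,
            PermutationConfig(n_perm=n_perm, seed=_sub_seed(seed, r, 777), alpha=alpha),
        )
        significant = [c for c in clusters if c.p_value <= alpha]
        if significant:
            best = min(significant, key=lambda c: c.p_value)
            j = temporal_jaccard((best.start_ms, best.end_ms), window_ms)
        else:
            j = 0.0
        jaccards.append(j)
        recovered += j >= jaccard_threshold
    return {
        "recovery_rate": recovered / n_replicates,
        "jaccards": jaccards,
        "n_replicates": n_replicates,
        "jaccard_threshold": jaccard_threshold,
    }
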