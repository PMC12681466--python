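"""Cluster-based permutation test for paired variability time courses.

At every time point a one-sample t statistic of the paired condition
difference is computed; contiguous runs of same-sign samples whose |t|
exceeds the cluster-forming threshold become clusters, scored by their mass
(sum of t values).  The null distribution of the maximum |mass| is built by
independently flipping the sign of each participant's difference series —
equivalent to exchanging the condition labels within participants — which
controls the familywise error rate over the whole time base and both signs
jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, DegenerateInputError, ParameterError
from .variability import ConditionTimeCourse


@dataclass
class PairedDesign:
    """Per-participant pair of condition time courses on one time base.

    ``a`` and ``b`` are (N participants x T time points) arrays of the two
    conditions' variability series.
    """

    times_ms: np.ndarray
    a: np.ndarray
    b: np.ndarray
    participants: list = field(default_factory=list)

    def __post_init__(self):
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise AlignmentError("condition matrices must have identical shape")
        if self.a.shape[1] != len(self.times_ms):
            raise AlignmentError("time base length does not match data")
        if self.a.shape[0] < 2:
            raise DegenerateInputError("paired design needs >= 2 participants")

    @property
    def n_participants(self) -> int:
        return self.a.shape[0]

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    @classmethod
    def from_timecourses(
        cls,
        timecourses: Sequence[ConditionTimeCourse],
        condition_a: tuple,
        condition_b: tuple,
    ) -> "PairedDesign":
        """Assemble a paired design from aggregated condition time courses."""
        table = {(tc.participant, tc.condition): tc for tc in timecourses}
        participants = sorted({tc.participant for tc in timecourses}, key=str)
        rows_a, rows_b = [], []
        base = None
        for p in participants:
            try:
                ta, tb = table[(p, condition_a)], table[(p, condition_b)]
            except KeyError as exc:
                raise AlignmentError(f"participant {p} missing condition {exc}") from None
            if base is None:
                base = ta.series.times_ms
            rows_a.append(ta.series.values)
            rows_b.append(tb.series.values)
        return cls(times_ms=base, a=np.array(rows_a), b=np.array(rows_b),
                   participants=list(participants))


@dataclass
class PermutationConfig:
    """Settings of the permutation scheme.

    ``n_perm`` may be the string ``'exhaustive'`` to enumerate all 2^N
    sign-flip patterns (exact test).  ``cluster_alpha`` sets the two-sided
    cluster-forming threshold; ``alpha`` flags significant clusters.
    """

    n_perm: int | str = 2000
    seed: int | None = None
    alpha: float = 0.05
    cluster_alpha: float = 0.05

    def __post_init__(self):
        if self.n_perm != "exhaustive" and int(self.n_perm) < 1:
            raise ParameterError("n_perm must be >= 1 or 'exhaustive'")
        for name in ("alpha", "cluster_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class ClusterResult:
    """A contiguous suprathreshold window with its mass and permutation p."""

    start_ms: float
    end_ms: float  # inclusive
    mass: float
    sign: str  # '+' or '-'
    p_value: float
    start_index: int = 0
    end_index: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _t_one_sample(d: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t over axis 0; zero-variance points give t = 0."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def pointwise_paired_t(design: PairedDesign) -> np.ndarray:
    """t statistic of the paired differences at each time point (df = N-1)."""
    return _t_one_sample(design.differences)


def form_clusters(
    t: np.ndarray, df: int, cluster_alpha: float = 0.05
) -> list[tuple[int, int, float, int]]:
    """Maximal same-sign runs with |t| above the two-sided critical value.

    Returns (start_index, end_index inclusive, mass, sign) tuples; a sign
    change splits a run even if |t| stays suprathreshold.
    """
    threshold = stats.t.ppf(1.0 - cluster_alpha / 2.0, df=df)
    return _clusters_above(np.asarray(t, dtype=float), threshold)


def _clusters_above(t: np.ndarray, threshold: float) -> list[tuple[int, int, float, int]]:
    sign = np.where(t > threshold, 1, np.where(t < -threshold, -1, 0))
    if not sign.any():
        return []
    change = np.flatnonzero(np.diff(sign)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [sign.size]))  # exclusive
    csum = np.concatenate(([0.0], np.cumsum(t)))
    return [
        (int(s), int(e - 1), float(csum[e] - csum[s]), int(sign[s]))
        for s, e in zip(starts, ends)
        if sign[s] != 0
    ]


def _max_null_masses(
    d: np.ndarray, signs: np.ndarray, threshold: float
) -> np.ndarray:
    """Max |cluster mass| per sign-flip pattern, vectorised over patterns.

    Under sign flips the per-point second moment of the differences is
    unchanged, so only the flipped means vary across patterns.
    """
    n = d.shape[0]
    mean_sq = (d * d).mean(axis=0)  # (T,)
    m = signs @ d / n  # (P, T)
    var = (mean_sq - m * m) * (n / (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t = np.where(var > 0, t, 0.0)
    out = np.empty(signs.shape[0])
    for k in range(signs.shape[0]):
        clusters = _clusters_above(t[k], threshold)
        out[k] = max((abs(c[2]) for c in clusters), default=0.0)
    return out


def permutation_test(
    design: PairedDesign, config: PermutationConfig = PermutationConfig()
) -> tuple[list[ClusterResult], np.ndarray]:
    """Cluster-based permutation test of a paired two-condition contrast.

    Returns the observed clusters with their permutation p-values and the
    null distribution of maximum |cluster mass|.  With randomized
    permutations, p = (1 + #{null >= observed}) / (n_perm + 1); with
    ``n_perm='exhaustive'`` all 2^N patterns (including identity) are
    enumerated and p = #{null >= observed} / 2^N exactly.  Ties count as
    exceedances.  Reproducible given ``config.seed``.
    """
    d = design.differences
    n, n_time = d.shape
    df = n - 1
    threshold = stats.t.ppf(1.0 - config.cluster_alpha / 2.0, df=df)
    t_obs = _t_one_sample(d)
    observed = _clusters_above(t_obs, threshold)

    if config.n_perm == "exhaustive":
        if n > 20:
            raise ParameterError("exhaustive enumeration limited to N <= 20")
        patterns = np.array(
            [[1 if (k >> i) & 1 == 0 else -1 for i in range(n)] for k in range(2**n)],
            dtype=float,
        )
        null = _max_null_masses(d, patterns, threshold)
        denom = float(len(null))
        add = 0.0
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(int(config.n_perm), n))
        null = _max_null_masses(d, signs, threshold)
        denom = float(config.n_perm) + 1.0
        add = 1.0

    results = []
    for start, end, mass, sign in observed:
        p = (add + float(np.sum(null >= abs(mass) - 1e-12))) / denom
        results.append(
            ClusterResult(
                start_ms=float(design.times_ms[start]),
                end_ms=float(design.times_ms[end]),
                mass=mass,
                sign="+" if sign > 0 else "-",
                p_value=min(p, 1.0),
                start_index=start,
                end_index=end,
            )
        )
    results.sort(key=lambda c: c.p_value)
    return results, null
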