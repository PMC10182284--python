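"""Nonparametric change-point detection of rotary pauses.

A rotary trace of a stepping motor is piecewise constant (a pause) with
abrupt transitions.  The boundaries are found without any noise model:

1. For a segment ``x_1..x_n`` the CUSUM series
   ``CUSUM(t) = sum_{t'<=t} (x_t' - xbar)`` fluctuates strongly when a
   level shift is present; its range ``D = max(CUSUM) - min(CUSUM)`` is
   the test statistic.
2. A permutation test (uniform random shufflings of the segment) gives a
   p-value for "no change point"; if rejected, the change point is placed
   at the split minimising the total squared error around the left and
   right segment means.
3. Recursive binary segmentation repeats the test on both halves until no
   further change point is significant.
4. A cleanup pass merges adjacent intervals whose median angles differ by
   less than ``A * (MAD_i + MAD_{i+1})``; the factor A is chosen by
   sweeping it upward and stopping just before the squared error between
   the raw trace and the interval-median (denoised) trace rises sharply —
   beyond that point genuine steps start being merged.

Medians and median absolute deviations are used for the cleanup and all
downstream statistics because they are robust to outliers; change-point
localisation itself uses least-squares means.  All indices are 0-based
with half-open ``[start, stop)`` intervals; a change point at index k
separates ``[.., k)`` from ``[k, ..)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import RotaryTrace

__all__ = [
    "Segment",
    "CPInterval",
    "CPResult",
    "cusum_series",
    "cusum_statistic",
    "permutation_test",
    "locate_changepoint",
    "detect_changepoints",
    "merge_intervals",
    "a_factor_sweep",
    "select_A",
    "intervals_from_changepoints",
]

# elements processed per vectorised permutation batch (memory/speed tradeoff)
_BATCH_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class Segment:
    """A view into a parent trace: values ``x[start:stop]``."""

    values: np.ndarray
    start: int = 0
    stop: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.stop is None:
            object.__setattr__(self, "stop", self.start + len(self.values))
        if self.stop - self.start != len(self.values):
            raise ValueError("segment bounds inconsistent with values length")


@dataclass
class CPInterval:
    """A pause candidate between consecutive change points."""

    start: int
    stop: int
    median_angle: float
    mad: float

    @property
    def n(self) -> int:
        return self.stop - self.start

    @classmethod
    def from_values(cls, values: np.ndarray, start: int, stop: int) -> "CPInterval":
        seg = values[start:stop]
        med = float(np.median(seg))
        mad = float(np.median(np.abs(seg - med)))
        return cls(start=start, stop=stop, median_angle=med, mad=mad)


@dataclass
class CPResult:
    """Outcome of detection on one trace."""

    changepoints: list[int]
    intervals: list[CPInterval]
    params: dict = field(default_factory=dict)


def cusum_series(values: np.ndarray) -> np.ndarray:
    """Cumulative sum of deviations from the segment mean.

    The last element is 0 up to rounding (telescoping identity)."""
    values = np.asarray(values, dtype=float)
    return np.cumsum(values - values.mean())


def cusum_statistic(values: np.ndarray) -> float:
    """Range of the CUSUM series: ``D = max(CUSUM) - min(CUSUM)`` >= 0."""
    c = cusum_series(values)
    return float(c.max() - c.min())


def _batched_exceedances(
    centered: np.ndarray,
    d_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    stop_count: int | None = None,
) -> tuple[int, int]:
    """Count permutations whose CUSUM range reaches ``d_obs``.

    Permutations are drawn in vectorised batches.  If ``stop_count`` is
    given, stop as soon as that many exceedances have been seen (used by
    the segmentation loop, where only the accept/reject decision at the
    significance level matters — once the count guarantees non-rejection
    the remaining permutations cannot change the decision).

    Returns (exceedances, permutations actually drawn).
    """
    n = centered.size
    batch = int(np.clip(_BATCH_ELEMENTS // max(n, 1), 1, n_perm))
    count = 0
    done = 0
    thresh = d_obs * (1.0 - 1e-12)
    while done < n_perm:
        b = min(batch, n_perm - done)
        block = rng.permuted(np.broadcast_to(centered, (b, n)), axis=1)
        np.cumsum(block, axis=1, out=block)
        d = block.max(axis=1) - block.min(axis=1)
        count += int(np.count_nonzero(d >= thresh))
        done += b
        if stop_count is not None and count >= stop_count:
            break
    return count, done


def permutation_test(
    segment: Segment | np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the presence of a change point.

    The null hypothesis is that the segment has no change point, so its
    values are exchangeable; the test statistic is the CUSUM range D.
    The add-one estimator ``p = (1 + #{D_perm >= D_obs}) / (1 + n_perm)``
    is used, so p is always in (0, 1].
    """
    values = segment.values if isinstance(segment, Segment) else np.asarray(segment, float)
    if values.size < 2:
        raise ValueError("permutation test requires at least 2 samples")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centered = values - values.mean()
    d_obs = cusum_statistic(values)
    count, done = _batched_exceedances(centered, d_obs, n_perm, rng)
    return (1 + count) / (1 + done)


def locate_changepoint(segment: Segment | np.ndarray) -> int:
    """Split index k minimising the two-mean total squared error.

    ``SSE(k) = sum_{t<k}(x_t - mean_left)^2 + sum_{t>=k}(x_t - mean_right)^2``
    over k in [1, n-1]; ties break toward the smallest k.  Computed in
    O(n) from prefix sums.
    """
    values = segment.values if isinstance(segment, Segment) else np.asarray(segment, float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 samples to place a change point")
    c1 = np.cumsum(values)
    c2 = np.cumsum(values * values)
    k = np.arange(1, n)
    left_ss = c2[k - 1] - c1[k - 1] ** 2 / k
    right_sum = c1[-1] - c1[k - 1]
    right_ss = (c2[-1] - c2[k - 1]) - right_sum**2 / (n - k)
    sse = left_ss + right_ss
    return int(np.argmin(sse)) + 1  # argmin returns first minimum -> smallest k


def intervals_from_changepoints(values: np.ndarray, changepoints: list[int]) -> list[CPInterval]:
    """Tile ``[0, len)`` into intervals bounded by the change points."""
    values = np.asarray(values, dtype=float)
    bounds = [0] + sorted(changepoints) + [values.size]
    return [
        CPInterval.from_values(values, a, b) for a, b in zip(bounds, bounds[1:])
    ]


def detect_changepoints(
    trace: RotaryTrace | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.01,
    min_seg: int = 5,
    seed: int = 0,
) -> CPResult:
    """Recursive binary segmentation of a rotary trace.

    Each candidate segment is tested with the CUSUM permutation test; when
    ``p < alpha`` a change point is placed by least-squares localisation
    and both halves are re-examined.  Recursion stops when the test fails
    or a segment is shorter than ``2 * min_seg``.  A single seeded
    generator drives all permutations, consumed in a deterministic
    traversal order, so results are reproducible end-to-end.
    """
    values = trace.angle if isinstance(trace, RotaryTrace) else np.asarray(trace, float)
    if values.size < 2 * min_seg:
        raise ValueError("trace shorter than 2 * min_seg")
    rng = np.random.default_rng(seed)
    # smallest exceedance count for which p >= alpha is already certain
    stop_count = int(np.ceil(alpha * (1 + n_perm) - 1))
    cps: list[int] = []
    stack: list[tuple[int, int]] = [(0, values.size)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_seg:
            continue
        seg = values[a:b]
        if np.ptp(seg) == 0.0:  # degenerate: identical values, no CP
            continue
        centered = seg - seg.mean()
        d_obs = cusum_statistic(seg)
        count, done = _batched_exceedances(centered, d_obs, n_perm, rng, stop_count=stop_count)
        p = (1 + count) / (1 + n_perm)
        if done == n_perm and p < alpha:
            k = a + locate_changepoint(seg)
            cps.append(k)
            # LIFO right-then-left gives left-to-right deterministic order
            stack.append((k, b))
            stack.append((a, k))
    cps.sort()
    return CPResult(
        changepoints=cps,
        intervals=intervals_from_changepoints(values, cps),
        params={
            "n_perm": n_perm,
            "alpha": alpha,
            "min_seg": min_seg,
            "seed": seed,
        },
    )


def merge_intervals(
    values: np.ndarray, intervals: list[CPInterval], A: float
) -> list[CPInterval]:
    """Remove change points between similar adjacent intervals.

    The CP between intervals i and i+1 is removed when
    ``|median_i - median_{i+1}| < A * (MAD_i + MAD_{i+1})``.  The sweep is
    left-to-right; a merged interval's median and MAD are recomputed from
    the pooled samples, and sweeping repeats until a full pass removes
    nothing.  Intervals must tile the trace and remain a tiling.
    """
    if A < 0:
        raise ValueError("A must be >= 0")
    values = np.asarray(values, dtype=float)
    current = list(intervals)
    changed = True
    while changed:
        changed = False
        merged: list[CPInterval] = []
        for itv in current:
            if merged and abs(merged[-1].median_angle - itv.median_angle) < A * (
                merged[-1].mad + itv.mad
            ):
                merged[-1] = CPInterval.from_values(values, merged[-1].start, itv.stop)
                changed = True
            else:
                merged.append(itv)
        current = merged
    return current


def _denoised(values: np.ndarray, intervals: list[CPInterval]) -> np.ndarray:
    out = np.empty_like(values)
    for itv in intervals:
        out[itv.start : itv.stop] = itv.median_angle
    return out


def a_factor_sweep(
    values: np.ndarray | RotaryTrace,
    intervals: list[CPInterval],
    A_grid: np.ndarray,
) -> list[tuple[float, float]]:
    """Squared error of the denoised trace as the merge factor A grows.

    For each A the original intervals are merged, the denoised trace is
    the per-sample interval median, and the error is
    ``sum (x_t - denoised_t)^2``.  Small A removes only spurious change
    points (error barely grows); past some A genuine steps merge and the
    error jumps — the basis for :func:`select_A`.
    """
    values = values.angle if isinstance(values, RotaryTrace) else np.asarray(values, float)
    A_grid = np.asarray(A_grid, dtype=float)
    if A_grid.size < 3 or np.any(np.diff(A_grid) <= 0):
        raise ValueError("A_grid must be ascending with at least 3 values")
    curve = []
    for A in A_grid:
        merged = merge_intervals(values, intervals, float(A))
        err = float(np.sum((values - _denoised(values, merged)) ** 2))
        curve.append((float(A), err))
    return curve


def select_A(curve: list[tuple[float, float]], rel_jump: float = 0.02) -> float:
    """Pick the merge factor just before the sudden error increase.

    Merging spurious change points barely changes the denoised trace, so
    the squared error stays near the baseline residual of the raw
    segmentation; once genuine steps start merging, each grid step adds
    error comparable to the baseline itself.  ``A*`` is therefore the
    largest grid value before the first increment exceeding ``rel_jump``
    times the baseline (first-grid-point) error.  The increase is judged
    against the baseline rather than the curve's total range because once
    A is large enough to merge everything the error explodes by orders of
    magnitude and would mask the onset of the rise.  A flat curve (or one
    whose rise lies beyond the grid) falls back to the largest grid value.
    """
    if not curve:
        raise ValueError("empty A-sweep curve")
    A_vals = [a for a, _ in curve]
    errs = np.array([e for _, e in curve])
    if errs[-1] - errs[0] <= 0:
        return A_vals[-1]
    inc = np.diff(errs)
    thresh = rel_jump * errs[0] + 1e-12 * errs[-1]
    big = np.nonzero(inc > thresh)[0]
    if big.size == 0:
        return A_vals[-1]
    return A_vals[int(big[0])]
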