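"""Pause-level analysis of change-point intervals.

After change-point detection and cleanup, each surviving interval is a
candidate pause.  The number of pauses per turn is read from the angular
histogram of interval *medians* — each interval counts once, regardless of
its length, so even brief pauses register.  Two histogram-level filters
precede counting: intervals shorter than 7 frames are dropped, and
intervals that differ from both neighbours by less than 40 degrees without
a progressive (monotone forward) angle sequence are removed as backsteps
or residual fluctuations.

Six pauses per turn indicate a sub-pause between successive main pauses.
Because the spacing of main pauses fluctuates around 120 degrees (probe
tilt etc.), sub-pause position is quantified by the angular distance
ratio a/b: the distance from a main pause to the following sub-pause (a)
over the distance from that sub-pause to the next main pause (b).  TF1
geometry (sub 40 degrees after main) gives ~0.5; bMF1 geometry (sub
midway) gives ~1.0.  Mean ratios of different motors are compared by
average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .changepoint import CPInterval

__all__ = [
    "PauseSummary",
    "interval_angle_histogram",
    "filter_short_intervals",
    "filter_nonprogressive",
    "count_pauses_per_turn",
    "classify_stepper",
    "label_main_sub",
    "angular_distance_ratio",
    "mean_ratio",
    "cluster_ratios",
]


@dataclass
class PauseSummary:
    """Per-molecule pause structure evidence."""

    peak_angles: list[float]
    labels: list[str]  # "main" | "sub" per peak, aligned with peak_angles
    n_pauses_per_turn: int
    ratios: list[float]
    mean_ratio: float | None
    mean_ratio_se: float | None
    stepper_class: str
    notes: list[str] = field(default_factory=list)


def interval_angle_histogram(
    intervals: list[CPInterval], bin_width: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of interval median angles folded to [0, 360).

    Each interval contributes exactly one count at its median angle, so
    the histogram weights pauses equally irrespective of dwell length.

    Returns (counts, bin_edges) with ``len(edges) == len(counts) + 1``.
    """
    if not intervals:
        raise ValueError("no intervals to histogram")
    medians = np.mod([itv.median_angle for itv in intervals], 360.0)
    n_bins = int(np.ceil(360.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(medians, bins=edges)
    return counts, edges


def filter_short_intervals(
    intervals: list[CPInterval], min_len: int = 7
) -> list[CPInterval]:
    """Drop intervals shorter than ``min_len`` frames (default 7).

    This is a histogram-level filter: survivors are returned unchanged and
    the tiling of the trace is intentionally broken.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [itv for itv in intervals if itv.n >= min_len]


def filter_nonprogressive(
    intervals: list[CPInterval], thresh: float = 40.0
) -> list[CPInterval]:
    """Remove backsteps and residual fluctuations.

    An interior interval is removed when it sits within ``thresh`` degrees
    of its nearer temporal neighbour (unwrapped medians) and the three
    consecutive medians do not increase strictly monotonically in the
    rotation direction — i.e. it is a small backward or sideways excursion
    rather than a genuine forward pause.  A genuine forward step of at
    least ``thresh`` degrees on *both* sides is always kept, as is any
    progressive (strictly increasing) triple.  The first and last
    intervals are kept: a backstep cannot be judged from a single
    neighbour.  Removal decisions are taken simultaneously on the
    original sequence.
    """
    m = [itv.median_angle for itv in intervals]
    n = len(intervals)
    if n <= 2:
        return list(intervals)
    keep = np.ones(n, dtype=bool)
    for i in range(1, n - 1):
        close = min(abs(m[i] - m[i - 1]), abs(m[i + 1] - m[i])) < thresh
        progressive = m[i - 1] < m[i] < m[i + 1]
        if close and not progressive:
            keep[i] = False
    return [itv for itv, k in zip(intervals, keep) if k]


def _circular_gap_clusters(angles: np.ndarray, gap: float) -> list[np.ndarray]:
    """Single-linkage clustering of angles in [0, 360) by circular gaps.

    Sorted angles are cut wherever the circular spacing to the next angle
    is >= gap; returns index arrays into ``angles``, ordered by cluster
    mean angle.
    """
    order = np.argsort(angles)
    srt = angles[order]
    n = srt.size
    gaps = np.diff(np.concatenate([srt, [srt[0] + 360.0]]))
    cut_after = np.nonzero(gaps >= gap)[0]
    if cut_after.size == 0:
        return [order]
    clusters = []
    starts = (cut_after + 1) % n
    for s, e in zip(np.roll(cut_after + 1, 1), cut_after + 1):
        idx = np.arange(s, e) if s < e else np.concatenate([np.arange(s, n), np.arange(0, e)])
        clusters.append(order[idx])
    # order clusters by circular mean for a deterministic presentation
    means = [_circular_mean(angles[c]) for c in clusters]
    return [c for _, c in sorted(zip(means, clusters), key=lambda t: t[0])]


def _circular_mean(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    ang = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    out = float(np.mod(ang, 360.0))
    return 0.0 if out >= 360.0 else out  # guard the float edge mod(-eps, 360)


def count_pauses_per_turn(
    intervals: list[CPInterval],
    gap: float = 20.0,
    min_members: int | None = None,
    bin_width: float = 3.0,
    rel_floor: float = 0.05,
) -> tuple[int, list[float]]:
    """Count significant peaks in the folded angular histogram.

    Interval medians (mod 360) are binned at ``bin_width`` degrees; bins
    holding fewer than ``rel_floor`` of the tallest bin's count are
    treated as empty, so a handful of straggler intervals (e.g. residual
    merged transitions) cannot chain two genuine peaks together.  The
    occupied bins are then clustered by single linkage with a circular
    ``gap`` threshold, and clusters whose member intervals number at
    least ``min_members`` (default ``max(2, 1% of intervals)``) are
    significant peaks.

    Returns (number of significant peaks, circular mean angle per peak).
    A count of 0 signals an ambiguous molecule, not an error.
    """
    if not intervals:
        return 0, []
    if min_members is None:
        min_members = max(2, int(0.01 * len(intervals)))
    medians = np.mod([itv.median_angle for itv in intervals], 360.0)
    n_bins = int(np.ceil(360.0 / bin_width))
    edges = np.arange(n_bins + 1) * (360.0 / n_bins)
    counts, _ = np.histogram(medians, bins=edges)
    floor = max(1.0, rel_floor * counts.max())
    occupied = np.nonzero(counts >= floor)[0]
    if occupied.size == 0:
        return 0, []
    centers = (edges[occupied] + edges[occupied + 1]) / 2.0
    bin_clusters = _circular_gap_clusters(centers, gap)
    bin_of = np.clip(np.digitize(medians, edges) - 1, 0, n_bins - 1)
    peaks = []
    for c in bin_clusters:
        members = np.isin(bin_of, occupied[c])
        if members.sum() >= min_members:
            peaks.append(_circular_mean(medians[members]))
    return len(peaks), sorted(peaks)


def classify_stepper(n_at_km: int, n_at_sat: int | None = None) -> tuple[str, str]:
    """Stepper class from pause counts at Km and at saturation.

    Three pauses at Km mean binding and catalytic waits share an angle —
    a 3-stepper.  Six (or more) pauses at Km leave a 6-vs-9 ambiguity that
    the saturating-condition count addresses: a 9-stepper still shows 6
    pauses at saturation (catalytic + short dwells) while a plain
    6-stepper collapses to 3.  The saturating count is *evidence only*:
    extra sub-pauses such as the temperature-sensitive dwell can make a
    genuine 6-stepper show 6 pauses at saturation, so final discrimination
    defers to the angular distance ratio.

    Returns (class, evidence note); class is one of
    ``"3" | "6" | "9" | "6-or-9" | "ambiguous"``.
    """
    if n_at_km == 3:
        return "3", "3 pauses at Km: binding and catalytic waits share angles"
    if n_at_km >= 6:
        if n_at_sat is None:
            return "6-or-9", "≥6 pauses at Km; saturating-condition count needed"
        if n_at_sat == 6:
            return (
                "9",
                "candidate only: 6 pauses at saturation; a TS-type sub-pause can "
                "mimic this in a 6-stepper — confirm with the a/b ratio",
            )
        if n_at_sat == 3:
            return "6", "candidate: collapses to 3 pauses at saturation"
        return "ambiguous", f"unexpected saturating count {n_at_sat}"
    return "ambiguous", f"unexpected Km-condition count {n_at_km}"


def label_main_sub(
    peak_angles: list[float], intervals: list[CPInterval]
) -> tuple[list[str], list[float]]:
    """Label 6 peaks per turn as main or sub by occupancy.

    With six alternating peaks, the three peaks (one per 120-degree
    repeat) whose assigned intervals carry the larger total occupancy
    (summed frame counts) are main; occupancy ties break toward the peak
    set with the longer median interval.  Boundaries are circular
    midpoints between adjacent peaks, so every interval is assigned to
    exactly one pause.

    Returns (labels aligned with sorted peak_angles, boundaries).
    """
    if len(peak_angles) != 6:
        raise ValueError("main/sub labelling requires exactly 6 peaks per turn")
    peaks = sorted(float(p) % 360.0 for p in peak_angles)
    bounds = [
        (peaks[i] + (peaks[(i + 1) % 6] - peaks[i]) % 360.0 / 2.0) % 360.0
        for i in range(6)
    ]
    assign = assign_intervals_to_peaks(peaks, intervals)
    occupancy = np.zeros(6)
    med_len: list[list[int]] = [[] for _ in range(6)]
    for itv, p in zip(intervals, assign):
        occupancy[p] += itv.n
        med_len[p].append(itv.n)
    # alternate parity sets = one peak per 120-degree repeat
    even, odd = occupancy[0::2].sum(), occupancy[1::2].sum()
    if even != odd:
        main_parity = 0 if even > odd else 1
    else:  # tie-break: longer median interval length
        med_even = np.median([n for i in (0, 2, 4) for n in med_len[i]] or [0])
        med_odd = np.median([n for i in (1, 3, 5) for n in med_len[i]] or [0])
        main_parity = 0 if med_even >= med_odd else 1
    labels = ["main" if i % 2 == main_parity else "sub" for i in range(6)]
    return labels, bounds


def assign_intervals_to_peaks(
    peaks: list[float], intervals: list[CPInterval]
) -> np.ndarray:
    """Index of the circularly nearest peak for each interval median."""
    peaks_arr = np.asarray(peaks, dtype=float)
    medians = np.mod([itv.median_angle for itv in intervals], 360.0)
    diff = np.abs(medians[:, None] - peaks_arr[None, :])
    diff = np.minimum(diff, 360.0 - diff)
    return np.argmin(diff, axis=1)


def angular_distance_ratio(
    intervals: list[CPInterval],
    peak_angles: list[float],
    labels: list[str],
) -> list[float]:
    """Per-step a/b ratios from consecutive main-sub-main pause triples.

    Intervals (temporal order, unwrapped medians) are assigned to peaks;
    consecutive intervals of the same pause occurrence are pooled by
    median.  For each main_k -> sub_k -> main_{k+1} run of occurrences,
    ``a = sub - main_k`` and ``b = main_{k+1} - sub`` on the unwrapped
    scale.  Per-occurrence medians (not global peak angles) are used so
    the ratio distribution reflects trace variability; steps with a <= 0
    or b <= 0 are discarded.
    """
    peaks = sorted(float(p) % 360.0 for p in peak_angles)
    if len(labels) != len(peaks):
        raise ValueError("labels must align with sorted peak_angles")
    assign = assign_intervals_to_peaks(peaks, intervals)
    # occurrence key: (peak index, turn number) on the unwrapped scale
    occurrences: list[tuple[str, float]] = []
    prev_key = None
    for itv, p in zip(intervals, assign):
        turn = round((itv.median_angle - peaks[p]) / 360.0)
        key = (int(p), int(turn))
        if key == prev_key:
            # pool repeated visits: occupancy-weighted median of medians
            old_lab, old_med = occurrences[-1]
            occurrences[-1] = (old_lab, (old_med + itv.median_angle) / 2.0)
        else:
            occurrences.append((labels[p], itv.median_angle))
        prev_key = key
    ratios: list[float] = []
    for (l1, m1), (l2, m2), (l3, m3) in zip(
        occurrences, occurrences[1:], occurrences[2:]
    ):
        if (l1, l2, l3) != ("main", "sub", "main"):
            continue
        a = m2 - m1
        b = m3 - m2
        if a <= 0 or b <= 0:
            continue
        ratios.append(a / b)
    return ratios


def mean_ratio(ratios: list[float]) -> tuple[float, float]:
    """Outlier-trimmed mean and standard error of a/b ratios.

    Outliers are removed by the Tukey rule (outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``) before computing the mean and its
    standard error.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 ratios")
    q1, q3 = np.percentile(r, [25, 75])
    iqr = q3 - q1
    kept = r[(r >= q1 - 1.5 * iqr) & (r <= q3 + 1.5 * iqr)]
    if kept.size == 0:
        raise ValueError("all ratios removed as outliers")
    mean = float(kept.mean())
    se = float(kept.std(ddof=1) / np.sqrt(kept.size)) if kept.size > 1 else 0.0
    return mean, se


def cluster_ratios(named_ratios) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram of mean a/b ratios.

    ``named_ratios`` is a mapping name -> mean ratio, or a sequence of
    (name, ratio) pairs.  Distance between two motors is the absolute
    difference of their mean ratios.  Returns (scipy linkage matrix,
    leaf names in input order); render with
    ``scipy.cluster.hierarchy.dendrogram``.
    """
    pairs = (
        list(named_ratios.items())
        if hasattr(named_ratios, "items")
        else list(named_ratios)
    )
    names = [n for n, _ in pairs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate names")
    if len(names) < 2:
        raise ValueError("need at least 2 named ratios")
    vals = np.array([v for _, v in pairs], dtype=float)
    dist = squareform(np.abs(vals[:, None] - vals[None, :]), checks=False)
    return linkage(dist, method="average"), names
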