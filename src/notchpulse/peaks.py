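"""Peak calling on tiling-array ChIP enrichment tracks.

Binding regions are called from probe-level log2(ChIP/input) enrichment by
combining the magnitude of enrichment with the number of consecutive enriched
probes: a peak is a maximal run of at least ``min_run`` probes at or above a
log2 threshold, after averaging replicates per probe; nearby runs separated by
at most ``merge_gap`` sub-threshold probes are merged.  Peak strength over the
ChIP timecourse is summarised by the area under the enrichment profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProbeTrack:
    """Ordered probe-level enrichment for one factor on one chromosome.

    ``data`` has shape (n_probes, n_times, n_reps) holding log2 enrichment;
    ``positions`` are probe midpoints in 0-based bp, strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    data: np.ndarray = field(repr=False)
    times: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None, None]
        elif self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if self.spacing <= 0:
            raise ValueError("probe spacing must be positive")
        if self.data.shape[0] != len(self.positions):
            raise ValueError("data rows must match probe positions")
        if self.data.shape[1] != len(self.times):
            raise ValueError("data time axis must match times")

    def mean_over_reps(self, time_index: int) -> np.ndarray:
        return self.data[:, time_index, :].mean(axis=1)

    def min_over_reps(self, time_index: int) -> np.ndarray:
        return self.data[:, time_index, :].min(axis=1)

    def slice_interval(self, start: float, end: float) -> np.ndarray:
        """Indices of probes with midpoint in [start, end)."""
        return np.flatnonzero((self.positions >= start) & (self.positions < end))


@dataclass
class Peak:
    """A called enrichment interval (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    time: float
    max_enrichment: float
    area: float
    summit: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("peak start must precede end")


def _enriched_runs(values: np.ndarray, threshold: float, min_run: int, merge_gap: int):
    """Index runs [i, j] (inclusive) of enriched probes after gap merging.

    Maximal stretches of values >= threshold are found first; stretches
    separated by at most ``merge_gap`` sub-threshold probes are merged; a
    merged run is kept if it contains at least one consecutive stretch of
    ``min_run`` enriched probes.
    """
    above = values >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # gap of g sub-threshold probes between consecutive enriched probes
    # appears as a difference of g+1 in idx
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    runs = []
    for s, e in zip(starts, ends):
        lo, hi = idx[s], idx[e]
        seg = above[lo : hi + 1]
        # longest consecutive enriched stretch within the merged run
        best = run = 0
        for flag in seg:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best >= min_run:
            runs.append((lo, hi))
    return runs


def call_peaks(
    track: ProbeTrack,
    time_index: int,
    threshold: float = 1.0,
    min_run: int = 4,
    merge_gap: int = 2,
    combine: str = "mean",
) -> list[Peak]:
    """Call peaks at one timepoint of a probe track.

    Replicates are combined per probe (``mean`` default, ``min`` for a
    stringent call) before the run-length rule is applied.  Peak boundaries
    extend half a probe spacing beyond the first and last enriched probe.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if len(track.positions) == 0:
        return []
    values = track.mean_over_reps(time_index) if combine == "mean" else track.min_over_reps(time_index)
    half = track.spacing / 2
    peaks = []
    for lo, hi in _enriched_runs(values, threshold, min_run, merge_gap):
        start = int(track.positions[lo] - half)
        end = int(track.positions[hi] + half)
        seg = values[lo : hi + 1]
        summit = int(track.positions[lo + int(np.argmax(seg))])
        area = float(np.sum(np.clip(seg, 0, None)) * track.spacing)
        peaks.append(
            Peak(
                chrom=track.chrom,
                start=max(start, 0),
                end=end,
                time=float(track.times[time_index]),
                max_enrichment=float(seg.max()),
                area=area,
                summit=summit,
            )
        )
    return peaks


def call_peaks_all_times(track: ProbeTrack, **kwargs) -> dict[float, list[Peak]]:
    """Peaks per timepoint, keyed by the timepoint in minutes."""
    return {
        float(t): call_peaks(track, j, **kwargs) for j, t in enumerate(track.times)
    }


def peak_area(track: ProbeTrack, peak: Peak, time_index: int | None = None) -> float:
    """Rectangle-rule area under a peak: sum of max(enrichment, 0) x spacing.

    Negative probe values inside the interval contribute zero, matching the
    non-negative log2 enrichment convention of the tracks.
    """
    if time_index is None:
        time_index = int(np.argmin(np.abs(track.times - peak.time)))
    if peak.start < track.positions[0] - track.spacing or peak.end > track.positions[-1] + track.spacing:
        raise ValueError("peak extends outside the track")
    idx = track.slice_interval(peak.start, peak.end)
    if len(idx) == 0:
        return 0.0
    values = track.mean_over_reps(time_index)[idx]
    return float(np.sum(np.clip(values, 0, None)) * track.spacing)


def peak_area_timecourse(
    track: ProbeTrack, interval: tuple[int, int]
) -> np.ndarray:
    """Area under the enrichment profile in a fixed interval at every timepoint.

    This is the per-region binding timecourse used to follow factor occupancy
    through the activation pulse (e.g. a Su(H) pulse peaking at 20-30 min).
    """
    start, end = interval
    idx = track.slice_interval(start, end)
    out = np.zeros(len(track.times))
    for j in range(len(track.times)):
        vals = track.mean_over_reps(j)[idx]
        out[j] = np.sum(np.clip(vals, 0, None)) * track.spacing
    return out
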