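"""RNA Pol II binding-state classification from ChIP enrichment tracks.

Each transcript at each ChIP timepoint is assigned one of four states:

* ``UB`` (unbound) — no Pol II at the promoter or in the gene body;
* ``P`` (poised) — Pol II at the 5' end but not within the body;
* ``AP`` (active poised) — a 5' peak plus body binding, with a pausing ratio
  log2(max promoter enrichment) / log2(median body enrichment) >= 2;
* ``AU`` (active uniform) — body binding with pausing ratio < 2.

The ratio is taken on the log2 enrichment values as printed on the tracks
(not on linear fold changes), with the body median floored (default 0.25) to
avoid division blow-up.  Gene-level state aggregates transcript states by the
precedence AU > AP > P > UB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peaks import ProbeTrack, _enriched_runs

#: Precedence order for gene-level aggregation: most active wins.
STATE_PRECEDENCE = ("AU", "AP", "P", "UB")

#: Pausing-ratio cutoff separating AP from AU.
PAUSING_RATIO_CUTOFF = 2.0


@dataclass
class PolIIState:
    """Classification of one transcript at one timepoint."""

    state: str
    pausing_ratio: float | None
    promoter_bound: bool
    body_bound: bool

    def __post_init__(self) -> None:
        if self.state not in STATE_PRECEDENCE:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class Transcript:
    """Genomic extent of a transcript (0-based half-open) with strand."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def promoter_interval(self, window: int) -> tuple[int, int]:
        return (self.tss - window, self.tss + window)

    def body_interval(self, window: int) -> tuple[int, int]:
        """Transcript body: from the promoter-window edge to the 3' end."""
        if self.strand == "+":
            return (min(self.tss + window, self.end), self.end)
        return (self.start, max(self.end - window, self.start))


def pausing_ratio(
    track: ProbeTrack,
    transcript: Transcript,
    time_index: int,
    promoter_window: int = 500,
    floor: float = 0.25,
) -> float | None:
    """Ratio of maximal promoter log2 enrichment to median body enrichment.

    Returns None when no probes fall in the promoter window; the body median
    is floored at ``floor`` before dividing.
    """
    values = track.mean_over_reps(time_index)
    p_lo, p_hi = transcript.promoter_interval(promoter_window)
    prom = track.slice_interval(p_lo, p_hi)
    if len(prom) == 0:
        return None
    b_lo, b_hi = transcript.body_interval(promoter_window)
    body = track.slice_interval(b_lo, b_hi)
    body_med = float(np.median(values[body])) if len(body) else 0.0
    return float(values[prom].max() / max(body_med, floor))


def _region_bound(
    values: np.ndarray, idx: np.ndarray, threshold: float, min_run: int, merge_gap: int
) -> bool:
    if len(idx) == 0:
        return False
    return bool(_enriched_runs(values[idx], threshold, min_run, merge_gap))


def classify_transcript(
    track: ProbeTrack,
    transcript: Transcript,
    time_index: int,
    promoter_window: int = 500,
    threshold: float = 1.0,
    min_run: int = 4,
    merge_gap: int = 2,
    floor: float = 0.25,
) -> PolIIState:
    """Assign the Pol II state of one transcript at one timepoint.

    Promoter and body binding are decided by the same threshold/run-length
    rule as peak calling, applied within each region.  Body binding without
    a promoter peak is active-uniform by construction.
    """
    if transcript.end <= track.positions[0] - track.spacing or transcript.start >= track.positions[-1] + track.spacing:
        raise ValueError(f"transcript {transcript.transcript_id} outside the track")
    values = track.mean_over_reps(time_index)
    p_lo, p_hi = transcript.promoter_interval(promoter_window)
    b_lo, b_hi = transcript.body_interval(promoter_window)
    prom_idx = track.slice_interval(p_lo, p_hi)
    body_idx = track.slice_interval(b_lo, b_hi)
    # the promoter window spans ~2*window/spacing probes; a run longer than
    # the window cannot be required, so cap min_run at the probe count
    prom_min_run = min(min_run, max(len(prom_idx), 1))
    promoter_bound = _region_bound(values, prom_idx, threshold, prom_min_run, merge_gap)
    body_bound = _region_bound(values, body_idx, threshold, min_run, merge_gap)
    ratio = pausing_ratio(track, transcript, time_index, promoter_window, floor)

    if not promoter_bound and not body_bound:
        state = "UB"
    elif promoter_bound and not body_bound:
        state = "P"
    elif body_bound and not promoter_bound:
        state = "AU"
    else:
        if ratio is None or ratio < PAUSING_RATIO_CUTOFF:
            state = "AU"
        else:
            state = "AP"
    return PolIIState(
        state=state,
        pausing_ratio=ratio,
        promoter_bound=promoter_bound,
        body_bound=body_bound,
    )


def gene_state(states: list[PolIIState | str]) -> str:
    """Aggregate transcript states to a gene state by AU > AP > P > UB."""
    if not states:
        raise ValueError("gene has no transcript states")
    labels = {s.state if isinstance(s, PolIIState) else s for s in states}
    unknown = labels - set(STATE_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown states {unknown}")
    for s in STATE_PRECEDENCE:
        if s in labels:
            return s
    raise AssertionError("unreachable")
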