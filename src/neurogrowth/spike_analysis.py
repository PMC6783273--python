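"""Multi-electrode-array activity analytics on spike-time tables.

The pipeline mirrors standard MEA practice for developing cultures, where
activity organizes into network-wide synchronized bursting events (SBEs):

1. per-electrode bursts: maximal spike runs whose consecutive inter-spike
   intervals stay below 100 ms;
2. SBE cores: periods during which at least T electrodes burst
   simultaneously, T = ceil(10% of active sites) clipped to [3, 20]
   (an active site is any electrode with at least one spike in the
   session); cores are padded by 25 ms on both sides to capture build-up
   and fading, and overlapping padded events are merged;
3. session statistics: AFR (grand-average firing rate per active site),
   SBE rate (events per minute), SBE strength (mean spikes per SBE per
   active site), PFR (peak of the 0.2 s boxcar-filtered network rate during
   an SBE, per active site), and network synchrony (mean pairwise Pearson
   correlation of 30 ms binned spike counts).

Undefined quantities (no active sites, zero baseline) are reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SpikeRecording",
    "Burst",
    "SBEvent",
    "ActivityStats",
    "DEFAULT_DIV_WINDOWS",
    "detect_bursts",
    "detect_sbes",
    "activity_stats",
    "peak_firing_rate",
    "network_synchrony",
    "relative_change",
    "summarize_development",
]

DEFAULT_DIV_WINDOWS: Tuple[Tuple[float, float], ...] = (
    (3, 5), (6, 9), (10, 14), (15, 20), (21, 27), (28, 35), (36, 44),
    (45, math.inf),
)


@dataclass
class SpikeRecording:
    """Per-electrode sorted spike times (seconds) with session duration."""

    spikes: Dict[str, np.ndarray]
    duration: float
    div: Optional[float] = None

    def __post_init__(self) -> None:
        clean: Dict[str, np.ndarray] = {}
        for el, times in self.spikes.items():
            t = np.asarray(times, dtype=float)
            if t.size and (np.any(t < 0) or np.any(t > self.duration)):
                raise ValueError(
                    f"electrode {el}: spike times outside [0, duration]"
                )
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"electrode {el}: spike times not sorted")
            clean[str(el)] = t
        self.spikes = clean

    @property
    def electrodes(self) -> List[str]:
        return list(self.spikes)

    @property
    def active_sites(self) -> List[str]:
        """Electrodes detecting at least one spike during the session."""
        return [el for el, t in self.spikes.items() if t.size > 0]

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def merged_spike_train(self) -> np.ndarray:
        """All spikes across electrodes, time-sorted (the global train)."""
        if not self.spikes:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.spikes.values())))


@dataclass
class Burst:
    """One per-electrode burst: a maximal sub-100-ms-ISI spike run."""

    electrode: str
    t_start: float
    t_end: float
    spike_times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class SBEvent:
    """One synchronized bursting event.

    ``core`` is the interval during which the coincident-burst count stayed
    at or above threshold; ``ext`` extends it by the build-up/fading pad.
    """

    core_start: float
    core_end: float
    ext_start: float
    ext_end: float
    spikes: Dict[str, np.ndarray] = field(default_factory=dict)
    n_sites: int = 0

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))


@dataclass
class ActivityStats:
    """Session-level activity summary (NaN marks undefined entries)."""

    afr: float
    sbe_rate: float
    sbe_strength: float
    pfr: float
    synchrony: float
    n_active_sites: int

    FIELDS = ("afr", "sbe_rate", "sbe_strength", "pfr", "synchrony")


def detect_bursts(
    spike_times: Sequence[float],
    isi_max: float = 0.1,
    min_spikes: int = 2,
    electrode: str = "",
) -> List[Burst]:
    """Detect bursts as maximal runs of consecutive ISIs < ``isi_max``.

    Runs with fewer than ``min_spikes`` spikes are discarded (a single
    spike is not a series).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    bursts: List[Burst] = []
    if t.size == 0:
        return bursts
    breaks = np.flatnonzero(np.diff(t) >= isi_max)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_spikes:
            bursts.append(Burst(electrode, float(t[s]), float(t[e]), t[s : e + 1]))
    return bursts


def coincidence_threshold(
    n_active: int, fraction: float = 0.10, min_sites: int = 3, max_sites: int = 20
) -> int:
    """Simultaneous-burst threshold: ceil(fraction * active sites) clipped
    to [min_sites, max_sites] so criteria stay comparable across array
    sizes."""
    return int(min(max(math.ceil(fraction * n_active), min_sites), max_sites))


def _burst_cores(
    bursts: List[Burst], threshold: int
) -> List[Tuple[float, float]]:
    """Maximal intervals where >= threshold bursts are simultaneously
    ongoing (burst intervals closed; exact event sweep, no discretization).

    At a tie, burst starts are processed before ends so that instantaneous
    overlaps (one burst ending exactly when another starts) count."""
    if not bursts:
        return []
    events = []  # (time, order, delta): starts (order 0) before ends (order 1)
    for b in bursts:
        events.append((b.t_start, 0, +1))
        events.append((b.t_end, 1, -1))
    events.sort()
    cores: List[Tuple[float, float]] = []
    count = 0
    core_start: Optional[float] = None
    for time, _, delta in events:
        count += delta
        if core_start is None and count >= threshold:
            core_start = time
        elif core_start is not None and count < threshold:
            cores.append((core_start, time))
            core_start = None
    return cores


def detect_sbes(
    rec: SpikeRecording,
    isi_max: float = 0.1,
    fraction: float = 0.10,
    min_sites: int = 3,
    max_sites: int = 20,
    pad: float = 0.025,
    min_spikes_per_burst: int = 2,
) -> List[SBEvent]:
    """Detect synchronized bursting events.

    Cores are maximal periods with at least T simultaneous per-electrode
    bursts; each core is extended by ``pad`` on both sides, overlapping
    extended events are merged, and member spikes (any electrode) within
    the extended interval are attached.  ``n_sites`` counts electrodes with
    a burst overlapping the extended interval.
    """
    active = rec.active_sites
    if not active:
        return []
    threshold = coincidence_threshold(len(active), fraction, min_sites, max_sites)
    all_bursts: List[Burst] = []
    for el in active:
        all_bursts.extend(
            detect_bursts(rec.spikes[el], isi_max, min_spikes_per_burst, el)
        )
    cores = _burst_cores(all_bursts, threshold)
    if not cores:
        return []
    # pad, then merge overlapping extended intervals (cores never overlap)
    merged: List[List[float]] = []
    for cs, ce in cores:
        es, ee = cs - pad, ce + pad
        if merged and es <= merged[-1][3]:
            merged[-1][1] = ce
            merged[-1][3] = ee
        else:
            merged.append([cs, ce, es, ee])
    events: List[SBEvent] = []
    for cs, ce, es, ee in merged:
        spikes: Dict[str, np.ndarray] = {}
        for el in active:
            t = rec.spikes[el]
            sel = t[(t >= es) & (t <= ee)]
            if sel.size:
                spikes[el] = sel
        n_sites = len(
            {
                b.electrode
                for b in all_bursts
                if b.t_start <= ee and b.t_end >= es
            }
        )
        events.append(SBEvent(cs, ce, es, ee, spikes, n_sites))
    return events


def peak_firing_rate(
    rec: SpikeRecording, sbe: SBEvent, kernel: float = 0.2
) -> float:
    """Peak network firing rate within an SBE, per active site (Hz).

    The global spike train restricted to the extended SBE interval is
    boxcar-filtered with ``kernel`` width; the exact maximum of the sliding
    count (windows anchored at spike times) divided by kernel width and by
    the number of active sites is returned.  Empty events yield 0.
    """
    n_active = len(rec.active_sites)
    if n_active == 0:
        return float("nan")
    merged = rec.merged_spike_train()
    t = merged[(merged >= sbe.ext_start) & (merged <= sbe.ext_end)]
    if t.size == 0:
        return 0.0
    # max spikes in any closed window [t_i, t_i + kernel]
    hi = np.searchsorted(t, t + kernel, side="right")
    lo = np.arange(t.size)
    peak_count = int((hi - lo).max())
    return peak_count / kernel / n_active


def network_synchrony(rec: SpikeRecording, bin_width: float = 0.03) -> float:
    """Mean pairwise Pearson correlation of binned spike counts across
    active sites; electrodes with zero count variance are excluded.  NaN
    when fewer than two usable electrodes remain."""
    active = rec.active_sites
    if len(active) < 2:
        return float("nan")
    n_bins = max(1, int(math.ceil(rec.duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.stack(
        [np.histogram(rec.spikes[el], bins=edges)[0] for el in active]
    ).astype(float)
    usable = counts.std(axis=1) > 0
    counts = counts[usable]
    if counts.shape[0] < 2:
        return float("nan")
    corr = np.corrcoef(counts)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(corr[iu].mean())


def activity_stats(
    rec: SpikeRecording,
    sbes: Optional[List[SBEvent]] = None,
    kernel: float = 0.2,
    bin_width: float = 0.03,
) -> ActivityStats:
    """Session-level summary; SBEs are detected with defaults when not
    supplied.  PFR is the mean over the session's SBEs."""
    active = rec.active_sites
    n_active = len(active)
    if n_active == 0 or rec.duration <= 0:
        nan = float("nan")
        return ActivityStats(nan, nan, nan, nan, nan, n_active)
    if sbes is None:
        sbes = detect_sbes(rec)
    afr = rec.n_spikes / rec.duration / n_active
    duration_min = rec.duration / 60.0
    sbe_rate = len(sbes) / duration_min
    if sbes:
        sbe_strength = float(np.mean([e.n_spikes for e in sbes])) / n_active
        pfr = float(np.mean([peak_firing_rate(rec, e, kernel) for e in sbes]))
    else:
        sbe_strength = float("nan")
        pfr = float("nan")
    sync = network_synchrony(rec, bin_width)
    return ActivityStats(afr, sbe_rate, sbe_strength, pfr, sync, n_active)


def relative_change(
    baseline: ActivityStats, treated: ActivityStats, field_name: str
) -> float:
    """Percent change of one statistic relative to baseline, e.g. burst
    strength across a treatment hour vs. the preceding baseline hour.
    NaN when the baseline value is zero or undefined."""
    b = getattr(baseline, field_name)
    t = getattr(treated, field_name)
    if not np.isfinite(b) or not np.isfinite(t) or b == 0:
        return float("nan")
    return 100.0 * (t - b) / b


def summarize_development(
    stats_list: Sequence[Tuple[float, ActivityStats]],
    windows: Sequence[Tuple[float, float]] = DEFAULT_DIV_WINDOWS,
) -> pd.DataFrame:
    """Pool per-recording statistics in DIV windows of increasing width.

    Returns a tidy frame with one row per (window, field): mean, SEM
    (ddof 1; NaN for singleton windows) and recording count n.  Recordings
    whose DIV falls outside every window are excluded; windows must not
    overlap.
    """
    for (a1, b1), (a2, b2) in zip(windows, list(windows)[1:]):
        if b1 >= a2:
            raise ValueError("DIV windows must be non-overlapping and sorted")
    rows = []
    for lo, hi in windows:
        label = f"{lo:g}-{hi:g}" if math.isfinite(hi) else f"{lo:g}+"
        members = [s for div, s in stats_list if div is not None and lo <= div <= hi]
        for fname in ActivityStats.FIELDS:
            vals = np.array(
                [getattr(s, fname) for s in members
                 if np.isfinite(getattr(s, fname))]
            )
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append(
                {"window": label, "div_lo": lo, "div_hi": hi, "field": fname,
                 "mean": mean, "sem": sem, "n": n}
            )
    return pd.DataFrame(rows)
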