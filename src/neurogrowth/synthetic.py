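"""Synthetic fixtures with known ground truth for every analysis path.

Point patterns emulate the spatial regimes of developing cultures
(hard-core random seeding, grid-like regularity, migration-driven
clustering); spike recordings emulate MEA sessions with background Poisson
activity plus synchronized bursting events of controlled rate, spread and
strength; Ca pairs follow the exponential gain law with multiplicative
noise.  Generators return their latent parameters/event lists so the
corresponding detectors and estimators can be validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .geometry import hard_core_pattern, wrap_positions
from .network_metrics import PointPattern
from .spike_analysis import SpikeRecording

__all__ = [
    "TrueSBE",
    "gen_point_pattern",
    "gen_spike_recording",
    "gen_ca_pairs",
]


@dataclass
class TrueSBE:
    """Ground truth for one synthesized bursting event."""

    t_start: float
    t_end: float
    electrodes: List[str]
    n_spikes: int


def gen_point_pattern(
    kind: str,
    m: int,
    domain_side: float = 1000.0,
    d_min: float = 12.0,
    cluster_count: int = 10,
    cluster_sd: float = 20.0,
    rng: Optional[np.random.Generator] = None,
) -> PointPattern:
    """Generate a point pattern of one of three spatial regimes.

    ``random``: hard-core rejection sampling, identical to network
    initialization (CI ≈ 1).  ``grid``: square lattice fitted to the torus
    (CI > 1).  ``clustered``: Gaussian clumps around ``cluster_count``
    uniformly drawn centers with multinomial-uniform occupancy, hard core
    enforced by rejection (CI < 1 for tight clumps).
    """
    if rng is None:
        rng = np.random.default_rng()
    if m < 1:
        raise ValueError("m must be >= 1")
    if kind == "random":
        pts = hard_core_pattern(m, domain_side, d_min, rng)
    elif kind == "grid":
        k = int(np.ceil(np.sqrt(m)))
        spacing = domain_side / k
        if spacing < d_min:
            raise ValueError("grid spacing below the hard-core distance")
        gx, gy = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel()]) * spacing
        pts = lattice[:m].astype(float)
    elif kind == "clustered":
        centers = rng.uniform(0.0, domain_side, size=(cluster_count, 2))
        pts = np.empty((m, 2))
        placed = 0
        attempts = 0
        budget = 1000 * m
        while placed < m:
            c = centers[int(rng.integers(cluster_count))]
            cand = wrap_positions(c + rng.normal(0.0, cluster_sd, size=2), domain_side)
            delta = pts[:placed] - cand
            delta -= domain_side * np.round(delta / domain_side)
            if placed == 0 or np.all(
                np.einsum("ij,ij->i", delta, delta) >= d_min * d_min
            ):
                pts[placed] = cand
                placed += 1
            attempts += 1
            if attempts > budget:
                raise ValueError(
                    "clustered pattern infeasible: clumps too tight for the "
                    "hard core"
                )
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return PointPattern(pts, domain_side, d_min)


def gen_spike_recording(
    n_electrodes: int = 20,
    duration: float = 1800.0,
    bg_rate: float = 0.05,
    sbe_rate: float = 3.0,
    sites_per_sbe: int = 15,
    spikes_per_site_per_sbe: int = 8,
    sbe_width: float = 0.15,
    div: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SpikeRecording, List[TrueSBE]]:
    """Synthesize an MEA session with known SBE structure.

    Background: independent Poisson spiking at ``bg_rate`` Hz per
    electrode.  Events: a Poisson process at ``sbe_rate`` per minute; each
    event places ``spikes_per_site_per_sbe`` spikes uniformly within
    ``sbe_width`` seconds on ``sites_per_sbe`` randomly chosen electrodes.
    With sbe_width at or below the boxcar kernel, the expected detected PFR
    is sites*spikes/kernel/n_active.  Returns the recording together with
    the latent event list.
    """
    if rng is None:
        rng = np.random.default_rng()
    if sites_per_sbe > n_electrodes:
        raise ValueError("sites_per_sbe exceeds electrode count")
    if duration <= 0 or sbe_width <= 0:
        raise ValueError("duration and sbe_width must be positive")
    electrodes = [f"e{i:02d}" for i in range(n_electrodes)]
    trains: dict[str, list] = {el: [] for el in electrodes}
    for el in electrodes:
        n_bg = rng.poisson(bg_rate * duration)
        trains[el].extend(rng.uniform(0.0, duration, size=n_bg))
    n_events = rng.poisson(sbe_rate * duration / 60.0)
    starts = np.sort(rng.uniform(0.0, max(duration - sbe_width, 0.0), size=n_events))
    truth: List[TrueSBE] = []
    for t0 in starts:
        sites = rng.choice(n_electrodes, size=sites_per_sbe, replace=False)
        for si in sites:
            times = t0 + np.sort(
                rng.uniform(0.0, sbe_width, size=spikes_per_site_per_sbe)
            )
            trains[electrodes[si]].extend(times)
        truth.append(
            TrueSBE(
                float(t0),
                float(t0 + sbe_width),
                [electrodes[si] for si in sites],
                sites_per_sbe * spikes_per_site_per_sbe,
            )
        )
    spikes = {el: np.sort(np.asarray(t)) for el, t in trains.items()}
    return SpikeRecording(spikes, duration=duration, div=div), truth


def gen_ca_pairs(
    k: float = 0.11,
    n: int = 500,
    pfr_range: Tuple[float, float] = (0.0, 80.0),
    noise_cv: float = 0.1,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw (PFR, amplitude) pairs from the exponential gain law with
    multiplicative Gaussian noise, amplitudes truncated at zero.

    amplitude = (exp(k * pfr) - 1) * (1 + eps), eps ~ N(0, noise_cv).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    pfr = rng.uniform(pfr_range[0], pfr_range[1], size=n)
    clean = np.expm1(k * pfr)
    amp = np.maximum(clean * (1.0 + rng.normal(0.0, noise_cv, size=n)), 0.0)
    return np.column_stack([pfr, amp])
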