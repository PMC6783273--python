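"""Exponential Ca2+-gain model linking somatic calcium transients to the
peak firing rate (PFR) of synchronized bursting events.

Somatic GCaMP fluorescence is converted to ΔF/F against a running
low-percentile baseline; for each SBE, the peak ΔF/F within 200 ms of
onset is paired with the simultaneously recorded PFR.  Amplitudes scale
exponentially with PFR,

    ΔF/F = exp(k * PFR) - 1,

and k is obtained by derivative-free least squares (the whole-dataset
estimate in cortical cultures is k = 0.11 per Hz).  Because the gain is
convex in PFR, concentrating the same number of spikes into fewer,
stronger events raises total Ca2+ influx — the lever through which
long-term influx converges across network architectures.  Long-term
influx is the per-event influx summed over all SBEs per hour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.optimize import minimize

__all__ = [
    "CaTrace",
    "GainFit",
    "DEFAULT_GAIN_EXPONENT",
    "delta_f_over_f",
    "sbe_peak_amplitude",
    "fit_gain_exponent",
    "influx_per_sbe",
    "longterm_influx_rate",
]

DEFAULT_GAIN_EXPONENT = 0.11  # per Hz, whole-dataset estimate


@dataclass
class CaTrace:
    """ΔF/F samples at a fixed frame rate (default 25 Hz imaging)."""

    samples: np.ndarray
    rate: float = 25.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("frame rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class GainFit:
    """Fitted gain exponent with residual diagnostics."""

    k: float
    rss: float
    n: int


def delta_f_over_f(
    raw: Sequence[float],
    rate: float = 25.0,
    baseline_window: float = 30.0,
    percentile: float = 8.0,
    t0: float = 0.0,
) -> CaTrace:
    """Convert a raw fluorescence series to ΔF/F = (F - F0)/F0.

    F0 is a running low-percentile baseline (default 8th percentile over a
    30 s window), which tracks slow drift while ignoring transients shorter
    than the window.  Raises when the baseline is not strictly positive.
    """
    f = np.asarray(raw, dtype=float)
    if f.size == 0:
        raise ValueError("empty fluorescence series")
    size = max(1, int(round(baseline_window * rate)))
    size = min(size, f.size)
    f0 = percentile_filter(f, percentile=percentile, size=size, mode="nearest")
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline F0; check raw trace")
    return CaTrace((f - f0) / f0, rate=rate, t0=t0)


def sbe_peak_amplitude(trace: CaTrace, onset: float, window: float = 0.2) -> float:
    """Peak ΔF/F within ``window`` seconds after an SBE onset.

    The onset (electrophysiology clock) is snapped to the nearest imaging
    frame; the maximum over frames in [onset, onset + window] is returned.
    Raises when the window does not fit inside the trace.
    """
    i0 = int(round((onset - trace.t0) * trace.rate))
    i1 = i0 + int(np.floor(window * trace.rate))
    if i0 < 0 or i1 >= trace.samples.size:
        raise ValueError("peak window lies outside the trace")
    return float(trace.samples[i0 : i1 + 1].max())


def fit_gain_exponent(
    pairs: Sequence[Tuple[float, float]],
    k0: float = 0.1,
) -> GainFit:
    """Least-squares fit of amplitude = exp(k * PFR) - 1 to (PFR, ΔF/F)
    pairs by Nelder-Mead simplex search from ``k0``.

    Requires at least two pairs and at least one non-zero PFR (otherwise
    the exponent is unidentifiable).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (pfr, amplitude) pairs")
    pfr, amp = arr[:, 0], arr[:, 1]
    if np.any(pfr < 0):
        raise ValueError("PFR values must be non-negative")
    if not np.any(pfr > 0):
        raise ValueError("all PFR values are zero; exponent unidentifiable")

    def rss(kv: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            resid = amp - np.expm1(kv[0] * pfr)
        resid = np.where(np.isfinite(resid), resid, 1e12)
        return float(resid @ resid)

    res = minimize(
        rss,
        x0=[k0],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10_000},
    )
    k = float(res.x[0])
    return GainFit(k=k, rss=rss(res.x), n=arr.shape[0])


def influx_per_sbe(pfr, k: float = DEFAULT_GAIN_EXPONENT):
    """Estimated Ca2+ influx of one SBE: exp(k * PFR) - 1.

    Zero at PFR 0, strictly increasing and convex in PFR.  Vectorized.
    """
    pfr = np.asarray(pfr, dtype=float)
    if np.any(pfr < 0):
        raise ValueError("PFR must be non-negative")
    out = np.expm1(k * pfr)
    return float(out) if out.ndim == 0 else out


def longterm_influx_rate(
    sbes_pfr: Sequence[float],
    duration_hr: float,
    k: float = DEFAULT_GAIN_EXPONENT,
    per: str = "hr",
) -> float:
    """Long-term Ca2+ influx: per-SBE influx summed over all events,
    divided by the recording duration (per hour, or per minute with
    ``per='min'``)."""
    if duration_hr <= 0:
        raise ValueError("duration must be positive")
    pfr = np.asarray(sbes_pfr, dtype=float)
    total = float(np.sum(influx_per_sbe(pfr, k))) if pfr.size else 0.0
    rate = total / duration_hr
    if per == "hr":
        return rate
    if per == "min":
        return rate / 60.0
    raise ValueError("per must be 'hr' or 'min'")
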