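"""Peri-stimulus time histograms and distance-dependent response features.

The PSTH of one episode pools spikes from a 75-ms window after each pulse
onset into 40-us bins, smooths them with a Gaussian kernel
``exp(-t^2 / (2 sigma^2))`` with sigma = 1.5 ms, and normalizes by the
number of stimulus repetitions M, so a unit-probability pulse-locked
response has peak amplitude 1. A curve is considered valid only when it
pools more than 20 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import StimulationEpisode
from .layout import MEALayout

__all__ = [
    "PSTHCurve",
    "compute_psth",
    "peri_event_histogram",
    "psth_features",
    "distance_bin",
    "DISTANCE_CATEGORIES_UM",
]

#: Radial distance categories (um) used in the distance-response analysis.
DISTANCE_CATEGORIES_UM = (30.0, 60.0, 100.0, 200.0, 500.0, 1000.0)

#: Minimum pooled spike count for a PSTH to be considered valid.
MIN_VALID_SPIKES = 20


@dataclass
class PSTHCurve:
    """Smoothed per-episode response function on the 40-us grid."""

    bin_centers_ms: np.ndarray
    values: np.ndarray
    window_ms: float
    n_spikes: int  # N: spikes pooled over all pulses
    n_pulses: int  # M: stimulus repetitions
    sigma_ms: float
    valid: bool

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("PSTH values must be non-negative")

    def integral(self) -> float:
        """Time integral of the curve in ms units."""
        dt = self.bin_centers_ms[1] - self.bin_centers_ms[0]
        return float(self.values.sum() * dt)


def _pooled_latencies_ms(
    timestamps_s: np.ndarray, onsets_s: np.ndarray, window_ms: float
) -> np.ndarray:
    t = np.asarray(timestamps_s, float)
    lat = []
    w = window_ms / 1e3
    for onset in np.asarray(onsets_s, float):
        sel = (t >= onset) & (t < onset + w)
        lat.append((t[sel] - onset) * 1e3)
    return np.concatenate(lat) if lat else np.empty(0)


def compute_psth(
    timestamps_s: np.ndarray,
    episode: StimulationEpisode,
    window_ms: float = 75.0,
    bin_us: float = 40.0,
    sigma_ms: float = 1.5,
) -> PSTHCurve:
    """Gaussian-smoothed stimulus-aligned spike histogram, peak-normalized
    by the pulse count M.

    The kernel is truncated at +-5 sigma; latencies near the window edges
    keep only the kernel mass falling inside the window (no
    renormalization).
    """
    m = episode.n_pulses
    if m == 0:
        raise ValueError("episode has no pulses")
    bin_ms = bin_us / 1e3
    n_bins = int(round(window_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    centers = (edges[:-1] + edges[1:]) / 2

    lat = _pooled_latencies_ms(timestamps_s, episode.onsets, window_ms)
    counts, _ = np.histogram(lat, bins=edges)

    half = int(np.ceil(5 * sigma_ms / bin_ms))
    k_t = np.arange(-half, half + 1) * bin_ms
    kernel = np.exp(-0.5 * (k_t / sigma_ms) ** 2)
    smoothed = np.convolve(counts.astype(float), kernel, mode="same") / m

    return PSTHCurve(
        bin_centers_ms=centers,
        values=smoothed,
        window_ms=window_ms,
        n_spikes=int(counts.sum()),
        n_pulses=m,
        sigma_ms=sigma_ms,
        valid=bool(counts.sum() > MIN_VALID_SPIKES),
    )


def psth_features(curve: PSTHCurve) -> tuple[float, float]:
    """(peak amplitude, peak latency in ms); ties resolve to the earliest bin."""
    if not curve.valid:
        raise ValueError("PSTH is not valid (20 or fewer pooled spikes)")
    i = int(np.argmax(curve.values))
    return float(curve.values[i]), float(curve.bin_centers_ms[i])


def peri_event_histogram(
    timestamps_s: np.ndarray,
    onsets_s: np.ndarray,
    span_ms: float = 500.0,
    bin_ms: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Cumulative post-stimulus spike counts in coarse bins, plus a raster.

    Returns ``(bin_edges_ms, counts, raster)`` where counts accumulate over
    all pulses and the raster is long-format ``(pulse_index, latency_ms)``
    ordered by pulse index (rows stack bottom to top in a raster plot).
    When the span is not a whole number of bins the final bin is truncated
    at the span (spikes beyond the span never count).
    """
    if span_ms <= 0 or bin_ms <= 0:
        raise ValueError("span and bin width must be positive")
    n_bins = int(np.ceil(span_ms / bin_ms - 1e-9))
    edges = np.minimum(np.arange(n_bins + 1) * bin_ms, span_ms)
    t = np.asarray(timestamps_s, float)
    rows = []
    for k, onset in enumerate(np.asarray(onsets_s, float)):
        sel = (t >= onset) & (t < onset + span_ms / 1e3)
        for lat in (t[sel] - onset) * 1e3:
            rows.append((k, lat))
    raster = pd.DataFrame(rows, columns=["pulse_index", "latency_ms"])
    counts, _ = np.histogram(raster["latency_ms"], bins=edges)
    return edges, counts, raster


def distance_bin(
    target_xy: tuple[float, float],
    electrode_center: tuple[float, float],
    layout: MEALayout,
    convention: str = "edge",
    categories: tuple[float, ...] = DISTANCE_CATEGORIES_UM,
    margin_um: float = 1000.0,
) -> float | None:
    """Sort a stimulation-site-to-electrode distance into a radial category.

    ``convention="edge"`` measures from the electrode rim (Euclidean
    centre distance minus the electrode radius, clipped at zero);
    ``"center"`` uses the plain centre-to-centre distance. Returns the
    smallest category >= the distance, or ``None`` beyond the largest
    category.
    """
    tx, ty = map(float, target_xy)
    xmin, ymin, xmax, ymax = layout.bounding_box()
    if not (xmin - margin_um <= tx <= xmax + margin_um
            and ymin - margin_um <= ty <= ymax + margin_um):
        raise ValueError("target lies outside the array bounding box + margin")
    d = float(np.hypot(tx - electrode_center[0], ty - electrode_center[1]))
    if convention == "edge":
        d = max(d - layout.electrode_diameter / 2, 0.0)
    elif convention != "center":
        raise ValueError(f"unknown distance convention {convention!r}")
    for cat in categories:
        if d <= cat:
            return cat
    return None
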