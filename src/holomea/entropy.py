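"""Baseline functional connectivity via spectral-entropy synchronicity.

Each filtered electrode signal is split into overlapping segments
(250 ms, 80% overlap by default). Per segment the power spectrum is
normalized to unit sum and collapsed into one normalized Shannon entropy
value S_i = sum_f P_norm(f) log(1 / P_norm(f)) / log(N), with N the
number of samples per segment. Synchronized network states depress
entropy simultaneously across electrodes, so the lag-0 Pearson
correlation r_xy of two entropy time courses measures electrode-electrode
synchronicity. Edges with r_xy above a display threshold (default 0.1)
form the baseline map; segment-order shuffling provides a surrogate null
that collapses genuine correlations to near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .recording import RawRecording
from .spikes import robust_sigma

__all__ = [
    "EntropySignal",
    "spectral_entropy",
    "entropy_correlation",
    "shuffle_null",
    "baseline_map",
]


@dataclass
class EntropySignal:
    """Spectral-entropy time course of one channel."""

    values: np.ndarray  # S_i per segment; NaN flags all-zero segments
    segment_s: float
    overlap: float
    n_per_segment: int  # N: samples per segment (normalization constant)
    fs: float

    @property
    def n_segments(self) -> int:
        return self.values.size


def spectral_entropy(
    signal: np.ndarray,
    fs: float,
    segment_s: float = 0.250,
    overlap: float = 0.8,
    taper: str | None = None,
    normalization: str = "segment_length",
) -> EntropySignal:
    """Per-segment normalized spectral entropy of one channel.

    Segments advance by ``segment_s * (1 - overlap)``. The spectrum is the
    one-sided periodogram of each segment (optionally Hann-tapered). The
    entropy is normalized by ``log(N)`` with N the samples per segment
    (``normalization="segment_length"``, default) or by the number of
    frequency bins (``normalization="n_bins"``), the latter bounding S_i
    by 1. All-zero segments have undefined entropy and are flagged NaN.
    """
    x = np.asarray(signal, float)
    n_seg = int(round(segment_s * fs))
    if n_seg < 2:
        raise ValueError("segment too short for the sampling rate")
    if x.size < n_seg:
        raise ValueError("signal shorter than one segment")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = max(int(round(n_seg * (1.0 - overlap))), 1)
    starts = np.arange(0, x.size - n_seg + 1, hop)

    window = np.hanning(n_seg) if taper == "hann" else np.ones(n_seg)
    n_bins = n_seg // 2 + 1
    log_norm = np.log(n_seg) if normalization == "segment_length" else np.log(n_bins)
    if normalization not in ("segment_length", "n_bins"):
        raise ValueError(f"unknown normalization {normalization!r}")

    values = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = x[s : s + n_seg] * window
        power = np.abs(np.fft.rfft(seg)) ** 2
        total = power.sum()
        if total == 0:
            values[i] = np.nan
            continue
        p = power / total
        nz = p > 0
        values[i] = float(-(p[nz] * np.log(p[nz])).sum() / log_norm)

    return EntropySignal(values, segment_s, overlap, n_seg, fs)


def entropy_correlation(sx: EntropySignal | np.ndarray, sy: EntropySignal | np.ndarray) -> float:
    """Lag-0 cross-correlation coefficient r_xy = C_xy / (sigma_x sigma_y).

    C_xy is the lag-0 cross-covariance over the O shared segments; this is
    the Pearson correlation of the two entropy series.
    """
    ax = sx.values if isinstance(sx, EntropySignal) else np.asarray(sx, float)
    ay = sy.values if isinstance(sy, EntropySignal) else np.asarray(sy, float)
    if ax.size != ay.size:
        raise ValueError("entropy signals must have equal segment counts")
    ok = ~(np.isnan(ax) | np.isnan(ay))
    ax, ay = ax[ok], ay[ok]
    if ax.size < 2:
        raise ValueError("need at least two segments")
    dx, dy = ax - ax.mean(), ay - ay.mean()
    sx_sd, sy_sd = dx.std(), dy.std()
    if sx_sd == 0 or sy_sd == 0:
        raise ValueError("constant entropy signal has undefined correlation")
    return float((dx * dy).mean() / (sx_sd * sy_sd))


def shuffle_null(
    sx: EntropySignal | np.ndarray,
    sy: EntropySignal | np.ndarray,
    n_shuffles: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Surrogate distribution of r after permuting the segment order of S_x."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    ax = np.array(sx.values if isinstance(sx, EntropySignal) else sx, float)
    ay = sy.values if isinstance(sy, EntropySignal) else np.asarray(sy, float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = entropy_correlation(rng.permutation(ax), ay)
    return out


def baseline_map(
    recording: RawRecording,
    r_threshold: float = 0.1,
    event_k_sigma: float = 6.0,
    segment_s: float = 0.250,
    overlap: float = 0.8,
    **entropy_kwargs,
) -> nx.Graph:
    """Electrode-electrode baseline connectivity graph.

    Channels without a single event exceeding ``event_k_sigma`` times the
    robust noise SD are excluded as inactive. All remaining pairs are
    scored by :func:`entropy_correlation`; edges with r above
    ``r_threshold`` are kept. Node attribute ``activity`` records each
    channel's mean supra-6-sigma event count per second; graph attributes
    record the threshold used.
    """
    eligible: list[str] = []
    entropies: dict[str, EntropySignal] = {}
    activity: dict[str, float] = {}
    for eid, x in zip(recording.electrode_ids, recording.signals):
        x = np.asarray(x, float)
        sigma = robust_sigma(x)
        n_events = int((np.abs(x) > event_k_sigma * sigma).sum()) if sigma > 0 else 0
        if n_events == 0:
            continue
        eligible.append(eid)
        activity[eid] = n_events / recording.duration_s
        entropies[eid] = spectral_entropy(
            x, recording.fs, segment_s, overlap, **entropy_kwargs
        )

    graph = nx.Graph(r_threshold=r_threshold, event_k_sigma=event_k_sigma)
    for eid in eligible:
        graph.add_node(eid, activity=activity[eid])
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            r = entropy_correlation(entropies[a], entropies[b])
            if r > r_threshold:
                graph.add_edge(a, b, weight=r)
    return graph
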