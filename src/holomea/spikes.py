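"""Spike and burst extraction from raw multichannel recordings.

The processing chain follows standard extracellular practice: a
second-order Butterworth high-pass at 100 Hz removes drift, action
potentials are detected where the filtered signal crosses +-k*sigma of a
robust noise estimate (k = 5 by default), detected events are assigned to
units by nearest-template matching, and bursts are extracted with a
max-interval rule (20 ms ISI to start, 10 ms ISI to continue, >= 4 spikes
and >= 20 ms duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import RawRecording

__all__ = [
    "SpikeTrain",
    "BurstSet",
    "highpass",
    "robust_sigma",
    "detect_spikes",
    "extract_snippets",
    "assign_units",
    "detect_bursts",
    "activity_metrics",
    "select_active_electrodes",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class SpikeTrain:
    """Detected events on one electrode: sorted timestamps plus the sign of
    the threshold crossing and the noise estimate used."""

    electrode: str
    timestamps_s: np.ndarray
    polarity: np.ndarray = field(default=None)
    sigma: float = np.nan
    threshold: float = np.nan

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, float)
        if self.polarity is None:
            self.polarity = np.full(self.timestamps_s.shape, -1, dtype=int)
        if self.timestamps_s.size > 1 and (np.diff(self.timestamps_s) < 0).any():
            raise ValueError("timestamps must be sorted")

    def __len__(self) -> int:
        return self.timestamps_s.size


@dataclass
class BurstSet:
    """Bursts of one spike train with summary statistics."""

    bursts: list[tuple[float, float, int]]  # (start_s, end_s, n_spikes)
    n_spikes_total: int
    train_duration_s: float

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def burst_frequency_hz(self) -> float:
        if self.train_duration_s <= 0:
            return 0.0
        return self.n_bursts / self.train_duration_s

    @property
    def mean_duration_ms(self) -> float:
        if not self.bursts:
            return 0.0
        return float(np.mean([(e - s) * 1e3 for s, e, _ in self.bursts]))

    @property
    def pct_spikes_in_bursts(self) -> float:
        if self.n_spikes_total == 0:
            return 0.0
        in_bursts = sum(n for _, _, n in self.bursts)
        return 100.0 * in_bursts / self.n_spikes_total


# ---------------------------------------------------------------------------
# filtering and detection

def highpass(
    raw: RawRecording, cutoff_hz: float = 100.0, order: int = 2, zero_phase: bool = True
) -> RawRecording:
    """Butterworth high-pass; zero-phase (forward-backward) by default so
    spike timestamps are not skewed by filter delay."""
    if cutoff_hz >= raw.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=raw.fs, output="sos")
    x = np.asarray(raw.signals, dtype=np.float64)
    filtered = sps.sosfiltfilt(sos, x, axis=1) if zero_phase else sps.sosfilt(sos, x, axis=1)
    return RawRecording(
        signals=filtered.astype(raw.signals.dtype, copy=False),
        fs=raw.fs,
        electrode_ids=list(raw.electrode_ids),
        layout=raw.layout,
        session_id=raw.session_id,
    )


def robust_sigma(x: np.ndarray) -> float:
    """Median-based noise SD estimate, insensitive to spikes."""
    return float(np.median(np.abs(x)) / 0.6745)


def _detect_channel(
    x: np.ndarray, fs: float, k_sigma: float, debounce_ms: float
) -> tuple[np.ndarray, np.ndarray, float]:
    sigma = robust_sigma(x)
    # silent channels produce no events rather than dividing by zero
    sigma_eff = max(sigma, np.finfo(float).tiny)
    thr = k_sigma * sigma_eff
    above = np.abs(x) > thr
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return np.empty(0), np.empty(0, int), sigma
    gap = max(int(round(debounce_ms / 1e3 * fs)), 1)
    # split supra-threshold samples into clusters separated by >= gap samples
    splits = np.nonzero(np.diff(idx) >= gap)[0] + 1
    clusters = np.split(idx, splits)
    times, pols = [], []
    for cl in clusters:
        peak = cl[np.argmax(np.abs(x[cl]))]
        times.append(peak / fs)
        pols.append(-1 if x[peak] < 0 else 1)
    return np.asarray(times), np.asarray(pols, int), sigma


def detect_spikes(
    filtered: RawRecording, k_sigma: float = 5.0, debounce_ms: float = 1.0
) -> dict[str, SpikeTrain]:
    """Threshold detection at +-k_sigma per channel.

    Supra-threshold samples closer than the debounce window collapse to one
    event timestamped at the largest-|amplitude| sample.
    """
    if filtered.n_samples < filtered.fs:
        raise ValueError("need at least 1 s of signal to estimate noise")
    out: dict[str, SpikeTrain] = {}
    for eid, x in zip(filtered.electrode_ids, filtered.signals):
        times, pols, sigma = _detect_channel(
            np.asarray(x, float), filtered.fs, k_sigma, debounce_ms
        )
        out[eid] = SpikeTrain(eid, times, pols, sigma, k_sigma * sigma)
    return out


def extract_snippets(
    x: np.ndarray,
    fs: float,
    timestamps_s: np.ndarray,
    pre_ms: float = 0.55,
    post_ms: float = 1.45,
) -> np.ndarray:
    """Cut waveform snippets around event times (default 2 ms, peak-aligned).

    Events too close to the signal edges are zero-padded.
    """
    n_pre = int(round(pre_ms / 1e3 * fs))
    n_post = int(round(post_ms / 1e3 * fs))
    width = n_pre + n_post
    out = np.zeros((len(timestamps_s), width))
    for i, t in enumerate(np.asarray(timestamps_s, float)):
        c = int(round(t * fs))
        lo, hi = c - n_pre, c + n_post
        slo, shi = max(lo, 0), min(hi, x.size)
        out[i, slo - lo : shi - lo] = x[slo:shi]
    return out


def assign_units(
    trains: dict[str, SpikeTrain],
    snippets: dict[str, np.ndarray],
    templates: dict[str, dict[str, np.ndarray]],
    max_residual: float | None = None,
) -> pd.DataFrame:
    """Assign each detected event to the nearest waveform template.

    Template matching by least-squares distance; events whose best residual
    exceeds ``max_residual`` times the snippet energy are flagged as
    ``"unassigned"``. Electrodes without templates are skipped.

    Returns a unit spike table with columns ``time_s, electrode, unit``.
    """
    rows = []
    for eid, train in trains.items():
        tmpl = templates.get(eid)
        if not tmpl or len(train) == 0:
            continue
        snips = snippets[eid]
        names = list(tmpl)
        bank = np.stack([np.asarray(tmpl[u], float) for u in names])
        if bank.shape[1] != snips.shape[1]:
            raise ValueError(
                f"template length {bank.shape[1]} != snippet length {snips.shape[1]}"
            )
        # squared distance to every template, argmin per event
        d2 = ((snips[:, None, :] - bank[None, :, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        for i, t in enumerate(train.timestamps_s):
            unit = names[best[i]]
            if max_residual is not None:
                energy = (snips[i] ** 2).sum()
                if energy > 0 and d2[i, best[i]] > max_residual * energy:
                    unit = "unassigned"
            rows.append((float(t), eid, unit))
    table = pd.DataFrame(rows, columns=["time_s", "electrode", "unit"])
    return table.sort_values("time_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# bursts

def detect_bursts(
    timestamps_s: np.ndarray,
    start_isi_s: float = 0.020,
    end_isi_s: float = 0.010,
    min_ibi_s: float = 0.010,
    min_duration_s: float = 0.020,
    min_spikes: int = 4,
    train_duration_s: float | None = None,
) -> BurstSet:
    """Max-interval burst detection.

    A burst opens at an inter-spike interval <= ``start_isi_s`` and extends
    while intervals stay <= ``end_isi_s``; bursts separated by less than
    ``min_ibi_s`` are merged; candidates shorter than ``min_duration_s`` or
    with fewer than ``min_spikes`` spikes are discarded.
    """
    t = np.asarray(timestamps_s, float)
    if t.size and (np.diff(t) < 0).any():
        raise ValueError("spike train must be sorted")
    duration = train_duration_s if train_duration_s is not None else (
        float(t[-1] - t[0]) if t.size > 1 else 0.0
    )
    if t.size < 2:
        return BurstSet([], int(t.size), duration)

    isi = np.diff(t)
    spans: list[tuple[int, int]] = []  # inclusive spike index ranges
    i = 0
    while i < isi.size:
        if isi[i] <= start_isi_s:
            j = i + 1
            while j < isi.size and isi[j] <= end_isi_s:
                j += 1
            spans.append((i, j))  # spikes i..j
            i = j + 1
        else:
            i += 1

    # merge bursts closer than the minimum inter-burst interval
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and t[s] - t[merged[-1][1]] < min_ibi_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    bursts = [
        (float(t[s]), float(t[e]), e - s + 1)
        for s, e in merged
        if (t[e] - t[s]) >= min_duration_s and (e - s + 1) >= min_spikes
    ]
    return BurstSet(bursts, int(t.size), duration)


# ---------------------------------------------------------------------------
# activity metrics

def activity_metrics(
    table: pd.DataFrame,
    windows: list[tuple[float, float]],
    by: str = "unit",
    burst_kwargs: dict | None = None,
) -> pd.DataFrame:
    """AP frequency, burst frequency, and % APs in bursts within windows.

    ``windows`` is a list of ``(start_s, end_s)`` analysis windows (a single
    spontaneous span, per-pulse 75-ms windows, or the full-field
    first-to-last-pulse span). ``by`` groups per ``"unit"`` (electrode, unit)
    or per ``"electrode"``.
    """
    windows = [(float(a), float(b)) for a, b in windows]
    if any(b <= a for a, b in windows):
        raise ValueError("windows must have positive length")
    total = sum(b - a for a, b in windows)
    keys = ["electrode", "unit"] if by == "unit" else ["electrode"]
    times = table["time_s"].to_numpy()
    in_any = np.zeros(len(table), dtype=bool)
    for a, b in windows:
        in_any |= (times >= a) & (times < b)
    sub = table.loc[in_any]

    rows = []
    groups = sub.groupby(keys, sort=True) if len(sub) else []
    seen = set()
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        seen.add(key)
        ts = np.sort(grp["time_s"].to_numpy())
        bs = detect_bursts(ts, train_duration_s=total, **(burst_kwargs or {}))
        rows.append(
            (*key, len(ts), len(ts) / total, bs.burst_frequency_hz,
             bs.pct_spikes_in_bursts)
        )
    # groups present in the table but silent inside the windows report zeros
    for key, _ in table.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if key not in seen:
            rows.append((*key, 0, 0.0, 0.0, 0.0))
    cols = keys + ["n_spikes", "rate_hz", "burst_rate_hz", "pct_in_bursts"]
    return pd.DataFrame(rows, columns=cols).sort_values(keys).reset_index(drop=True)


def select_active_electrodes(
    session_rates: pd.DataFrame, min_rate_hz: float = 0.2, min_sessions: int = 2
) -> tuple[list[str], pd.DataFrame]:
    """Retain electrodes active (> ``min_rate_hz``) in >= ``min_sessions``
    sessions; on retained electrodes, sessions below threshold are zeroed.

    ``session_rates`` is electrodes x sessions (Hz).
    """
    if session_rates.shape[1] < 2:
        raise ValueError("need at least two sessions of metrics")
    active = session_rates > min_rate_hz
    keep = active.sum(axis=1) >= min_sessions
    retained = session_rates.loc[keep].where(active.loc[keep], 0.0)
    return list(retained.index), retained
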