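"""Single-neuron stimulation functional connectivity.

A stimulated-neuron -> recorded-unit connection is *valid* when the
unit's stimulus-relative spike-time distribution deviates from baseline
in every one of N_stim leave-one-stimulus-out Kolmogorov-Smirnov tests at
P < 0.01. The leave-one-out battery guards against a single spontaneous
burst masquerading as a response. Units silent at baseline are tested
against the all-zero distribution: any consistent evoked spiking rejects,
subject to a minimum-spike guard.

Connection strength is the maximum cross-correlation between the boxcar
stimulus pulse train S (50-ms boxes centred 25 ms after each onset) and
the Gaussian-smoothed spike events E within the episode span. Valid
connections aggregate into neuron->electrode maps with per-neuron and
per-electrode connection counts, and into a symmetric electrode-electrode
matrix where each episode with valid connections on >= 2 electrodes
increments every such electrode pair by one, normalized by experiment
duration and optionally by the cross-day maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .episodes import StimulationEpisode

__all__ = [
    "DIFSet",
    "ConnectionTest",
    "NeuronElectrodeMap",
    "ElectrodeMatrix",
    "displaced_impulses",
    "validate_connection",
    "connection_strength",
    "build_neuron_map",
    "electrode_matrix",
    "normalize_across_days",
]


# ---------------------------------------------------------------------------
# displaced impulses

@dataclass
class DIFSet:
    """Leave-one-stimulus-out latency distributions for one episode.

    ``loo_latencies_s[m]`` holds spike latencies relative to pulse onsets
    pooled over all pulses except pulse m; ``baseline_latencies_s`` holds
    latencies of baseline spikes relative to matched unstimulated window
    starts.
    """

    loo_latencies_s: list[np.ndarray]
    baseline_latencies_s: np.ndarray
    window_s: float

    @property
    def n_stim(self) -> int:
        return len(self.loo_latencies_s)


def _window_latencies(
    t: np.ndarray, starts: np.ndarray, window_s: float
) -> list[np.ndarray]:
    return [t[(t >= s) & (t < s + window_s)] - s for s in starts]


def displaced_impulses(
    timestamps_s: np.ndarray,
    episode: StimulationEpisode,
    baseline_timestamps_s: np.ndarray,
    baseline_span_s: tuple[float, float],
) -> DIFSet:
    """Empirical stimulus-relative spike-time distributions.

    The per-pulse window is the inter-pulse interval; the baseline span is
    chopped into windows of the same length and its spikes referenced to
    the window starts, yielding a latency distribution matched in support.
    """
    if episode.n_pulses < 2:
        raise ValueError("episode needs at least 2 pulses for leave-one-out tests")
    t = np.asarray(timestamps_s, float)
    window = episode.inter_pulse_interval_s
    per_pulse = _window_latencies(t, episode.onsets, window)

    m = episode.n_pulses
    loo = [
        np.concatenate([per_pulse[k] for k in range(m) if k != leave])
        for leave in range(m)
    ]

    b0, b1 = baseline_span_s
    n_windows = max(int((b1 - b0) / window), 1)
    starts = b0 + np.arange(n_windows) * window
    tb = np.asarray(baseline_timestamps_s, float)
    baseline = np.concatenate(_window_latencies(tb, starts, window)) if tb.size else np.empty(0)
    return DIFSet(loo, baseline, window)


# ---------------------------------------------------------------------------
# validation

@dataclass
class ConnectionTest:
    """Outcome of the N_stim leave-one-out KS battery for one
    (episode, electrode, unit) candidate connection."""

    episode_id: str
    electrode: str
    unit: str
    p_values: np.ndarray
    alpha: float
    valid: bool
    reason: str = "ok"
    strength: float = np.nan

    @property
    def n_stim(self) -> int:
        return self.p_values.size


def validate_connection(
    timestamps_s: np.ndarray,
    episode: StimulationEpisode,
    baseline_timestamps_s: np.ndarray,
    baseline_span_s: tuple[float, float],
    alpha: float = 0.01,
    min_spikes: int = 3,
    electrode: str = "",
    unit: str = "",
) -> ConnectionTest:
    """Run the N_stim leave-one-out KS battery for one candidate connection.

    Each leave-one-out latency set is compared against the baseline latency
    distribution with a two-sample KS test; when the baseline is silent the
    comparison is against the all-zero distribution, implemented as "any
    evoked latency mass rejects" guarded by ``min_spikes`` spikes per
    subset. The connection is valid iff every test has p < ``alpha``.
    """
    difs = displaced_impulses(
        timestamps_s, episode, baseline_timestamps_s, baseline_span_s
    )
    m = difs.n_stim
    total_evoked = sum(arr.size for arr in difs.loo_latencies_s)
    if total_evoked == 0:
        return ConnectionTest(
            episode.episode_id, electrode, unit, np.ones(m), alpha, False, "no_spikes"
        )

    p = np.ones(m)
    silent_baseline = difs.baseline_latencies_s.size == 0
    for i, lat in enumerate(difs.loo_latencies_s):
        if silent_baseline:
            p[i] = 0.0 if lat.size >= min_spikes else 1.0
        elif lat.size == 0:
            p[i] = 1.0
        else:
            p[i] = stats.ks_2samp(lat, difs.baseline_latencies_s).pvalue
    valid = bool((p < alpha).all())
    reason = "ok" if valid else (
        "insufficient_spikes" if silent_baseline and not valid else "not_significant"
    )
    return ConnectionTest(episode.episode_id, electrode, unit, p, alpha, valid, reason)


# ---------------------------------------------------------------------------
# connection strength

def connection_strength(
    timestamps_s: np.ndarray,
    episode: StimulationEpisode,
    grid_ms: float = 1.0,
    sigma_ms: float = 1.5,
) -> float:
    """Maximum cross-correlation of the stimulus boxcar train with the
    smoothed spike events of one episode.

    S is 1 inside each 50-ms pulse (a boxcar centred 25 ms after onset)
    and 0 elsewhere; E comprises the spikes between the first onset and
    the end of the last pulse, smoothed with a Gaussian of sigma 1.5 ms
    (full 1/e width 3 ms). Lags are limited to +- one inter-pulse
    interval. Returns 0 when no spikes fall in the episode span.
    """
    t = np.asarray(timestamps_s, float)
    span0, span1 = episode.span_s
    t = t[(t >= span0) & (t <= span1)]
    if t.size == 0:
        return 0.0

    dt = grid_ms / 1e3
    n = int(np.ceil((span1 - span0) / dt)) + 1
    grid0 = span0
    s_arr = np.zeros(n)
    width = episode.pulse_width_ms / 1e3
    for onset in episode.onsets:
        i0 = int(round((onset - grid0) / dt))
        i1 = int(round((onset + width - grid0) / dt))
        s_arr[max(i0, 0) : min(i1 + 1, n)] = 1.0

    e_arr = np.zeros(n)
    idx = np.clip(np.round((t - grid0) / dt).astype(int), 0, n - 1)
    np.add.at(e_arr, idx, 1.0)
    half = int(np.ceil(5 * sigma_ms / grid_ms))
    k_t = np.arange(-half, half + 1) * grid_ms
    kernel = np.exp(-0.5 * (k_t / sigma_ms) ** 2)
    e_smooth = np.convolve(e_arr, kernel, mode="same")

    xc = np.correlate(s_arr, e_smooth, mode="full")
    lags = np.arange(-(n - 1), n)
    max_lag = int(round(episode.inter_pulse_interval_s / dt))
    keep = np.abs(lags) <= max_lag
    return float(xc[keep].max())


# ---------------------------------------------------------------------------
# maps

@dataclass
class NeuronElectrodeMap:
    """Valid stimulated-neuron -> unit-on-electrode connections n_ijk.

    ``n_conn_neuron[i]`` counts valid connections of the neuron stimulated
    in episode i (summing over units and electrodes); ``n_conn_electrode[k]``
    counts valid connections terminating on electrode k (summing over
    episodes and units).
    """

    connections: pd.DataFrame  # episode_id, electrode, unit, strength, p_max
    n_stimulated_neurons: int = 0

    @property
    def n_conn_neuron(self) -> pd.Series:
        if self.connections.empty:
            return pd.Series(dtype=int)
        return self.connections.groupby("episode_id").size()

    @property
    def n_conn_electrode(self) -> pd.Series:
        if self.connections.empty:
            return pd.Series(dtype=int)
        return self.connections.groupby("electrode").size()

    def n_conn_electrode_normalized(self) -> pd.Series:
        """Per-electrode counts divided by the number of stimulated neurons."""
        if self.n_stimulated_neurons <= 0:
            raise ValueError("number of stimulated neurons unknown")
        return self.n_conn_electrode / self.n_stimulated_neurons


def build_neuron_map(
    tests: list[ConnectionTest],
    n_stimulated_neurons: int | None = None,
) -> NeuronElectrodeMap:
    """Collect the valid connections of a stimulation experiment."""
    seen = set()
    for ct in tests:
        key = (ct.episode_id, ct.electrode, ct.unit)
        if key in seen:
            raise ValueError(f"duplicate connection test for {key}")
        seen.add(key)
    rows = [
        (ct.episode_id, ct.electrode, ct.unit, ct.strength, float(ct.p_values.max()))
        for ct in tests
        if ct.valid
    ]
    conns = pd.DataFrame(
        rows, columns=["episode_id", "electrode", "unit", "strength", "p_max"]
    )
    n_stim = (
        n_stimulated_neurons
        if n_stimulated_neurons is not None
        else len({ct.episode_id for ct in tests})
    )
    return NeuronElectrodeMap(conns, n_stim)


@dataclass
class ElectrodeMatrix:
    """Symmetric electrode-electrode connection strengths with
    normalization metadata."""

    matrix: pd.DataFrame
    experiment_duration_s: float
    cross_day_max: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        if not np.allclose(m, m.T):
            raise ValueError("electrode matrix must be symmetric")
        if np.diag(m).any():
            raise ValueError("electrode matrix must have a zero diagonal")
        if (m < 0).any():
            raise ValueError("electrode matrix entries must be non-negative")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(**{k: v for k, v in self.metadata.items()})
        g.add_nodes_from(self.matrix.index)
        m = self.matrix.to_numpy(float)
        ids = list(self.matrix.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if m[i, j] > 0:
                    g.add_edge(ids[i], ids[j], weight=float(m[i, j]))
        return g


def electrode_matrix(
    nmap: NeuronElectrodeMap,
    electrode_ids: list[str],
    experiment_duration_s: float,
) -> ElectrodeMatrix:
    """Convert neuron->electrode connections to electrode-electrode strengths.

    For every episode whose valid connections span >= 2 distinct
    electrodes, each unordered electrode pair is incremented by one
    (one increment per pair per episode, regardless of how many units
    responded). The matrix is normalized by the experiment duration.
    """
    if experiment_duration_s <= 0:
        raise ValueError("experiment duration must be positive")
    n = len(electrode_ids)
    idx = {e: i for i, e in enumerate(electrode_ids)}
    m = np.zeros((n, n))
    if not nmap.connections.empty:
        for _, grp in nmap.connections.groupby("episode_id"):
            elecs = sorted(set(grp["electrode"]))
            for i, a in enumerate(elecs):
                for b in elecs[i + 1 :]:
                    m[idx[a], idx[b]] += 1.0
                    m[idx[b], idx[a]] += 1.0
    m /= experiment_duration_s
    frame = pd.DataFrame(m, index=electrode_ids, columns=electrode_ids)
    return ElectrodeMatrix(
        frame,
        experiment_duration_s,
        metadata={"normalized_by": "experiment_duration_s"},
    )


def normalize_across_days(matrices: list[ElectrodeMatrix]) -> list[ElectrodeMatrix]:
    """Scale duration-normalized matrices by their common cross-day maximum."""
    if not matrices:
        return []
    peak = max(float(em.matrix.to_numpy().max()) for em in matrices)
    if peak == 0:
        peak = 1.0
    out = []
    for em in matrices:
        out.append(
            ElectrodeMatrix(
                em.matrix / peak,
                em.experiment_duration_s,
                cross_day_max=peak,
                metadata={**em.metadata, "cross_day_max": peak},
            )
        )
    return out
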