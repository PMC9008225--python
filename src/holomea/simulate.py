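"""Event-driven simulation of optogenetically stimulated MEA cultures.

The simulator produces ground-truth spike tables with the statistical
structure the downstream analysis assumes:

* spontaneous per-neuron Poisson firing plus synchronized network bursts,
  with a per-session maturation scale;
* direct ChR2-like responses: a targeted opsin-positive neuron spikes
  within each light pulse with a configurable probability at a jittered
  latency;
* synaptic propagation along the ground-truth graph with per-edge
  transmission probability and delay, suppressible by a blockade switch
  emulating NBQX/APV;
* extracellular rendering: every spike inserts a biphasic waveform on
  each electrode within a pickup radius, attenuated with distance, on top
  of Gaussian noise.

A 2 ms refractory period per neuron keeps propagation through recurrent
graphs finite.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .episodes import StimulationEpisode
from .layout import MEALayout
from .network import NetworkGroundTruth
from .recording import RawRecording

__all__ = [
    "SimConfig",
    "simulate_recording",
    "render_extracellular",
    "ground_truth_units",
    "spike_waveform",
    "maturation_scales",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults model a mature active culture.

    Rates are per neuron; amplitudes and noise are in uV. The attenuation
    law is ``1 / (1 + (d/d0)^2)`` and electrodes farther than
    ``attenuation_radius_um`` from a neuron pick up nothing.
    """

    duration_s: float = 60.0
    fs: float = 25_000.0
    spont_rate_hz: float = 0.5
    burst_rate_hz: float = 0.04
    burst_n_spikes: int = 8
    burst_intra_isi_ms: float = 6.0
    burst_participation: float = 0.8
    burst_jitter_ms: float = 10.0
    chr2_spike_prob: float = 0.9
    direct_latency_ms: float = 8.0
    direct_jitter_ms: float = 2.0
    synaptic_blockade: bool = False
    noise_sd: float = 3.0
    attenuation_radius_um: float = 60.0
    attenuation_d0_um: float = 20.0
    refractory_ms: float = 2.0
    session_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for p in (self.chr2_spike_prob, self.burst_participation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def for_session(self, scale: float) -> "SimConfig":
        """Scaled copy emulating network maturation across sessions."""
        return replace(
            self,
            spont_rate_hz=self.spont_rate_hz * scale,
            burst_rate_hz=self.burst_rate_hz * scale,
            session_scale=scale,
        )


def maturation_scales(n_sessions: int, shape: str = "sigmoid") -> np.ndarray:
    """Per-session activity multipliers for multi-day emulation.

    ``sigmoid`` rises from ~0.1 to ~1.8 (rate growth then plateau);
    ``linear`` ramps 0.2 -> 2.0.
    """
    x = np.linspace(-2.5, 2.5, n_sessions)
    if shape == "sigmoid":
        return 0.1 + 1.7 / (1.0 + np.exp(-1.5 * x))
    if shape == "linear":
        return np.linspace(0.2, 2.0, n_sessions)
    raise ValueError(f"unknown maturation shape {shape!r}")


def _spontaneous_events(
    net: NetworkGroundTruth, cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[float, int]]:
    events: list[tuple[float, int]] = []
    # independent Poisson firing
    for n in range(net.n_neurons):
        count = rng.poisson(cfg.spont_rate_hz * cfg.duration_s)
        for t in rng.uniform(0.0, cfg.duration_s, count):
            events.append((float(t), n))
    # synchronized network bursts
    n_bursts = rng.poisson(cfg.burst_rate_hz * cfg.duration_s)
    burst_starts = rng.uniform(0.0, cfg.duration_s, n_bursts)
    for t0 in burst_starts:
        for n in range(net.n_neurons):
            if rng.random() >= cfg.burst_participation:
                continue
            onset = t0 + abs(rng.normal(0.0, cfg.burst_jitter_ms / 1e3))
            isis = rng.exponential(cfg.burst_intra_isi_ms / 1e3, cfg.burst_n_spikes)
            isis = np.maximum(isis, cfg.refractory_ms / 1e3)
            for t in onset + np.cumsum(isis):
                if t < cfg.duration_s:
                    events.append((float(t), n))
    return events


def _evoked_events(
    net: NetworkGroundTruth,
    cfg: SimConfig,
    episodes: list[StimulationEpisode],
    rng: np.random.Generator,
    allow_non_opsin: bool,
) -> list[tuple[float, int]]:
    events: list[tuple[float, int]] = []
    spans: list[tuple[float, float]] = []
    for ep in episodes:
        span = ep.span_s
        for s0, s1 in spans:
            if span[0] < s1 and s0 < span[1]:
                raise ValueError(f"episode {ep.episode_id} overlaps another episode")
        spans.append(span)
        if ep.mode == "full_field":
            targets = np.nonzero(net.expresses_opsin)[0]
        else:
            if ep.target_neuron is None:
                raise ValueError(
                    f"holographic episode {ep.episode_id} lacks a target neuron"
                )
            if not net.expresses_opsin[ep.target_neuron] and not allow_non_opsin:
                raise ValueError(
                    f"episode {ep.episode_id} targets non-opsin neuron "
                    f"{ep.target_neuron}"
                )
            targets = np.array([ep.target_neuron])
        for onset in ep.onsets:
            for n in targets:
                if rng.random() < cfg.chr2_spike_prob:
                    lat = cfg.direct_latency_ms + rng.normal(0.0, cfg.direct_jitter_ms)
                    t = onset + max(lat, 0.5) / 1e3
                    if t < cfg.duration_s:
                        events.append((float(t), int(n)))
    return events


def simulate_recording(
    net: NetworkGroundTruth,
    cfg: SimConfig,
    episodes: list[StimulationEpisode] | None = None,
    seed: int | None = None,
    allow_non_opsin: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ground-truth spiking under a stimulation protocol.

    Returns
    -------
    spikes:
        DataFrame with columns ``time_s``, ``neuron``, ``source``
        (``spont``/``evoked``/``synaptic``), time-sorted.
    stimulus_log:
        One row per light pulse: ``episode_id, pulse_index, onset_s,
        target_x, target_y, mode``.
    """
    episodes = list(episodes or [])
    rng = np.random.default_rng(seed)

    sources = [(t, n, "spont") for t, n in _spontaneous_events(net, cfg, rng)]
    sources += [
        (t, n, "evoked")
        for t, n in _evoked_events(net, cfg, episodes, rng, allow_non_opsin)
    ]

    counter = itertools.count()
    heap = [(t, next(counter), n, src) for t, n, src in sources]
    heapq.heapify(heap)

    refractory = cfg.refractory_ms / 1e3
    last_spike = np.full(net.n_neurons, -np.inf)
    out: list[tuple[float, int, str]] = []
    while heap:
        t, _, n, src = heapq.heappop(heap)
        if t - last_spike[n] < refractory:
            continue
        last_spike[n] = t
        out.append((t, n, src))
        if cfg.synaptic_blockade:
            continue
        for ei in net.out_edges(n):
            if rng.random() < net.weights[ei]:
                t_post = t + net.delays_ms[ei] / 1e3
                if t_post < cfg.duration_s:
                    heapq.heappush(
                        heap, (t_post, next(counter), int(net.edges[ei, 1]), "synaptic")
                    )

    spikes = pd.DataFrame(out, columns=["time_s", "neuron", "source"])
    spikes = spikes.sort_values("time_s", kind="stable").reset_index(drop=True)

    log_rows = []
    for ep in episodes:
        tx, ty = ep.target_xy if ep.target_xy is not None else (np.nan, np.nan)
        for k, onset in enumerate(ep.onsets):
            log_rows.append((ep.episode_id, k, float(onset), tx, ty, ep.mode))
    stimulus_log = pd.DataFrame(
        log_rows,
        columns=["episode_id", "pulse_index", "onset_s", "target_x", "target_y", "mode"],
    )
    return spikes, stimulus_log


def spike_waveform(fs: float, duration_ms: float = 2.0) -> np.ndarray:
    """Biphasic extracellular template: sharp negative lobe, slower positive
    rebound; negative peak amplitude -1 at 0.55 ms into the template."""
    t = np.arange(int(round(duration_ms / 1e3 * fs))) / fs * 1e3  # ms
    w = -np.exp(-(((t - 0.55) / 0.18) ** 2)) + 0.45 * np.exp(
        -(((t - 1.15) / 0.35) ** 2)
    )
    return w


#: Sample offset of the template's negative peak, as a fraction of 1 ms.
_TEMPLATE_PEAK_MS = 0.55


def _attenuation(d: np.ndarray, d0: float) -> np.ndarray:
    return 1.0 / (1.0 + (d / d0) ** 2)


def pickup_map(
    net: NetworkGroundTruth, layout: MEALayout, cfg: SimConfig
) -> dict[int, list[tuple[int, float]]]:
    """Neuron -> [(channel index, gain)] for electrodes within pickup radius."""
    centers = layout.electrode_centers
    mapping: dict[int, list[tuple[int, float]]] = {}
    for n, pos in enumerate(net.neuron_positions):
        d = np.linalg.norm(centers - pos[None, :], axis=1)
        near = np.nonzero(d <= cfg.attenuation_radius_um)[0]
        mapping[n] = [
            (int(c), float(net.amplitudes[n] * _attenuation(d[c], cfg.attenuation_d0_um)))
            for c in near
        ]
    return mapping


def render_extracellular(
    spikes: pd.DataFrame,
    net: NetworkGroundTruth,
    layout: MEALayout,
    cfg: SimConfig,
    seed: int | None = None,
    session_id: str = "session0",
) -> RawRecording:
    """Render ground-truth spikes into sampled extracellular voltage traces."""
    rng = np.random.default_rng(seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    n_channels = layout.n_electrodes
    signals = np.zeros((n_channels, n_samples), dtype=np.float64)

    template = spike_waveform(cfg.fs)
    peak_offset = int(round(_TEMPLATE_PEAK_MS / 1e3 * cfg.fs))
    gains = pickup_map(net, layout, cfg)

    for t, n in zip(spikes["time_s"].to_numpy(), spikes["neuron"].to_numpy()):
        targets = gains.get(int(n))
        if not targets:
            continue
        start = int(round(t * cfg.fs)) - peak_offset
        lo = max(start, 0)
        hi = min(start + len(template), n_samples)
        if hi <= lo:
            continue
        seg = template[lo - start : hi - start]
        for ch, gain in targets:
            signals[ch, lo:hi] += gain * seg

    if cfg.noise_sd > 0:
        signals += rng.normal(0.0, cfg.noise_sd, signals.shape)

    return RawRecording(
        signals=signals.astype(np.float32),
        fs=cfg.fs,
        electrode_ids=layout.electrode_ids,
        layout=layout,
        session_id=session_id,
    )


def ground_truth_units(
    spikes: pd.DataFrame,
    net: NetworkGroundTruth,
    layout: MEALayout,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Ideal unit-resolved spike table: each neuron appears as one unit on
    every electrode within pickup radius.

    Bypasses waveform rendering and detection; used for parameter-recovery
    tests of the connectivity stages in isolation.
    """
    ids = layout.electrode_ids
    gains = pickup_map(net, layout, cfg)
    rows = []
    for t, n in zip(spikes["time_s"].to_numpy(), spikes["neuron"].to_numpy()):
        for ch, _ in gains.get(int(n), ()):
            rows.append((t, ids[ch], f"n{int(n)}", int(n)))
    table = pd.DataFrame(rows, columns=["time_s", "electrode", "unit", "neuron"])
    return table.sort_values("time_s", kind="stable").reset_index(drop=True)
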