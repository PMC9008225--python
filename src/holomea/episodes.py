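"""Stimulation episode descriptions.

An episode is one stimulation bout: either a holographic train of 20-30
focused light pulses targeting a single neuron (50 ms pulses at 2 Hz), or
a full-field pulse train illuminating the whole culture (50 ms at 0.5 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulationEpisode",
    "holographic_episode",
    "full_field_train",
    "episodes_from_log",
    "FULL_FIELD",
]

#: Sentinel target marking whole-culture illumination.
FULL_FIELD = "full_field"


@dataclass(frozen=True)
class StimulationEpisode:
    """One stimulation episode.

    Attributes
    ----------
    episode_id:
        Unique identifier within an experiment.
    target_xy:
        (x, y) of the targeted neuron in um, or ``None`` for full-field.
    pulse_onsets_s:
        Strictly increasing pulse onset times tau_k (s).
    pulse_width_ms:
        Light pulse duration, default 50 ms.
    mode:
        ``"holographic"`` or ``"full_field"``.
    wavelength_nm:
        Stimulation wavelength tag (450 nm holographic, 470 nm full-field).
    target_neuron:
        Optional ground-truth neuron index (simulation only).
    """

    episode_id: str
    target_xy: tuple[float, float] | None
    pulse_onsets_s: tuple[float, ...]
    pulse_width_ms: float = 50.0
    mode: str = "holographic"
    wavelength_nm: float = 450.0
    target_neuron: int | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.pulse_onsets_s, float)
        if onsets.size == 0:
            raise ValueError("episode must contain at least one pulse")
        if onsets.size > 1 and not (np.diff(onsets) > 0).all():
            raise ValueError("pulse onsets must be strictly increasing")
        if self.mode not in ("holographic", "full_field"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_pulses(self) -> int:
        """Number of stimulus repetitions M (= N_stim)."""
        return len(self.pulse_onsets_s)

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray(self.pulse_onsets_s, float)

    @property
    def inter_pulse_interval_s(self) -> float:
        """Median inter-pulse interval; pulse-period window for latency analysis."""
        if self.n_pulses < 2:
            return self.pulse_width_ms / 1000.0 + 0.025
        return float(np.median(np.diff(self.onsets)))

    @property
    def span_s(self) -> tuple[float, float]:
        """[first onset, last onset + pulse width]."""
        return (
            float(self.onsets[0]),
            float(self.onsets[-1] + self.pulse_width_ms / 1000.0),
        )


def holographic_episode(
    episode_id: str,
    target_xy: tuple[float, float],
    start_s: float,
    n_pulses: int = 20,
    rate_hz: float = 2.0,
    pulse_width_ms: float = 50.0,
    target_neuron: int | None = None,
) -> StimulationEpisode:
    """Single-neuron episode: default 20 pulses of 50 ms at 2 Hz, 450 nm."""
    onsets = start_s + np.arange(n_pulses) / rate_hz
    return StimulationEpisode(
        episode_id=episode_id,
        target_xy=tuple(map(float, target_xy)),
        pulse_onsets_s=tuple(onsets),
        pulse_width_ms=pulse_width_ms,
        mode="holographic",
        wavelength_nm=450.0,
        target_neuron=target_neuron,
    )


def episodes_from_log(log, pulse_width_ms: float = 50.0) -> list[StimulationEpisode]:
    """Rebuild episode objects from a stimulus log table.

    The log has one row per pulse with columns ``episode_id, pulse_index,
    onset_s, target_x, target_y, mode`` (the simulator's output format).
    """
    episodes = []
    for eid, grp in log.groupby("episode_id", sort=False):
        grp = grp.sort_values("pulse_index")
        tx = grp["target_x"].iloc[0]
        ty = grp["target_y"].iloc[0]
        target = None if np.isnan(tx) else (float(tx), float(ty))
        episodes.append(
            StimulationEpisode(
                episode_id=str(eid),
                target_xy=target,
                pulse_onsets_s=tuple(grp["onset_s"].astype(float)),
                pulse_width_ms=pulse_width_ms,
                mode=str(grp["mode"].iloc[0]),
            )
        )
    return episodes


def full_field_train(
    episode_id: str,
    start_s: float,
    n_pulses: int = 23,
    rate_hz: float = 0.5,
    pulse_width_ms: float = 50.0,
) -> StimulationEpisode:
    """Whole-culture pulse train: default 50 ms pulses at 0.5 Hz, 470 nm."""
    onsets = start_s + np.arange(n_pulses) / rate_hz
    return StimulationEpisode(
        episode_id=episode_id,
        target_xy=None,
        pulse_onsets_s=tuple(onsets),
        pulse_width_ms=pulse_width_ms,
        mode="full_field",
        wavelength_nm=470.0,
        target_neuron=None,
    )
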