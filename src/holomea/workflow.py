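"""Pipeline orchestration: simulate -> detect -> analyze -> map.

A :class:`RunConfig` fully serializes one run: layout and network
geometry, simulation parameters, stimulation protocol, analysis
thresholds, stage toggles, and one master seed from which every stage
derives its own stream. Re-running with the same config reproduces the
same outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import entropy, simulate, spikes, stimmap
from .episodes import StimulationEpisode, holographic_episode
from .layout import MEALayout
from .network import NetworkGroundTruth, generate_network
from .simulate import SimConfig

log = logging.getLogger("holomea")

__all__ = ["RunConfig", "run_pipeline", "export_maps", "stim_connectivity_tests"]


@dataclass
class RunConfig:
    """Complete description of one simulation + analysis run."""

    # geometry / network
    layout: dict = field(default_factory=dict)  # MEALayout kwargs; {} = 60MEA default
    n_neurons: int = 30
    density: float = 0.05
    weight_range: tuple[float, float] = (0.3, 1.0)
    delay_range_ms: tuple[float, float] = (2.0, 10.0)
    # simulation
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    baseline_s: float = 20.0
    n_episodes: int = 10
    n_pulses: int = 20
    pulse_rate_hz: float = 2.0
    inter_episode_gap_s: float = 1.0
    # stage toggles
    render: bool = False  # False: analyze ground-truth unit tables directly
    run_baseline_map: bool = True
    run_stim_map: bool = True
    # analysis parameters
    k_sigma: float = 5.0
    r_threshold: float = 0.1
    segment_s: float = 0.250
    overlap: float = 0.8
    alpha: float = 0.01
    # bookkeeping
    seed: int = 0
    session_id: str = "session0"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def make_layout(self) -> MEALayout:
        if not self.layout:
            return MEALayout.default_60mea()
        kw = dict(self.layout)
        if "excluded_positions" in kw:
            kw["excluded_positions"] = tuple(tuple(p) for p in kw["excluded_positions"])
        return MEALayout(**kw)

    def make_sim_config(self, duration_s: float) -> SimConfig:
        return SimConfig(duration_s=duration_s, **self.sim)


def _derive_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def stim_connectivity_tests(
    units: pd.DataFrame,
    episodes: list[StimulationEpisode],
    baseline_span_s: tuple[float, float],
    alpha: float = 0.01,
) -> list[stimmap.ConnectionTest]:
    """Run the leave-one-out KS battery for every (episode, electrode, unit)
    candidate and attach connection strengths to the valid ones."""
    tests: list[stimmap.ConnectionTest] = []
    groups = {
        key: np.sort(grp["time_s"].to_numpy())
        for key, grp in units.groupby(["electrode", "unit"])
    }
    b0, b1 = baseline_span_s
    for ep in episodes:
        for (eid, uid), ts in sorted(groups.items()):
            baseline = ts[(ts >= b0) & (ts < b1)]
            ct = stimmap.validate_connection(
                ts, ep, baseline, baseline_span_s, alpha=alpha,
                electrode=eid, unit=uid,
            )
            if ct.valid:
                ct.strength = stimmap.connection_strength(ts, ep)
            tests.append(ct)
    return tests


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages and write all artifacts to ``out_dir``.

    Returns the machine-readable summary that is also written to
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed, 4)

    layout = config.make_layout()
    layout.to_json(out / "layout.json")

    net = generate_network(
        config.n_neurons,
        layout,
        density=config.density,
        weight_range=tuple(config.weight_range),
        delay_range_ms=tuple(config.delay_range_ms),
        seed=seeds[0],
    )

    # stimulation protocol: one holographic episode per selected opsin neuron
    rng = np.random.default_rng(seeds[1])
    opsin = np.nonzero(net.expresses_opsin)[0]
    if config.run_stim_map and opsin.size == 0:
        raise ValueError("no opsin-expressing neurons to stimulate")
    n_ep = min(config.n_episodes, opsin.size)
    targets = rng.choice(opsin, size=n_ep, replace=False) if config.run_stim_map else []
    episode_len = config.n_pulses / config.pulse_rate_hz
    episodes = []
    t0 = config.baseline_s
    for i, n in enumerate(targets):
        episodes.append(
            holographic_episode(
                f"ep{i:03d}",
                tuple(net.neuron_positions[n]),
                start_s=t0,
                n_pulses=config.n_pulses,
                rate_hz=config.pulse_rate_hz,
                target_neuron=int(n),
            )
        )
        t0 += episode_len + config.inter_episode_gap_s

    duration = t0 + 1.0
    sim_cfg = config.make_sim_config(duration)
    log.info("simulating %.1f s, %d neurons, %d episodes", duration, net.n_neurons, n_ep)
    gt_spikes, stim_log = simulate.simulate_recording(net, sim_cfg, episodes, seed=seeds[2])
    gt_spikes.to_csv(out / "ground_truth_spikes.csv", index=False)
    stim_log.to_csv(out / "stimulus_log.csv", index=False)

    if config.render:
        rec = simulate.render_extracellular(
            gt_spikes, net, layout, sim_cfg, seed=seeds[3], session_id=config.session_id
        )
        rec.to_hdf5(out / "recording.h5")
        filtered = spikes.highpass(rec)
        trains = spikes.detect_spikes(filtered, k_sigma=config.k_sigma)
        snippets = {
            eid: spikes.extract_snippets(
                np.asarray(filtered.channel(eid), float), filtered.fs, tr.timestamps_s
            )
            for eid, tr in trains.items()
        }
        templates = _unit_templates(net, layout, sim_cfg)
        units = spikes.assign_units(trains, snippets, templates)
        units["neuron"] = units["unit"].str.lstrip("n").astype(int)
    else:
        filtered = None
        units = simulate.ground_truth_units(gt_spikes, net, layout, sim_cfg)
    units.to_csv(out / "units.csv", index=False)

    summary: dict = {
        "seed": config.seed,
        "n_neurons": net.n_neurons,
        "n_edges": net.n_edges,
        "n_episodes": len(episodes),
        "n_ground_truth_spikes": int(len(gt_spikes)),
        "n_unit_spikes": int(len(units)),
        "n_units": int(units.groupby(["electrode", "unit"]).ngroups) if len(units) else 0,
    }

    if config.run_baseline_map:
        if filtered is None:
            rec = simulate.render_extracellular(
                gt_spikes, net, layout, sim_cfg, seed=seeds[3],
                session_id=config.session_id,
            )
            filtered = spikes.highpass(rec)
        n_base = int(config.baseline_s * filtered.fs)
        base_rec = type(filtered)(
            signals=filtered.signals[:, :n_base],
            fs=filtered.fs,
            electrode_ids=list(filtered.electrode_ids),
            layout=layout,
            session_id=config.session_id,
        )
        graph = entropy.baseline_map(
            base_rec,
            r_threshold=config.r_threshold,
            segment_s=config.segment_s,
            overlap=config.overlap,
        )
        export_maps({"baseline_map": graph}, "graphml", out)
        export_maps({"baseline_map": graph}, "csv", out)
        summary["baseline_nodes"] = graph.number_of_nodes()
        summary["baseline_edges"] = graph.number_of_edges()

    if config.run_stim_map and episodes:
        tests = stim_connectivity_tests(
            units, episodes, (0.0, config.baseline_s), alpha=config.alpha
        )
        nmap = stimmap.build_neuron_map(tests, n_stimulated_neurons=len(episodes))
        stim_duration = episodes[-1].span_s[1] - episodes[0].span_s[0]
        ematrix = stimmap.electrode_matrix(nmap, layout.electrode_ids, stim_duration)
        _write_connection_tables(tests, nmap, ematrix, out)
        summary["n_valid_connections"] = int(len(nmap.connections))
        summary["validation_rate"] = (
            float(np.mean([ct.valid for ct in tests])) if tests else 0.0
        )
        summary["n_conn_neuron_total"] = int(nmap.n_conn_neuron.sum())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _unit_templates(
    net: NetworkGroundTruth, layout: MEALayout, cfg: SimConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Per-electrode waveform templates from the simulator ground truth."""
    wf = simulate.spike_waveform(cfg.fs)
    gains = simulate.pickup_map(net, layout, cfg)
    ids = layout.electrode_ids
    templates: dict[str, dict[str, np.ndarray]] = {}
    for n, targets in gains.items():
        for ch, gain in targets:
            templates.setdefault(ids[ch], {})[f"n{n}"] = gain * wf
    return templates


def _write_connection_tables(tests, nmap, ematrix, out: Path) -> None:
    rows = [
        (
            ct.episode_id, ct.electrode, ct.unit,
            float(ct.p_values.min()), float(ct.p_values.max()),
            bool(ct.valid), float(ct.strength),
        )
        for ct in tests
    ]
    pd.DataFrame(
        rows,
        columns=["episode_id", "electrode", "unit", "p_min", "p_max", "valid", "strength"],
    ).to_csv(out / "connection_tests.csv", index=False)
    nmap.connections.to_csv(out / "valid_connections.csv", index=False)
    ematrix.matrix.to_csv(out / "electrode_matrix.csv")
    with open(out / "electrode_matrix_meta.json", "w") as fh:
        json.dump(
            {
                "experiment_duration_s": ematrix.experiment_duration_s,
                "cross_day_max": ematrix.cross_day_max,
                **ematrix.metadata,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def export_maps(maps: dict, fmt: str, out_dir) -> list[Path]:
    """Export connectivity maps losslessly as graphml, csv, or json.

    ``maps`` is ``{name: object}`` where objects are
    :class:`networkx.Graph` or :class:`~holomea.stimmap.ElectrodeMatrix`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in maps.items():
        graph = obj.to_graph() if isinstance(obj, stimmap.ElectrodeMatrix) else obj
        if fmt == "graphml":
            path = out / f"{name}.graphml"
            nx.write_graphml(graph, path)
        elif fmt == "csv":
            path = out / f"{name}_edges.csv"
            rows = [
                (a, b, data.get("weight", 1.0))
                for a, b, data in graph.edges(data=True)
            ]
            pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
                path, index=False
            )
        elif fmt == "json":
            path = out / f"{name}.json"
            payload = nx.node_link_data(graph, edges="edges")
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
        written.append(path)
    return written
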