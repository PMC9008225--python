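"""Ground-truth synthetic networks.

A :class:`NetworkGroundTruth` is a directed weighted graph of point neurons
placed on the plane of an MEA. Edge weights are synaptic transmission
probabilities in [0, 1] and each edge carries a fixed axonal+synaptic delay.
The ground truth is what parameter-recovery tests compare inferred
connectivity maps against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import MEALayout

__all__ = ["NetworkGroundTruth", "generate_network"]


@dataclass
class NetworkGroundTruth:
    """Directed weighted network of simulated neurons.

    Attributes
    ----------
    neuron_positions:
        (n_neurons, 2) array of (x, y) coordinates in um.
    edges:
        (n_edges, 2) integer array of (pre, post) neuron indices.
    weights:
        Per-edge transmission probability in [0, 1].
    delays_ms:
        Per-edge transmission delay, strictly positive (ms).
    expresses_opsin:
        Boolean flag per neuron; only opsin-positive neurons respond to
        light directly.
    seed:
        Seed used to generate the network (for provenance).
    """

    neuron_positions: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    delays_ms: np.ndarray
    expresses_opsin: np.ndarray
    seed: int | None = None
    amplitudes: np.ndarray = field(default=None)  # per-neuron spike amplitude scale

    def __post_init__(self) -> None:
        self.neuron_positions = np.atleast_2d(np.asarray(self.neuron_positions, float))
        self.edges = np.asarray(self.edges, int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, float)
        self.delays_ms = np.asarray(self.delays_ms, float)
        self.expresses_opsin = np.asarray(self.expresses_opsin, bool)
        if self.edges.size and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-edges are not allowed")
        if (self.delays_ms <= 0).any():
            raise ValueError("delays must be positive")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        if self.amplitudes is None:
            self.amplitudes = np.full(self.n_neurons, 200.0)

    @property
    def n_neurons(self) -> int:
        return self.neuron_positions.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def out_edges(self, neuron: int) -> np.ndarray:
        """Indices into the edge arrays of edges leaving ``neuron``."""
        return np.nonzero(self.edges[:, 0] == neuron)[0]


def generate_network(
    n_neurons: int,
    layout: MEALayout,
    density: float = 0.05,
    weight_range: tuple[float, float] = (0.3, 1.0),
    delay_range_ms: tuple[float, float] = (2.0, 10.0),
    opsin_fraction: float = 1.0,
    amplitude_range: tuple[float, float] = (150.0, 250.0),
    placement: str = "uniform",
    seed: int | None = None,
) -> NetworkGroundTruth:
    """Sample a random directed network over the layout's bounding box.

    Each ordered neuron pair becomes an edge independently with probability
    ``density``, so the expected edge count is ``density * n * (n - 1)``.
    Positions are uniform over the electrode bounding box by default;
    ``placement="clustered"`` draws positions from Gaussian clusters instead,
    mimicking aggregated cultures.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if not (0.0 < delay_range_ms[0] <= delay_range_ms[1] <= 50.0):
        raise ValueError("delay range must lie within (0, 50] ms")

    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = layout.bounding_box()

    if placement == "uniform":
        xs = rng.uniform(xmin, xmax, n_neurons)
        ys = rng.uniform(ymin, ymax, n_neurons)
    elif placement == "clustered":
        n_clusters = max(1, n_neurons // 20)
        cx = rng.uniform(xmin, xmax, n_clusters)
        cy = rng.uniform(ymin, ymax, n_clusters)
        which = rng.integers(0, n_clusters, n_neurons)
        spread = 0.5 * layout.pitch
        xs = np.clip(cx[which] + rng.normal(0, spread, n_neurons), xmin, xmax)
        ys = np.clip(cy[which] + rng.normal(0, spread, n_neurons), ymin, ymax)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    positions = np.column_stack([xs, ys])

    pre, post = np.meshgrid(np.arange(n_neurons), np.arange(n_neurons), indexing="ij")
    mask = pre != post
    pairs = np.column_stack([pre[mask], post[mask]])
    keep = rng.random(len(pairs)) < density
    edges = pairs[keep]
    weights = rng.uniform(*weight_range, len(edges))
    delays = rng.uniform(*delay_range_ms, len(edges))
    opsin = rng.random(n_neurons) < opsin_fraction
    amplitudes = rng.uniform(*amplitude_range, n_neurons)

    return NetworkGroundTruth(
        neuron_positions=positions,
        edges=edges,
        weights=weights,
        delays_ms=delays,
        expresses_opsin=opsin,
        seed=seed,
        amplitudes=amplitudes,
    )
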