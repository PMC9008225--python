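"""Multi-electrode array geometry.

An :class:`MEALayout` describes the recording grid shared by the simulator,
the distance-dependent response analysis, and hologram/grid registration.
The default layout models a 60MEA200/30-style array: an 8x8 grid with
200 um pitch and 30 um electrode diameter, with the four corner positions
absent and one position occupied by the internal counter electrode, which
leaves 59 recording electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MEALayout"]


@dataclass(frozen=True)
class MEALayout:
    """Electrode grid geometry, coordinates in micrometres.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions.
    pitch:
        Centre-to-centre electrode spacing (um).
    electrode_diameter:
        Electrode diameter (um); must be smaller than the pitch.
    excluded_positions:
        ``(row, col)`` pairs that carry no recording electrode (missing
        corners, counter electrode).
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch: float = 200.0
    electrode_diameter: float = 30.0
    excluded_positions: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch <= self.electrode_diameter:
            raise ValueError("pitch must exceed electrode diameter")
        if self.n_electrodes < 1:
            raise ValueError("layout has no recording electrodes")

    @classmethod
    def default_60mea(cls) -> "MEALayout":
        """8x8 grid, 200 um pitch, 30 um diameter, 59 recording electrodes.

        The four corners are absent and position (0, 3) holds the internal
        counter electrode.
        """
        excluded = ((0, 0), (0, 7), (7, 0), (7, 7), (0, 3))
        return cls(8, 8, 200.0, 30.0, excluded)

    @property
    def grid_positions(self) -> list[tuple[int, int]]:
        """``(row, col)`` indices of recording electrodes, row-major order."""
        excluded = set(map(tuple, self.excluded_positions))
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in excluded
        ]

    @property
    def n_electrodes(self) -> int:
        return len(self.grid_positions)

    @property
    def electrode_centers(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) centres in um; x along columns."""
        pos = np.asarray(self.grid_positions, dtype=float)
        return np.column_stack([pos[:, 1] * self.pitch, pos[:, 0] * self.pitch])

    @property
    def electrode_ids(self) -> list[str]:
        """Electrode labels ``"r<row>c<col>"`` aligned with ``electrode_centers``."""
        return [f"r{r}c{c}" for r, c in self.grid_positions]

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the electrode centres (um)."""
        centers = self.electrode_centers
        xmin, ymin = centers.min(axis=0)
        xmax, ymax = centers.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": self.pitch,
            "electrode_diameter_um": self.electrode_diameter,
            "excluded_positions": [list(p) for p in self.excluded_positions],
            "electrodes": [
                {"id": eid, "row": r, "col": c, "x_um": x, "y_um": y}
                for eid, (r, c), (x, y) in zip(
                    self.electrode_ids, self.grid_positions, self.electrode_centers
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MEALayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            n_rows=payload["n_rows"],
            n_cols=payload["n_cols"],
            pitch=payload["pitch_um"],
            electrode_diameter=payload["electrode_diameter_um"],
            excluded_positions=tuple(
                tuple(p) for p in payload["excluded_positions"]
            ),
        )
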