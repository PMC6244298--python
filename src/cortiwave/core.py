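"""Shared data model for micro-ECoG grid recordings.

A recording session is a matrix of surface field potentials (microvolts)
sampled simultaneously on a rectangular micro-electrode grid.  The default
geometry is the 8 x 8 array with 500 um pitch used throughout the package;
three conventions are fixed here and used everywhere downstream:

* channels are 0-based and row-major from the top-left corner of the array
  as drawn (channel ``k`` sits at row ``k // n_cols``, column ``k % n_cols``
  unless an explicit ``channel_order`` says otherwise);
* physical coordinates are ``x = col * pitch`` (rightward) and
  ``y = row * pitch`` (downward), in micrometres;
* units are uV for voltages, ms for delays, radians for phases.

Bad (e.g. high-impedance) channels are carried as metadata and excluded
from downstream statistics rather than interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "MultichannelRecording",
    "GridMap",
    "map_to_grid",
    "grid_to_channels",
]


@dataclass(frozen=True)
class GridGeometry:
    """Electrode-grid layout: shape, pitch, channel placement, bad channels.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; ``n_rows * n_cols`` is the channel count.
    pitch
        Centre-to-centre electrode spacing in micrometres.
    channel_order
        ``(n_channels, 2)`` integer array mapping channel index ->
        ``(row, col)``.  ``None`` means row-major from the top-left.
    bad_channels
        Channel indices excluded from all statistics (never interpolated).
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch: float = 500.0
    channel_order: np.ndarray | None = None
    bad_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0 um, got {self.pitch}")
        if self.channel_order is not None:
            order = np.asarray(self.channel_order, dtype=int)
            if order.shape != (self.n_channels, 2):
                raise ValueError(
                    f"channel_order must have shape ({self.n_channels}, 2), "
                    f"got {order.shape}"
                )
            cells = {(int(r), int(c)) for r, c in order}
            if len(cells) != self.n_channels or any(
                not (0 <= r < self.n_rows and 0 <= c < self.n_cols)
                for r, c in cells
            ):
                raise ValueError("channel_order must be a bijection onto the grid")
            object.__setattr__(self, "channel_order", order)
        bad = frozenset(int(b) for b in self.bad_channels)
        if any(b < 0 or b >= self.n_channels for b in bad):
            raise ValueError("bad_channels outside the channel range")
        object.__setattr__(self, "bad_channels", bad)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def rowcol(self, channel: int) -> tuple[int, int]:
        """(row, col) cell of a channel index."""
        if self.channel_order is None:
            return divmod(int(channel), self.n_cols)
        r, c = self.channel_order[int(channel)]
        return int(r), int(c)

    def rowcols(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) per channel."""
        if self.channel_order is not None:
            return self.channel_order.copy()
        idx = np.arange(self.n_channels)
        return np.column_stack(divmod(idx, self.n_cols))

    def positions(self) -> np.ndarray:
        """(n_channels, 2) physical (x, y) positions in um (x right, y down)."""
        rc = self.rowcols()
        return np.column_stack((rc[:, 1] * self.pitch, rc[:, 0] * self.pitch)).astype(
            float
        )

    def good_channels(self) -> np.ndarray:
        """Sorted indices of channels not flagged bad."""
        return np.array(
            [k for k in range(self.n_channels) if k not in self.bad_channels],
            dtype=int,
        )


@dataclass
class MultichannelRecording:
    """Voltage traces (uV) for every grid channel plus acquisition metadata.

    ``data`` is ``(n_channels, n_samples)``; ``fs`` the per-channel sampling
    rate in Hz; ``t0`` the absolute start time in seconds.
    """

    data: np.ndarray
    fs: float
    geometry: GridGeometry
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0 Hz, got {self.fs}")
        if self.data.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but geometry declares "
                f"{self.geometry.n_channels}"
            )
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            ch, s = bad[0]
            raise ValueError(
                f"non-finite sample at channel {ch}, sample {s} "
                f"({bad.shape[0]} non-finite values total)"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "MultichannelRecording":
        """Same metadata, new traces (shape-checked)."""
        return MultichannelRecording(data=data, fs=self.fs, geometry=self.geometry, t0=self.t0)


_GRIDMAP_KINDS = ("amplitude", "phase", "delay")


@dataclass
class GridMap:
    """One scalar per electrode arranged on the physical grid.

    ``values`` is ``(n_rows, n_cols)`` with NaN marking bad/missing cells.
    ``kind`` selects the unit convention: amplitude (uV), phase (radians,
    wrapped to (-pi, pi]), or delay (ms relative to a reference channel).
    """

    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridMap values must be 2-D")
        if self.kind not in _GRIDMAP_KINDS:
            raise ValueError(f"kind must be one of {_GRIDMAP_KINDS}, got {self.kind!r}")
        if self.kind == "phase":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
                raise ValueError("phase values must lie in (-pi, pi]")


def map_to_grid(values: np.ndarray, geometry: GridGeometry, kind: str = "amplitude",
                label: str = "") -> GridMap:
    """Arrange a per-channel vector on the electrode grid.

    ``values[k]`` is placed at ``geometry.channel_order[k]``; cells of bad
    channels are set to NaN (flagged missing, never interpolated).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (geometry.n_channels,):
        raise ValueError(
            f"expected {geometry.n_channels} values, got shape {values.shape}"
        )
    grid = np.full((geometry.n_rows, geometry.n_cols), np.nan)
    rc = geometry.rowcols()
    grid[rc[:, 0], rc[:, 1]] = values
    for b in geometry.bad_channels:
        r, c = geometry.rowcol(b)
        grid[r, c] = np.nan
    return GridMap(values=grid, kind=kind, label=label)


def grid_to_channels(gm: GridMap, geometry: GridGeometry) -> np.ndarray:
    """Inverse of :func:`map_to_grid`: read the grid back into channel order.

    Bad channels come back as NaN.
    """
    if gm.values.shape != (geometry.n_rows, geometry.n_cols):
        raise ValueError("grid shape does not match geometry")
    rc = geometry.rowcols()
    return gm.values[rc[:, 0], rc[:, 1]].copy()


def warn_short(condition: bool, message: str) -> None:
    """Internal helper: emit a UserWarning when ``condition`` holds."""
    if condition:
        warnings.warn(message, UserWarning, stacklevel=3)
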