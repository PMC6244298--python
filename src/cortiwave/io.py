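"""Readers and writers for recordings and grid maps.

Two containers are supported:

* **HDF5** (lossless): datasets ``/data`` (channels x samples, float64 uV),
  ``/fs``, ``/t0`` and a ``/geometry`` group holding ``n_rows``, ``n_cols``,
  ``pitch``, ``channel_order`` and ``bad_channels``.
* **CSV** (documented import/export path): one row per channel, preceded by
  a ``#`` comment line carrying the sampling rate and the geometry as JSON.

Validation happens on load: the declared channel count must match the
geometry and every sample must be finite.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import GridGeometry, GridMap, MultichannelRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_gridmap_csv",
    "save_gridmap_png",
]

_CSV_DECIMALS = 6  # uV stored to 1e-6 uV in the text path


def _geometry_to_dict(g: GridGeometry) -> dict:
    return {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "pitch": g.pitch,
        "channel_order": None if g.channel_order is None else np.asarray(g.channel_order).tolist(),
        "bad_channels": sorted(g.bad_channels),
    }


def _geometry_from_dict(d: dict) -> GridGeometry:
    for key in ("n_rows", "n_cols", "pitch"):
        if key not in d:
            raise ValueError(f"geometry metadata missing required field {key!r}")
    order = d.get("channel_order")
    return GridGeometry(
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        pitch=float(d["pitch"]),
        channel_order=None if order is None else np.asarray(order, dtype=int),
        bad_channels=frozenset(int(b) for b in d.get("bad_channels", ())),
    )


def save_recording(rec: MultichannelRecording, path: str | Path,
                   format: str | None = None) -> Path:
    """Write a recording to ``path`` as HDF5 (default) or CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.create_dataset("fs", data=float(rec.fs))
            f.create_dataset("t0", data=float(rec.t0))
            gg = f.create_group("geometry")
            gg.create_dataset("n_rows", data=rec.geometry.n_rows)
            gg.create_dataset("n_cols", data=rec.geometry.n_cols)
            gg.create_dataset("pitch", data=rec.geometry.pitch)
            gg.create_dataset("channel_order", data=rec.geometry.rowcols())
            gg.create_dataset(
                "bad_channels", data=np.array(sorted(rec.geometry.bad_channels), dtype=int)
            )
    elif fmt == "csv":
        meta = {"fs": rec.fs, "t0": rec.t0, "geometry": _geometry_to_dict(rec.geometry)}
        header = "# cortiwave-recording " + json.dumps(meta)
        np.savetxt(path, rec.data, delimiter=",", fmt=f"%.{_CSV_DECIMALS}f",
                   header=header, comments="")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'hdf5' or 'csv')")
    return path


def load_recording(path: str | Path, format: str | None = None) -> MultichannelRecording:
    """Load and validate a recording written by :func:`save_recording`.

    Raises
    ------
    ValueError
        If geometry metadata is absent, the channel count disagrees with
        the geometry, or any sample is non-finite (the error names the
        first offending channel and sample).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "geometry" not in f:
                raise ValueError(f"{path}: missing geometry metadata")
            gg = f["geometry"]
            geometry = _geometry_from_dict(
                {
                    "n_rows": gg["n_rows"][()],
                    "n_cols": gg["n_cols"][()],
                    "pitch": gg["pitch"][()],
                    "channel_order": gg["channel_order"][()],
                    "bad_channels": gg["bad_channels"][()],
                }
            )
            data = f["data"][()]
            fs = float(f["fs"][()])
            t0 = float(f["t0"][()]) if "t0" in f else 0.0
    elif fmt == "csv":
        with open(path) as fh:
            first = fh.readline().strip()
        prefix = "# cortiwave-recording "
        if not first.startswith(prefix):
            raise ValueError(f"{path}: missing geometry metadata header line")
        meta = json.loads(first[len(prefix):])
        if "geometry" not in meta:
            raise ValueError(f"{path}: missing geometry metadata")
        geometry = _geometry_from_dict(meta["geometry"])
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        fs = float(meta["fs"])
        t0 = float(meta.get("t0", 0.0))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'hdf5' or 'csv')")

    if data.shape[0] != geometry.n_channels:
        raise ValueError(
            f"{path}: file has {data.shape[0]} channels but geometry declares "
            f"{geometry.n_channels}"
        )
    # MultichannelRecording.__post_init__ re-checks finiteness with indices.
    return MultichannelRecording(data=data, fs=fs, geometry=geometry, t0=t0)


def save_gridmap_csv(gm: GridMap, path: str | Path) -> Path:
    """Write a grid map as a plain n_rows x n_cols CSV (NaN for missing)."""
    path = Path(path)
    np.savetxt(path, gm.values, delimiter=",", fmt="%.6g")
    return path


def save_gridmap_png(gm: GridMap, path: str | Path, cmap: str = "RdBu_r") -> Path:
    """Render a grid map as a heatmap PNG (bad channels blanked)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(gm.values, cmap=cmap, interpolation="nearest")
    unit = {"amplitude": "uV", "phase": "rad", "delay": "ms"}[gm.kind]
    fig.colorbar(im, ax=ax, label=f"{gm.kind} ({unit})")
    if gm.label:
        ax.set_title(gm.label)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
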