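"""Run outputs: HDF5 field snapshots, CSV tables, JSON summaries, PNG renders."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import GridSpec, ScalarField

__all__ = ["write_field_snapshots", "write_summary_json", "render_field_png"]


def write_field_snapshots(path: str | Path, grid: GridSpec,
                          snapshots: dict[str, dict[float, np.ndarray]],
                          units: str = "dimensionless") -> None:
    """Write ``{field_name: {time_days: array}}`` as one HDF5 group per field
    per time point, with grid metadata as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["domain_size_mm"] = grid.domain_size_mm
        f.attrs["n_cells"] = grid.n_cells
        f.attrs["length_scale_mm"] = grid.length_scale_mm
        for name, series in snapshots.items():
            grp = f.create_group(name)
            for t, arr in series.items():
                ds = grp.create_dataset(f"t_{t:.4f}", data=np.asarray(arr))
                ds.attrs["time_days"] = t
                ds.attrs["units"] = units


def write_summary_json(path: str | Path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float))


def render_field_png(path: str | Path, field: ScalarField, title: str = "",
                     cmap: str = "viridis") -> None:
    """Optional heat-map render (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.4))
    extent = (0, field.grid.domain_size_mm, 0, field.grid.domain_size_mm)
    im = ax.imshow(field.values, origin="lower", extent=extent, cmap=cmap)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
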