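"""Readers and writers for the pipeline's on-disk formats.

Movies travel as multi-page TIFF (pages ordered frame-major, channel-minor)
with a JSON sidecar recording channel order, pixel size and timestamps;
tracks as CSV (cell_id, t_s, x_um, y_um); kymographs as HDF5 (matrix, bin
edges, timestamps) plus long-form CSV; ground truth as HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .image_prep import Movie
from .kinematics import Track
from .peripheral import AngularKymograph


def write_movie(movie: Movie, tiff_path) -> None:
    tiff_path = Path(tiff_path)
    channels = movie.meta.get("channel_order") or sorted(movie.frames)
    pages = []
    for i in range(movie.n_frames):
        for ch in channels:
            pages.append(movie.frames[ch][i].astype(np.float32))
    tifffile.imwrite(tiff_path, np.stack(pages), photometric="minisblack")
    sidecar = {
        "channel_order": list(channels),
        "pixel_size_um": movie.pixel_size_um,
        "timestamps_s": movie.timestamps_s.tolist(),
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(tiff_path) -> Movie:
    tiff_path = Path(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    pages = tifffile.imread(tiff_path)
    channels = sidecar["channel_order"]
    nch = len(channels)
    frames = {
        ch: np.asarray(pages[k::nch], dtype=float) for k, ch in enumerate(channels)
    }
    return Movie(
        frames=frames,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        timestamps_s=np.asarray(sidecar["timestamps_s"], dtype=float),
        meta={"channel_order": channels},
    )


def write_tracks(tracks, csv_path) -> None:
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.t_s, tr.x_um, tr.y_um):
            rows.append({"cell_id": tr.cell_id, "t_s": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_tracks(csv_path) -> list[Track]:
    df = pd.read_csv(csv_path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(
            Track(
                cell_id=str(cid),
                t_s=grp["t_s"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
            )
        )
    return out


def write_kymograph(kym: AngularKymograph, h5_path, csv_path=None) -> None:
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("values", data=kym.values)
        fh.create_dataset("bin_centers_deg", data=kym.bin_centers_deg)
        fh.create_dataset("timestamps_s", data=kym.timestamps_s)
    if csv_path is not None:
        t_grid, bins = np.meshgrid(kym.timestamps_s, kym.bin_centers_deg, indexing="ij")
        pd.DataFrame(
            {
                "t_s": t_grid.ravel(),
                "bin_deg": bins.ravel(),
                "value": kym.values.ravel(),
            }
        ).to_csv(csv_path, index=False)


def read_kymograph(h5_path) -> AngularKymograph:
    with h5py.File(h5_path, "r") as fh:
        return AngularKymograph(
            timestamps_s=fh["timestamps_s"][:],
            bin_centers_deg=fh["bin_centers_deg"][:],
            values=fh["values"][:],
        )


def render_kymograph_png(kym: AngularKymograph, png_path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(kym.bin_centers_deg, kym.timestamps_s, kym.values, shading="auto")
    ax.set_xlabel("angle from initial heading (deg)")
    ax.set_ylabel("time (s)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="intensity")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
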