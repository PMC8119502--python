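"""Reading and writing the pipeline's file formats.

Image stacks are multi-page 16-bit grayscale TIFFs with a plain key=value
sidecar carrying the physical calibration; tabular outputs (edges, vectors,
metrics, centroids) are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .edges import EdgeCurve
from .piv import FlowField, FlowFieldSequence
from .synthetic import ImageStack

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_flow_sequence_csv",
    "read_flow_sequence_csv",
    "write_edges_csv",
]


def write_image_stack(stack: ImageStack, tiff_path: str | Path, meta_path: str | Path | None = None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(stack.frames, dtype=np.uint16))
    meta_path = Path(meta_path) if meta_path is not None else tiff_path.with_suffix(".meta.txt")
    meta_path.write_text(
        "pixel_size_um={}\nframe_interval_min={}\nstage_x_um={}\nstage_y_um={}\n".format(
            stack.pixel_size, stack.frame_interval, *stack.stage_position
        )
    )


def read_image_stack(tiff_path: str | Path, meta_path: str | Path | None = None) -> ImageStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    meta_path = Path(meta_path) if meta_path is not None else tiff_path.with_suffix(".meta.txt")
    meta = {}
    for line in meta_path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = float(v)
    return ImageStack(
        frames=frames,
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_min"],
        stage_position=(meta.get("stage_x_um", 0.0), meta.get("stage_y_um", 0.0)),
    )


def write_flow_sequence_csv(seq: FlowFieldSequence, path: str | Path) -> None:
    """Long-format vectors: frame, x_um, y_um, u_um_per_min, v_um_per_min, snr, valid."""
    rows = []
    for t, f in enumerate(seq.fields):
        X, Y = np.meshgrid(f.x, f.y)
        rows.append(
            pd.DataFrame(
                {
                    "frame": t,
                    "x_um": X.ravel(),
                    "y_um": Y.ravel(),
                    "u_um_per_min": f.u.ravel(),
                    "v_um_per_min": f.v.ravel(),
                    "snr": f.snr.ravel(),
                    "valid": f.valid.ravel().astype(int),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_flow_sequence_csv(path: str | Path, frame_interval: float) -> FlowFieldSequence:
    df = pd.read_csv(path)
    fields = []
    for t, g in df.groupby("frame", sort=True):
        x = np.unique(g["x_um"].to_numpy())
        y = np.unique(g["y_um"].to_numpy())
        shape = (len(y), len(x))
        order = np.lexsort((g["x_um"].to_numpy(), g["y_um"].to_numpy()))
        g = g.iloc[order]
        fields.append(
            FlowField(
                x=x,
                y=y,
                u=g["u_um_per_min"].to_numpy().reshape(shape),
                v=g["v_um_per_min"].to_numpy().reshape(shape),
                snr=g["snr"].to_numpy().reshape(shape),
                valid=g["valid"].to_numpy().astype(bool).reshape(shape),
            )
        )
    return FlowFieldSequence(fields=fields, frame_interval=frame_interval)


def write_edges_csv(edges: list[EdgeCurve], path: str | Path, pixel_size: float = 1.0) -> None:
    rows = []
    for e in edges:
        pts = e.points
        rows.append(
            pd.DataFrame(
                {
                    "frame": e.frame_index,
                    "index": np.arange(len(pts)),
                    "row": pts[:, 0],
                    "col": pts[:, 1],
                    "x_um": pts[:, 1] * pixel_size,
                    "y_um": -pts[:, 0] * pixel_size,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
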