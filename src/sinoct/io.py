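"""Raster interchange: 32-bit float single-channel TIFF with JSON sidecars.

Sinograms carry their geometry and completeness metadata in a ``.json``
sidecar next to the ``.tif``; network checkpoints are ``.npz`` parameter
archives with a JSON architecture descriptor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import tifffile

from sinoct.geometry import CTImage, FanGeometry, Sinogram
from sinoct.network import SinoUNet, build_unet

__all__ = [
    "load_checkpoint",
    "load_image",
    "load_sinogram",
    "save_checkpoint",
    "save_image",
    "save_sinogram",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_image(path, image: CTImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"type": "ct_image", "pixel_size": image.pixel_size}, indent=1)
    )


def load_image(path) -> CTImage:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    pixel_size = 1.0
    sc = _sidecar(path)
    if sc.exists():
        pixel_size = float(json.loads(sc.read_text()).get("pixel_size", 1.0))
    return CTImage(values, pixel_size=pixel_size)


def _geometry_dict(g: FanGeometry) -> dict:
    return {
        "source_distance": g.source_distance,
        "n_views": g.n_views,
        "angular_range": g.angular_range,
        "n_channels": g.n_channels,
        "channel_spacing": g.channel_spacing,
    }


def save_sinogram(path, sino: Sinogram) -> None:
    path = Path(path)
    tifffile.imwrite(path, sino.values.astype(np.float32))
    meta = {
        "type": "sinogram",
        "kind": sino.kind,
        "factor": sino.factor,
        "max_angle": sino.max_angle,
        "geometry": _geometry_dict(sino.geometry),
        "view_indices": np.asarray(sino.view_indices).tolist(),
        "measured_mask": (
            None
            if sino.measured_mask is None
            else np.asarray(sino.measured_mask).astype(int).tolist()
        ),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    geom = FanGeometry(**meta["geometry"])
    view_indices = np.asarray(meta["view_indices"])
    mask = meta.get("measured_mask")
    return Sinogram(
        np.asarray(tifffile.imread(path), dtype=np.float64),
        geom.view_angles[view_indices],
        geom,
        kind=meta["kind"],
        factor=meta["factor"],
        max_angle=meta["max_angle"],
        view_indices=view_indices,
        measured_mask=None if mask is None else np.asarray(mask, dtype=bool),
    )


def save_checkpoint(path, net: SinoUNet, epoch: int = 0, extra: dict | None = None) -> None:
    path = Path(path)
    arrays = {f"p{i:05d}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, **arrays)
    meta = {
        "type": "checkpoint",
        "input_shape": list(net.input_shape),
        "base_channels": net.base_channels,
        "depth": net.depth,
        "pooling_mode": net.pooling_mode,
        "epoch": epoch,
        "n_arrays": len(arrays),
    }
    if extra:
        meta.update(extra)
    _sidecar(path.with_suffix(".npz")).write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> Tuple[SinoUNet, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    net = build_unet(
        tuple(meta["input_shape"]),
        meta["base_channels"],
        meta["depth"],
        meta["pooling_mode"],
    )
    with np.load(path) as data:
        arrays = [data[f"p{i:05d}"] for i in range(meta["n_arrays"])]
    net.load_state_arrays(arrays)
    return net, meta
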