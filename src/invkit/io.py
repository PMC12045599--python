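"""Reading and writing images, masks and sidecar metadata.

Images are plain multi-page TIFF (axes T,C,Y,X / C,Y,X / Z,Y,X); channel
roles, pixel size and timing travel in a JSON sidecar next to the image.
Ground truth and per-cell outputs are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from invkit.capture_quant import FieldImage

__all__ = ["write_field", "read_field", "write_mask", "read_mask",
           "load_config", "dump_config"]


def write_field(path, field: FieldImage) -> None:
    """Write a field image and its JSON metadata sidecar (``<path>.json``)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(field.data, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "roles": field.roles,
        "pixel_size": field.pixel_size,
        "frame_interval": field.frame_interval,
        "onset_frame": field.onset_frame,
        "axes": "TCYX" if field.data.ndim == 4 else "CYX",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_field(path) -> FieldImage:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FieldImage(
        data=np.asarray(data, dtype=float),
        roles=meta.get("roles", {"fkbp_marker": 0, "poi": 1, "mitotrap": 2}),
        pixel_size=meta.get("pixel_size", 1.0),
        frame_interval=meta.get("frame_interval", 1.0),
        onset_frame=meta.get("onset_frame"),
    )


def write_mask(path, mask: np.ndarray) -> None:
    """Write a label or binary mask as an integer TIFF."""
    tifffile.imwrite(Path(path), np.asarray(mask).astype(np.int32))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
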