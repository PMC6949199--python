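"""Volume and table I/O: multi-page TIFF stacks with JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile


def write_volume(volume: np.ndarray, path, metadata: dict | None = None) -> Path:
    """Write a 3-D attenuation volume as a multi-page TIFF.

    Geometry and acquisition metadata (voxel size, energy, time, seed, ...)
    go to a ``<path>.json`` sidecar.  The voxel dtype is preserved so the
    round trip is bit-exact.
    """
    path = Path(path)
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D (nz, ny, nx) volume")
    tifffile.imwrite(path, vol, photometric="minisblack")
    if metadata is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(metadata, fh, indent=2, default=float)
    return path


def read_volume(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"unknown volume format: {path.suffix!r} (expected TIFF)")
    vol = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return vol, meta


def read_volume_pair(path_32, path_34) -> tuple[np.ndarray, np.ndarray, dict, dict]:
    """Read a co-registered energy pair, enforcing matching grids."""
    v32, m32 = read_volume(path_32)
    v34, m34 = read_volume(path_34)
    if v32.shape != v34.shape:
        raise ValueError(f"energy pair grid mismatch: {v32.shape} vs {v34.shape}")
    for key in ("voxel_um",):
        if key in m32 and key in m34 and m32[key] != m34[key]:
            raise ValueError(f"metadata mismatch between energy pair: {key}")
    return v32, v34, m32, m34


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
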