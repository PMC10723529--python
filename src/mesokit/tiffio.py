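"""TIFF interchange: FRAP movies with JSON sidecars, label masks, stacks.

Movies travel as multi-page TIFF plus a JSON ROI/timing sidecar;
segmentation label masks are written as 16-bit TIFF.
"""

from __future__ import annotations

import json

import numpy as np
import tifffile


def write_movie(path, movie: np.ndarray, meta: dict | None = None) -> None:
    """Write a (frames, y, x) movie as multi-page TIFF; ``meta`` (the
    ROI/timing sidecar) goes to ``<path>.json``."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    if meta is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump({k: _jsonable(v) for k, v in meta.items()}, fh, indent=2)


def read_movie(path) -> tuple[np.ndarray, dict | None]:
    """Read a multi-page TIFF movie and its JSON sidecar if present."""
    movie = tifffile.imread(path)
    meta = None
    try:
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return movie, meta


def write_labels(path, labels: np.ndarray) -> None:
    """Write an integer label mask as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (tuple, list, np.ndarray)):
        return [_jsonable(x) for x in v]
    return v
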