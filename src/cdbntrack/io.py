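"""File formats: frame directories, OTB box files, results CSV, models.

OTB ground-truth files carry one "x,y,w,h" line per frame (comma- or
tab-separated), with 1-based pixel coordinates; internally the package
uses 0-based top-left coordinates, so the reader subtracts 1 from x and
y and the writer adds it back.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .cdbn import load_model, save_model  # re-exported  # noqa: F401
from .tracker import ObjectState, TrackResult, FrameRecord

__all__ = ["read_groundtruth", "write_groundtruth", "write_results",
           "read_results", "load_frames", "write_frames",
           "save_model", "load_model"]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def read_groundtruth(path) -> list[ObjectState]:
    """Parse an OTB box file into 0-based :class:`ObjectState` boxes."""
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = re.split(r"[,\t\s]+", line)
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 values 'x,y,w,h', got {line!r}")
            try:
                x, y, w, h = (float(p) for p in parts)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value in {line!r}") from None
            boxes.append(ObjectState(x - 1.0, y - 1.0, w, h))
    if not boxes:
        raise ValueError(f"{path}: no boxes found")
    return boxes


def write_groundtruth(boxes, path) -> None:
    """Write 0-based boxes back to the 1-based OTB text format."""
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.x + 1:g},{b.y + 1:g},{b.w:g},{b.h:g}\n")


def write_results(result: TrackResult, path, diagnostics_path=None) -> None:
    """Per-frame CSV (frame, x, y, w, h, confidence); repr round-trips."""
    df = pd.DataFrame(list(result.to_rows()),
                      columns=["frame", "x", "y", "w", "h", "confidence"])
    df.to_csv(path, index=False, float_format="%.17g")
    if diagnostics_path is not None:
        with open(diagnostics_path, "w") as fh:
            for r in result.records:
                fh.write(json.dumps(dict(frame=r.frame, ess=r.ess,
                                         resampled=bool(r.resampled),
                                         lost=bool(r.lost))) + "\n")


def read_results(path) -> TrackResult:
    df = pd.read_csv(path)
    result = TrackResult()
    for row in df.itertuples(index=False):
        result.records.append(FrameRecord(
            frame=int(row.frame),
            state=ObjectState(row.x, row.y, row.w, row.h),
            confidence=float(row.confidence), ess=float("nan"),
            resampled=False))
    return result


def load_frames(directory) -> list[np.ndarray]:
    """Read a frame directory in lexicographic filename order."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not paths:
        raise ValueError(f"no image files found in {directory}")
    return [np.asarray(iio.imread(p)) for p in paths]


def write_frames(frames, directory, prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, f in enumerate(frames):
        p = directory / f"{prefix}{i:04d}.png"
        iio.imwrite(p, np.asarray(f))
        out.append(p)
    return out


def read_cifar10_batch(path) -> tuple[np.ndarray, np.ndarray]:
    """Optional reader for the CIFAR-10 binary batch format.

    Each record is 1 label byte followed by 3072 bytes (3 x 32 x 32,
    channel-major). Returns ``(X, y)`` with X (N, 32, 32, 3) float in
    [0, 1]. Only used when a real dataset is supplied by the user.
    """
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size % 3073:
        raise ValueError(f"{path}: not a CIFAR-10 binary batch "
                         f"({raw.size} bytes is not a multiple of 3073)")
    rec = raw.reshape(-1, 3073)
    y = rec[:, 0].astype(int)
    X = rec[:, 1:].reshape(-1, 3, 32, 32).transpose(0, 2, 3, 1) / 255.0
    return X, y
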