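"""Reading and writing fluoroscopy frame sequences.

Supported inputs: a multi-page TIFF, or a directory of single-frame
PNG/TIFF images (lexicographic filename order) or DICOM files (pixel
data only).  All intensities are normalised to floating point in
[0, 1] on read; the writer quantises to 16-bit, so a write/read round
trip is bit-identical after the same quantisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError
from .tracking import FrameSequence

__all__ = ["read_frames", "write_frames", "quantize16"]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_IMAGE_SUFFIXES = _TIFF_SUFFIXES | {".png"}


def quantize16(frames: np.ndarray) -> np.ndarray:
    """Quantise [0, 1] float frames to uint16 (the writer's on-disk form)."""
    return np.round(np.clip(frames, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _normalize(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance mean
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"{name}: expected a 2-D grayscale frame, got {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    arr = arr.astype(np.float64)
    peak = arr.max()
    return arr / peak if peak > 1.0 else arr


def _read_one(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() == ".dcm":
            import pydicom

            return _normalize(pydicom.dcmread(path).pixel_array, path.name)
        return _normalize(iio.imread(path), path.name)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read frame file {path.name}: {exc}") from exc


def read_frames(
    path: str | Path,
    pattern: str = "*",
    frame_rate_hz: float = 30.0,
    pixel_spacing: Optional[float] = None,
) -> FrameSequence:
    """Load an ordered frame sequence from a TIFF stack or image directory.

    Directory frames are ordered lexicographically by filename; TIFF
    pages keep their page order.  At least two frames are required, and
    all frames must share dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such frame source: {path}")
    if path.is_file():
        if path.suffix.lower() not in _TIFF_SUFFIXES:
            raise FormatError(f"single-file input must be TIFF, got {path.name}")
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read frame file {path.name}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_normalize(page, f"{path.name}[{i}]") for i, page in enumerate(stack)]
    else:
        files = sorted(
            p
            for p in path.glob(pattern)
            if p.suffix.lower() in (_IMAGE_SUFFIXES | {".dcm"})
        )
        if not files:
            raise FileNotFoundError(f"no frame files matching {pattern!r} in {path}")
        frames = [_read_one(p) for p in files]
    if len(frames) < 2:
        raise FormatError(f"need at least 2 frames, found {len(frames)}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"mixed frame dimensions: {sorted(shapes)}")
    return FrameSequence(
        frames=np.stack(frames),
        frame_rate_hz=frame_rate_hz,
        pixel_spacing=pixel_spacing,
    )


def write_frames(seq: FrameSequence, path: str | Path, fmt: str = "tiff") -> Path:
    """Write frames as a multi-page TIFF (``fmt='tiff'``) or a PNG directory."""
    path = Path(path)
    data = quantize16(seq.frames)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(data):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
    else:
        raise FormatError(f"unknown frame format {fmt!r}; use 'tiff' or 'png'")
    return path
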