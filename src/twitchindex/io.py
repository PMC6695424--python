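"""Reading and writing stacks, masks and tables.

Stacks are stored as multi-page grayscale TIFF. On write, frames go out as
32-bit float with the frame rate embedded in the page description as JSON;
on read, integer containers are normalised to [0, 1] by their bit-depth
maximum so the movement index is comparable across 8- and 16-bit sources.
"""

from __future__ import annotations

import json

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError
from .simkit import FrameStack, NucleiField

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
]


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as a float32 multi-page TIFF with fps metadata."""
    meta = json.dumps({"fps": stack.fps, "origin": stack.origin})
    tifffile.imwrite(
        path,
        np.asarray(stack.frames, dtype=np.float32),
        photometric="minisblack",
        description=meta,
    )


def read_stack(path, fps: float | None = None) -> FrameStack:
    """Read a multi-page grayscale image file as a :class:`FrameStack`.

    Parameters
    ----------
    path
        Multi-page TIFF. Integer data are normalised by the container's
        bit-depth maximum; floating-point data are taken as already scaled.
    fps
        Frame rate; overrides any value stored in the TIFF metadata. If
        neither is available a :class:`~twitchindex.errors.ParameterError`
        is raised.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"mixed frame shapes in {path}: {shapes}")
            arr = tif.asarray()
            description = tif.pages[0].description
    except FormatError:
        raise
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read image stack {path}: {exc}") from exc

    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[0] < 2):
        raise FormatError(f"{path} holds fewer than 2 frames")
    if arr.ndim != 3:
        raise FormatError(f"{path} is not a grayscale (T, H, W) stack")

    if np.issubdtype(arr.dtype, np.integer):
        frames = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        frames = arr.astype(np.float32, copy=False)

    if fps is None:
        try:
            fps = float(json.loads(description)["fps"])
        except (TypeError, ValueError, KeyError):
            fps = None
    if fps is None:
        raise ParameterError(
            f"no frame rate found for {path}; pass fps explicitly"
        )
    return FrameStack(frames=frames, fps=float(fps), origin="file")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit image (0/255); PNG or TIFF by suffix."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a binary mask image; any non-zero pixel counts as foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"{path} is not a single-plane mask image")
    return arr > 0


def read_nuclei_field(dapi_path, hna_path, field_id: str = "field") -> NucleiField:
    return NucleiField(
        dapi_mask=read_mask(dapi_path),
        hna_mask=read_mask(hna_path),
        field_id=field_id,
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
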