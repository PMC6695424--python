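"""Movement-index contractility analysis by differential image subtraction.

Given a time-lapse stack of myotubes twitching under periodic electric pulse
stimulation (EPS), the movement index is computed as follows:

1. a per-frame activity trace (mean absolute inter-frame difference) locates
   the first maximum-contraction frame;
2. frames one stimulation period apart from that anchor are taken as
   contraction images, and frames half a period later as the matching
   relaxation images, over a 3–5 s analysis window;
3. each contraction/relaxation pair yields a differential image (absolute
   pixel-wise difference), the pairs are overlaid (pixel-wise mean), and the
   movement index is the spatial mean intensity of the overlay.

Because static scattering structures cancel in the subtraction, the index
responds only to moving parts; a noiseless static field scores exactly zero,
and a global additive intensity offset leaves the index unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from ._utils import require, round_half_up
from .errors import (
    InsufficientFrames,
    NoContractionDetected,
    ParameterError,
)
from .io import read_stack, write_stack  # re-exported: stack I/O lives in io
from .simkit import FrameStack

__all__ = [
    "FramePairing",
    "MovementResult",
    "FieldSummary",
    "read_stack",
    "write_stack",
    "motion_trace",
    "detect_contraction_peaks",
    "find_first_max_contraction",
    "pair_frames",
    "differential_image",
    "overlay_diffs",
    "movement_index",
    "summarize_fields",
    "render_pseudocolor",
]

#: Default prominence floor, as a fraction of (max - median) of the smoothed
#: activity trace, for calling a contraction peak.
DEFAULT_PROMINENCE_FRAC = 0.25


@dataclass
class FramePairing:
    """Contraction/relaxation frame pairs anchored at the first peak."""

    start_index: int
    pairs: list  # [(contraction_index, relaxation_index), ...]
    window_s: float
    stim_freq_hz: float


@dataclass
class MovementResult:
    """Differential images, their overlay and the scalar movement index."""

    pairing: FramePairing
    diff_images: np.ndarray  # (n_pairs, H, W)
    overlay: np.ndarray  # (H, W)
    movement_index: float
    per_pair_indices: np.ndarray  # mean intensity of each differential image
    field_id: str = "field"
    non_contractile: bool = False


@dataclass
class FieldSummary:
    """Mean ± SE of per-field movement indices."""

    indices: np.ndarray
    mean: float
    se: float | None  # None for a single field
    n_fields: int
    field_ids: list


# ---------------------------------------------------------------------------


def motion_trace(stack: FrameStack) -> np.ndarray:
    """Per-frame activity: mean absolute pixel difference to the previous frame.

    ``a[0] = 0`` by definition.
    """
    frames = np.asarray(stack.frames, dtype=np.float64)
    trace = np.zeros(frames.shape[0])
    trace[1:] = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    return trace


def _smooth(trace: np.ndarray, fps: float, stim_freq_hz: float,
            smooth_width: int | None) -> np.ndarray:
    width = smooth_width if smooth_width is not None else max(
        1, round_half_up(fps / (4.0 * stim_freq_hz))
    )
    return uniform_filter1d(np.asarray(trace, dtype=np.float64),
                            size=width, mode="nearest")


def detect_contraction_peaks(
    trace: np.ndarray,
    fps: float,
    stim_freq_hz: float = 1.0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_width: int | None = None,
) -> np.ndarray:
    """Indices of contraction peaks in an activity trace.

    The trace is smoothed with a centred moving average of width
    ``round(fps / (4 * stim_freq_hz))`` frames and peaks are kept if their
    topographic prominence is at least ``prominence_frac`` of the smoothed
    trace's (max - median) range. Each detected peak is then refined to the
    raw-trace argmax within one smoothing width (the moving average of a
    spike-plus-decay twitch lags the true activity maximum by up to half a
    window); ties and plateaus resolve to the earliest index.

    Raises :class:`NoContractionDetected` if no peak qualifies (flat trace).
    """
    trace = np.asarray(trace, dtype=np.float64)
    require(trace.size >= 2, "trace too short")
    width = smooth_width if smooth_width is not None else max(
        1, round_half_up(fps / (4.0 * stim_freq_hz))
    )
    smoothed = _smooth(trace, fps, stim_freq_hz, width)
    floor = prominence_frac * (smoothed.max() - np.median(smoothed))
    if floor <= 0:
        raise NoContractionDetected("activity trace is flat")
    _, props = find_peaks(smoothed, prominence=floor, plateau_size=(1, None))
    left_edges = props["left_edges"]
    if left_edges.size == 0:
        raise NoContractionDetected(
            "no activity peak exceeded the prominence floor"
        )
    refined: list = []
    for p in left_edges:
        lo = max(int(p) - width, 0)
        hi = min(int(p) + width + 1, trace.size)
        idx = lo + int(np.argmax(trace[lo:hi]))  # argmax takes earliest tie
        if not refined or idx > refined[-1]:
            refined.append(idx)
    return np.asarray(refined, dtype=int)


def find_first_max_contraction(
    trace: np.ndarray,
    fps: float,
    stim_freq_hz: float = 1.0,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_width: int | None = None,
) -> int:
    """Frame index of the first maximum-contraction state.

    This is the earliest qualifying peak of the smoothed activity trace; ties
    and plateaus resolve to the earliest index. See
    :func:`detect_contraction_peaks` for the peak rule.
    """
    peaks = detect_contraction_peaks(
        trace, fps, stim_freq_hz, prominence_frac, smooth_width
    )
    return int(peaks[0])


def pair_frames(
    start_index: int,
    fps: float,
    stim_freq_hz: float,
    window_s: float,
    n_frames: int,
) -> FramePairing:
    """Pair contraction frames with their half-period-later relaxation frames.

    Contraction frames sit at ``start_index + round(k * fps / f)`` for each
    stimulation cycle ``k`` in the analysis window; the paired relaxation
    frame is ``round(fps / (2 f))`` frames later (≈0.5 s for 1 Hz EPS).
    Pairs that would run past the end of the stack are dropped.

    Raises :class:`InsufficientFrames` when no complete pair fits.
    """
    require(fps > 0 and stim_freq_hz > 0, "fps and stim_freq_hz must be positive")
    require(window_s > 0, "window_s must be positive")
    if not 0 <= start_index < n_frames:
        raise ParameterError(
            f"start_index {start_index} outside stack of {n_frames} frames"
        )
    half_period = round_half_up(fps / (2.0 * stim_freq_hz))
    n_cycles = int(np.floor(window_s * stim_freq_hz))
    pairs = []
    for k in range(n_cycles):
        c = start_index + round_half_up(k * fps / stim_freq_hz)
        r = c + half_period
        if r <= n_frames - 1:
            pairs.append((c, r))
    if not pairs:
        raise InsufficientFrames(
            f"no complete contraction/relaxation pair fits after frame "
            f"{start_index} in a {n_frames}-frame stack"
        )
    return FramePairing(
        start_index=int(start_index),
        pairs=pairs,
        window_s=float(window_s),
        stim_freq_hz=float(stim_freq_hz),
    )


def differential_image(
    stack: FrameStack, pair: tuple, signed: bool = False
) -> np.ndarray:
    """Differential image of one contraction/relaxation pair.

    By default the absolute pixel-wise difference ``|contraction -
    relaxation|`` (movement magnitude); with ``signed=True`` the raw
    subtraction is returned instead.
    """
    c_idx, r_idx = pair
    n = stack.n_frames
    if not (0 <= c_idx < n and 0 <= r_idx < n):
        raise ParameterError(f"frame pair {pair} outside stack of {n} frames")
    diff = (
        stack.frames[c_idx].astype(np.float64)
        - stack.frames[r_idx].astype(np.float64)
    )
    return diff if signed else np.abs(diff)


def overlay_diffs(
    diff_images: Sequence[np.ndarray], mode: str = "mean"
) -> np.ndarray:
    """Overlay per-pair differential images into one movement map.

    ``mode="mean"`` (default) takes the pixel-wise mean, which makes the
    movement index equal to the mean of the per-pair indices and independent
    of window length in expectation; ``mode="max"`` takes the pixel-wise
    maximum.
    """
    if len(diff_images) == 0:
        raise ParameterError("need at least one differential image")
    arr = np.asarray(diff_images, dtype=np.float64)
    require(arr.ndim == 3, "differential images must share one shape")
    if mode == "mean":
        return arr.mean(axis=0)
    if mode == "max":
        return arr.max(axis=0)
    raise ParameterError(f"unknown overlay mode {mode!r}")


def movement_index(
    stack: FrameStack,
    fps: float | None = None,
    stim_freq_hz: float = 1.0,
    window_s: float = 3.0,
    signed: bool = False,
    overlay_mode: str = "mean",
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_width: int | None = None,
    field_id: str = "field",
) -> MovementResult:
    """Movement index of one field.

    Chains activity-trace extraction, first-maximum-contraction detection,
    frame pairing, per-pair differential images and their overlay; the index
    is the mean intensity over all pixels of the overlay. If no contraction
    peak is detected the same chain is anchored at frame 0 and the result is
    flagged ``non_contractile`` (poorly contracting fields still get a — low
    — index rather than an error).
    """
    fps = stack.fps if fps is None else float(fps)
    trace = motion_trace(stack)
    non_contractile = False
    try:
        start = find_first_max_contraction(
            trace, fps, stim_freq_hz, prominence_frac, smooth_width
        )
    except NoContractionDetected:
        start = 0
        non_contractile = True
    pairing = pair_frames(start, fps, stim_freq_hz, window_s, stack.n_frames)
    diffs = np.stack(
        [differential_image(stack, p, signed=signed) for p in pairing.pairs]
    )
    overlay = overlay_diffs(diffs, mode=overlay_mode)
    return MovementResult(
        pairing=pairing,
        diff_images=diffs,
        overlay=overlay,
        movement_index=float(overlay.mean()),
        per_pair_indices=diffs.mean(axis=(1, 2)),
        field_id=field_id,
        non_contractile=non_contractile,
    )


def summarize_fields(results: Sequence) -> FieldSummary:
    """Mean ± SE of movement indices over fields (typically three per
    culture condition). Accepts :class:`MovementResult` objects or floats.
    The SE is the sample SD over fields divided by sqrt(n); it is undefined
    (``None``) for a single field.
    """
    if len(results) == 0:
        raise ParameterError("no fields to summarize")
    indices = np.array(
        [
            r.movement_index if isinstance(r, MovementResult) else float(r)
            for r in results
        ]
    )
    field_ids = [
        r.field_id if isinstance(r, MovementResult) else f"field{i + 1}"
        for i, r in enumerate(results)
    ]
    n = indices.size
    se = float(indices.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return FieldSummary(
        indices=indices,
        mean=float(indices.mean()),
        se=se,
        n_fields=int(n),
        field_ids=field_ids,
    )


def render_pseudocolor(
    overlay: np.ndarray, out_path, colormap_name: str = "viridis"
) -> np.ndarray:
    """Render a movement overlay as a pseudo-colored PNG.

    The overlay is min–max scaled to [0, 1] (an all-zero overlay maps to the
    colormap floor) and pushed through a perceptually uniform colormap. The
    rendered RGB array is also returned.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    overlay = np.asarray(overlay, dtype=np.float64)
    require(np.isfinite(overlay).all(), "overlay contains non-finite values")
    span = overlay.max() - overlay.min()
    scaled = (overlay - overlay.min()) / span if span > 0 \
        else np.zeros_like(overlay)
    cmap = colormaps[colormap_name]
    rgb = (cmap(scaled)[..., :3] * 255).astype(np.uint8)
    if out_path is not None:
        iio.imwrite(out_path, rgb)
    return rgb
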