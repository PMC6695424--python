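"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit Python loops and elementary
arithmetic, deliberately independent of the library code paths it checks.
"""

import math

import numpy as np
from scipy import stats as _stats  # only for the t CDF in pooled_t


# ---------------------------------------------------------------------------
# connected components (8-connectivity) by breadth-first flood fill


def label_components(mask):
    """Return a list of components, each a set of (row, col) pixels."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    components = []
    for y0, x0 in np.argwhere(mask):
        if seen[y0, x0]:
            continue
        queue = [(int(y0), int(x0))]
        seen[y0, x0] = True
        comp = set()
        while queue:
            y, x = queue.pop()
            comp.add((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < h and 0 <= nx < w
                        and mask[ny, nx] and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
        components.append(comp)
    return components


# ---------------------------------------------------------------------------
# movement index recomputed with explicit loops


def _round_half_up(x):
    return int(math.floor(x + 0.5))


def _smooth_nearest(trace, size):
    """Moving average matching scipy.ndimage.uniform_filter1d semantics."""
    n = len(trace)
    left = size // 2
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(i - left, i - left + size):
            acc += trace[min(max(j, 0), n - 1)]
        out.append(acc / size)
    return out


def _prominence(values, peak):
    """Topographic prominence of a local maximum (scipy definition)."""
    height = values[peak]
    left_min = height
    i = peak - 1
    while i >= 0 and values[i] <= height:
        left_min = min(left_min, values[i])
        i -= 1
    right_min = height
    i = peak + 1
    while i < len(values) and values[i] <= height:
        right_min = min(right_min, values[i])
        i += 1
    return height - max(left_min, right_min)


def brute_movement_index(frames, fps, stim_freq_hz, window_s,
                         prominence_frac=0.25):
    """Recompute the movement index of a stack with explicit pixel loops.

    Returns (movement_index, start_index, pairs).
    """
    frames = np.asarray(frames, dtype=np.float64)
    n_frames, h, w = frames.shape

    # activity trace
    trace = [0.0]
    for t in range(1, n_frames):
        acc = 0.0
        for y in range(h):
            for x in range(w):
                acc += abs(frames[t, y, x] - frames[t - 1, y, x])
        trace.append(acc / (h * w))

    # smoothed-trace peak with prominence floor, refined to the raw argmax
    width = max(1, _round_half_up(fps / (4.0 * stim_freq_hz)))
    smoothed = _smooth_nearest(trace, width)
    floor = prominence_frac * (max(smoothed) - float(np.median(smoothed)))
    start = None
    for i in range(1, n_frames - 1):
        if smoothed[i] > smoothed[i - 1] and smoothed[i] > smoothed[i + 1]:
            if _prominence(smoothed, i) >= floor:
                lo = max(i - width, 0)
                hi = min(i + width + 1, n_frames)
                best = lo
                for j in range(lo, hi):
                    if trace[j] > trace[best]:
                        best = j
                start = best
                break
    assert start is not None, "toy stack must contain a detectable peak"

    # pairing
    half_period = _round_half_up(fps / (2.0 * stim_freq_hz))
    pairs = []
    for k in range(int(math.floor(window_s * stim_freq_hz))):
        c = start + _round_half_up(k * fps / stim_freq_hz)
        r = c + half_period
        if r <= n_frames - 1:
            pairs.append((c, r))
    assert pairs

    # differential images, mean overlay, spatial mean
    acc = 0.0
    for y in range(h):
        for x in range(w):
            pix = 0.0
            for c, r in pairs:
                pix += abs(frames[c, y, x] - frames[r, y, x])
            acc += pix / len(pairs)
    return acc / (h * w), start, pairs


# ---------------------------------------------------------------------------
# satellite gate, row by row


def brute_gate(table, thresholds):
    """Row-wise evaluation of CD11b- CD31- CD34- CD45- CD56+."""
    out = []
    for _, row in table.iterrows():
        out.append(
            row["CD11b"] < thresholds["CD11b"]
            and row["CD31"] < thresholds["CD31"]
            and row["CD34"] < thresholds["CD34"]
            and row["CD45"] < thresholds["CD45"]
            and row["CD56"] >= thresholds["CD56"]
        )
    return out


# ---------------------------------------------------------------------------
# pooled-variance two-sample t-test, textbook formula


def pooled_t(a, b):
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((v - m1) ** 2 for v in a)
    ss2 = sum((v - m2) ** 2 for v in b)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * _stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p
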