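"""Synthetic inputs with known ground truth.

Every generator in this module is a pure function of its parameters and an
explicit integer seed, and returns the ground truth it planted alongside the
data, so the downstream analysis (contractility, nuclei quantification,
gating, expression/secretion statistics) can be exercised end to end with no
external data.

The generated world mirrors a hybrid-myotube electric-pulse-stimulation (EPS)
experiment:

* time-lapse fields of bright elongated myotube ribbons twitching at the
  stimulation frequency (default 1 Hz) sampled at 14.4 frames/s;
* two-channel nuclei masks (all nuclei vs. human-nuclear-antigen positive)
  with a planted human fraction, default 14.25 %;
* per-cell surface-marker intensity tables with a CD56+ lineage-negative
  satellite-cell population among distractor populations;
* qPCR Ct tables with planted EPS fold changes, referenced to mouse GAPDH
  and human RPLP0;
* a multiplex secretion panel with planted upregulated, detected-but-flat,
  below-detection and mouse-cross-reactive analytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import require, round_half_up
from .errors import GeometryError, ParameterError

__all__ = [
    "VideoSimConfig",
    "FrameStack",
    "SimTruth",
    "NucleiField",
    "SecretionPanel",
    "MARKERS",
    "GATE_MARKERS",
    "POPULATIONS",
    "REFERENCE_GENES",
    "ANALYTE_CLASSES",
    "default_panel_class_map",
    "simulate_twitch_trace",
    "simulate_myotube_field",
    "simulate_nuclei_field",
    "simulate_marker_table",
    "simulate_ct_table",
    "simulate_secretion_panel",
]

# ---------------------------------------------------------------------------
# domain constants

MARKERS = ("CD11b", "CD31", "CD34", "CD45", "CD56", "PDGFRA")
#: The five markers entering the satellite-cell gate (PDGFRA is recorded but
#: not gated; it labels fibro/adipogenic progenitors).
GATE_MARKERS = ("CD11b", "CD31", "CD34", "CD45", "CD56")

#: Population -> set of markers expressed highly by that population.
POPULATIONS: Mapping[str, frozenset] = {
    "satellite": frozenset({"CD56"}),
    "blood": frozenset({"CD11b", "CD45"}),
    "endothelial": frozenset({"CD31", "CD34"}),
    "FAP": frozenset({"PDGFRA"}),
    "other": frozenset(),
}

#: Species-specific reference genes used for qPCR normalization.
REFERENCE_GENES = {"human": "RPLP0", "mouse": "GAPDH"}

ANALYTE_CLASSES = (
    "upregulated",
    "detected_not_upregulated",
    "not_detected",
    "cross_reactive",
)

_UPREGULATED = (
    # interleukins
    "IL-6", "IL-8", "IL-10", "IL-16",
    # CXC chemokines
    "CXCL1", "CXCL2", "CXCL5", "CXCL6", "CXCL10",
    # CC chemokines
    "CCL1", "CCL2", "CCL7", "CCL8", "CCL11", "CCL13", "CCL16", "CCL17",
    "CCL19", "CCL20", "CCL21", "CCL22", "CCL25", "CCL27",
    "IFN-gamma",
)
_DETECTED_NOT_UP = ("MIF",)
# CXCL12 is a placeholder member completing the published below-detection
# list; see docs/methods.md for the CCL16 ambiguity and the panel-size note.
_NOT_DETECTED = (
    "IL-1beta", "IL-2", "IL-4", "CXCL9", "CXCL11", "CXCL13",
    "CCL15", "CCL24", "GM-CSF", "TNF-alpha", "CXCL12",
)
_CROSS_REACTIVE = ("CX3CL1", "CCL3", "CCL12")


def default_panel_class_map() -> dict:
    """Template class map for the multiplex secretion panel.

    24 contraction-upregulated analytes (4 interleukins, 5 CXC chemokines,
    14 CC chemokines and IFN-gamma), MIF detected but not upregulated,
    11 analytes below the limit of detection and 3 analytes excluded because
    the human assay cross-reacts with the mouse homolog.
    """
    out: dict = {}
    for name in _UPREGULATED:
        out[name] = "upregulated"
    for name in _DETECTED_NOT_UP:
        out[name] = "detected_not_upregulated"
    for name in _NOT_DETECTED:
        out[name] = "not_detected"
    for name in _CROSS_REACTIVE:
        out[name] = "cross_reactive"
    return out


# ---------------------------------------------------------------------------
# containers


@dataclass
class FrameStack:
    """An ordered grayscale time-lapse stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of intensities in ``[0, 1]``.
    fps
        Acquisition rate in frames per second.
    origin
        ``"synthetic"`` or ``"file"``.
    """

    frames: np.ndarray
    fps: float
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        require(self.frames.ndim == 3, "frames must be a (T, H, W) array")
        require(self.frames.shape[0] >= 2, "a stack needs at least 2 frames")
        require(self.fps > 0, "fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple:
        return tuple(self.frames.shape)


@dataclass
class SimTruth:
    """Ground truth emitted beside every synthetic dataset."""

    seed: int
    displacement_trace: np.ndarray | None = None
    myotube_masks: np.ndarray | None = None  # (n_myotubes, H, W) bool
    amplitudes_px: np.ndarray | None = None
    human_fraction: float | None = None
    human_indices: np.ndarray | None = None  # indices of HNA+ nuclei
    n_nuclei: int | None = None
    fold_changes: dict | None = None  # {(species, gene): fold}
    analyte_classes: dict | None = None  # {analyte: class}
    population_labels: pd.Series | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable view (dense masks are summarised, not dumped)."""
        out: dict = {"seed": int(self.seed)}
        if self.displacement_trace is not None:
            out["displacement_trace"] = [float(v) for v in self.displacement_trace]
        if self.myotube_masks is not None:
            out["n_myotubes"] = int(self.myotube_masks.shape[0])
            out["myotube_areas_px"] = [
                int(m.sum()) for m in self.myotube_masks
            ]
        if self.amplitudes_px is not None:
            out["amplitudes_px"] = [float(a) for a in self.amplitudes_px]
        if self.human_fraction is not None:
            out["human_fraction"] = float(self.human_fraction)
        if self.human_indices is not None:
            out["human_indices"] = [int(i) for i in self.human_indices]
            out["n_human"] = len(self.human_indices)
        if self.n_nuclei is not None:
            out["n_nuclei"] = int(self.n_nuclei)
        if self.fold_changes is not None:
            out["fold_changes"] = {
                f"{sp}:{gene}": float(f) for (sp, gene), f in self.fold_changes.items()
            }
        if self.analyte_classes is not None:
            out["analyte_classes"] = dict(self.analyte_classes)
        if self.population_labels is not None:
            out["population_counts"] = (
                self.population_labels.value_counts().to_dict()
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass
class NucleiField:
    """Paired binary masks for one microscopy field.

    ``dapi_mask`` marks every nucleus; ``hna_mask`` marks the human-nuclear-
    antigen positive subset.
    """

    dapi_mask: np.ndarray
    hna_mask: np.ndarray
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.dapi_mask = np.asarray(self.dapi_mask, dtype=bool)
        self.hna_mask = np.asarray(self.hna_mask, dtype=bool)
        require(
            self.dapi_mask.shape == self.hna_mask.shape,
            "dapi and HNA masks must have the same shape",
        )


@dataclass
class SecretionPanel:
    """Per-analyte, per-well concentrations from a multiplex assay.

    ``data`` has columns ``analyte, well, condition, concentration`` with
    conditions ``EPS``, ``control``, ``mouse_only_media`` and ``blank``;
    ``lod`` is the per-analyte limit of detection in pg/mL. ``detected`` is
    filled in by :func:`twitchindex.respstats.censor_lod`.
    """

    data: pd.DataFrame
    lod: pd.Series
    detected: pd.Series | None = None

    REQUIRED_COLUMNS = ("analyte", "well", "condition", "concentration")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        require(not missing, f"panel table missing columns: {missing}")
        require((self.data["concentration"] >= 0).all(),
                "concentrations must be non-negative")
        self.lod = pd.Series(self.lod)
        missing_lod = set(self.data["analyte"]) - set(self.lod.index)
        require(not missing_lod, f"missing LOD for analytes: {sorted(missing_lod)}")

    @property
    def analytes(self) -> list:
        return sorted(self.data["analyte"].unique())

    @property
    def panel_size(self) -> int:
        return len(self.analytes)


@dataclass(frozen=True)
class VideoSimConfig:
    """Parameters of one synthetic contracting-myotube field.

    The stimulation protocol defaults mirror a 1 Hz EPS session imaged at
    14.4 frames/s. ``pulse_width_ms`` and ``field_v_per_mm`` are carried as
    protocol metadata only — no electric-field physics is modelled.
    """

    width_px: int = 256
    height_px: int = 256
    fps: float = 14.4
    stim_freq_hz: float = 1.0
    duration_s: float = 5.0
    n_myotubes: int = 5
    amplitude_px: float | Sequence[float] = 2.0
    twitch_rise_s: float = 0.1
    twitch_decay_s: float = 0.3
    noise_sd: float = 0.01
    baseline: float = 0.1
    seed: int = 0
    # protocol metadata (not used by the generator)
    pulse_width_ms: float = 4.0
    field_v_per_mm: float = 20.0 / 25.0

    def __post_init__(self) -> None:
        require(self.width_px >= 16 and self.height_px >= 16,
                "field must be at least 16x16 px")
        require(self.fps > 0 and self.stim_freq_hz > 0,
                "fps and stim_freq_hz must be positive")
        require(self.fps > 2 * self.stim_freq_hz,
                "fps must exceed twice the stimulation frequency "
                "(Nyquist for contraction/relaxation pairing)")
        require(self.duration_s > 0, "duration_s must be positive")
        require(round_half_up(self.fps * self.duration_s) >= 2,
                "stack must contain at least 2 frames")
        amps = np.atleast_1d(np.asarray(self.amplitude_px, dtype=float))
        require((amps >= 0).all(), "amplitude_px must be non-negative")
        require(amps.size in (1, self.n_myotubes),
                "amplitude_px must be scalar or one value per myotube")
        require(self.noise_sd >= 0, "noise_sd must be non-negative")
        require(0 <= self.baseline <= 1, "baseline must lie in [0, 1]")
        require(self.n_myotubes >= 1, "need at least one myotube")

    @property
    def amplitudes(self) -> np.ndarray:
        amps = np.atleast_1d(np.asarray(self.amplitude_px, dtype=float))
        if amps.size == 1:
            amps = np.repeat(amps, self.n_myotubes)
        return amps

    def replace(self, **kwargs) -> "VideoSimConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return VideoSimConfig(**current)


# ---------------------------------------------------------------------------
# twitch waveform


def simulate_twitch_trace(
    fps: float = 14.4,
    stim_freq_hz: float = 1.0,
    duration_s: float = 5.0,
    twitch_rise_s: float = 0.1,
    twitch_decay_s: float = 0.3,
) -> np.ndarray:
    """Per-frame displacement fraction ``s(t)`` of a periodic twitch.

    Within each stimulation cycle the displacement rises linearly from 0 to
    1 over ``twitch_rise_s`` seconds and then relaxes exponentially with time
    constant ``twitch_decay_s``. The frame nearest each cycle's peak is set
    to exactly 1 so that the discrete trace attains its maximum at the frame
    ``round(peak_time * fps)`` regardless of sampling phase.

    Returns
    -------
    numpy.ndarray
        Array of length ``round(fps * duration_s)`` with values in [0, 1];
        ``s[0] == 0``.
    """
    require(fps > 0, "fps must be positive")
    require(stim_freq_hz > 0, "stim_freq_hz must be positive")
    require(duration_s > 0, "duration_s must be positive")
    require(twitch_rise_s > 0 and twitch_decay_s > 0,
            "rise and decay times must be positive")
    period = 1.0 / stim_freq_hz
    require(twitch_rise_s + twitch_decay_s <= period,
            "twitch_rise_s + twitch_decay_s must not exceed one cycle")

    n = round_half_up(fps * duration_s)
    require(n >= 2, "duration too short for a trace")
    t = np.arange(n) / fps
    tau = np.mod(t, period)
    s = np.where(
        tau < twitch_rise_s,
        tau / twitch_rise_s,
        np.exp(-(tau - twitch_rise_s) / twitch_decay_s),
    )
    # snap the frame nearest each within-range peak to exactly 1
    m = 0
    while True:
        k = round_half_up((m * period + twitch_rise_s) * fps)
        if k >= n:
            break
        s[k] = 1.0
        m += 1
    return s


# ---------------------------------------------------------------------------
# contracting myotube field


def _ribbon_geometry(cfg: VideoSimConfig, rng: np.random.Generator) -> list:
    """Draw seeded ribbon parameters (centre, orientation, size, intensity)."""
    h, w = cfg.height_px, cfg.width_px
    short = min(h, w)
    tubes = []
    for _ in range(cfg.n_myotubes):
        tubes.append(
            {
                "cx": rng.uniform(0.2 * w, 0.8 * w),
                "cy": rng.uniform(0.2 * h, 0.8 * h),
                "theta": rng.uniform(0.0, np.pi),
                "half_length": rng.uniform(0.15 * short, 0.3 * short),
                "half_width": rng.uniform(0.015 * short, 0.03 * short),
                "intensity": rng.uniform(0.4, 0.7),
            }
        )
    return tubes


def simulate_myotube_field(config: VideoSimConfig) -> tuple:
    """Render a time-lapse stack of twitching myotube ribbons.

    Each myotube is an elongated soft-edged ribbon. At frame ``t`` its
    half-length is shortened by ``amplitude_px * s(t)`` toward the centroid
    (longitudinal contraction), where ``s`` is the twitch waveform from
    :func:`simulate_twitch_trace`. Gaussian noise of SD ``noise_sd`` is added
    after warping and intensities are clipped to [0, 1].

    Returns
    -------
    (FrameStack, SimTruth)
        The stack (float32) and the planted truth: the displacement trace,
        one resting-state mask per myotube and the per-myotube amplitudes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tubes = _ribbon_geometry(cfg, rng)
    amps = cfg.amplitudes
    for tube, amp in zip(tubes, amps):
        if amp >= tube["half_length"]:
            raise ParameterError(
                f"amplitude {amp:.1f} px >= myotube half-length "
                f"{tube['half_length']:.1f} px: contraction would collapse "
                "the myotube out of the field"
            )

    s = simulate_twitch_trace(
        cfg.fps, cfg.stim_freq_hz, cfg.duration_s,
        cfg.twitch_rise_s, cfg.twitch_decay_s,
    )
    n_frames = s.size
    yy, xx = np.mgrid[0:cfg.height_px, 0:cfg.width_px].astype(np.float32)

    frames = np.full(
        (n_frames, cfg.height_px * cfg.width_px), cfg.baseline,
        dtype=np.float32,
    )
    masks = np.zeros((cfg.n_myotubes, cfg.height_px, cfg.width_px), dtype=bool)
    for i, (tube, amp) in enumerate(zip(tubes, amps)):
        ct, st = np.cos(tube["theta"]), np.sin(tube["theta"])
        dx = xx - tube["cx"]
        dy = yy - tube["cy"]
        u = dx * ct + dy * st          # axial coordinate
        v = -dx * st + dy * ct         # transverse coordinate
        trans = tube["intensity"] * np.exp(
            -((v / tube["half_width"]) ** 6), dtype=np.float32
        )
        masks[i] = (np.abs(u) <= tube["half_length"]) & (
            np.abs(v) <= tube["half_width"]
        )
        # Frames are max(baseline, ribbon): pixels whose resting-state value
        # does not exceed the baseline can never change (the half-length only
        # shrinks), so per-frame math is confined to the ribbon's support.
        rest = trans * np.exp(-((u / tube["half_length"]) ** 6))
        support = np.flatnonzero(rest.ravel() > cfg.baseline)
        if support.size == 0:
            continue
        u_s = u.ravel()[support]
        trans_s = trans.ravel()[support]
        half_len_t = (tube["half_length"] - amp * s).astype(np.float32)
        q = (u_s[None, :] / half_len_t[:, None]) ** 2
        axial = np.exp(-(q * q * q))
        frames[:, support] = np.maximum(
            frames[:, support], trans_s[None, :] * axial
        )
    frames = frames.reshape(n_frames, cfg.height_px, cfg.width_px)

    if cfg.noise_sd > 0:
        frames = frames + rng.normal(
            0.0, cfg.noise_sd, size=frames.shape
        ).astype(np.float32)
    np.clip(frames, 0.0, 1.0, out=frames)

    stack = FrameStack(frames=frames, fps=cfg.fps, origin="synthetic")
    truth = SimTruth(
        seed=cfg.seed,
        displacement_trace=s,
        myotube_masks=masks,
        amplitudes_px=amps,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# nuclei fields


def simulate_nuclei_field(
    n_nuclei: int,
    human_fraction: float = 0.1425,
    shape: tuple = (512, 512),
    radius_range: tuple = (4.0, 7.0),
    seed: int = 0,
    field_id: str = "field",
    max_attempts_per_nucleus: int = 200,
) -> tuple:
    """Generate paired total-nuclei and HNA-channel masks.

    ``n_nuclei`` non-overlapping ellipses are placed uniformly at random; a
    ``Binomial(n_nuclei, human_fraction)``-sized random subset is marked in
    the HNA channel. The default ``human_fraction`` of 0.1425 matches the
    composition measured in hybrid human/mouse myotube cultures.

    Raises
    ------
    GeometryError
        If non-overlapping placement fails within the retry budget.
    """
    require(0 <= human_fraction <= 1, "human_fraction must lie in [0, 1]")
    require(n_nuclei >= 0, "n_nuclei must be non-negative")
    r_lo, r_hi = radius_range
    require(0 < r_lo <= r_hi, "invalid radius_range")
    h, w = shape
    margin = r_hi + 2.0
    min_dist = 2.0 * r_hi + 2.0  # guarantees disjoint components

    rng = np.random.default_rng(seed)
    centers = np.empty((0, 2))
    params = []
    for i in range(n_nuclei):
        for _ in range(max_attempts_per_nucleus):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if centers.size == 0 or (
                np.hypot(centers[:, 0] - cy, centers[:, 1] - cx) >= min_dist
            ).all():
                break
        else:
            raise GeometryError(
                f"could not place nucleus {i + 1}/{n_nuclei} without overlap"
            )
        centers = np.vstack([centers, (cy, cx)])
        params.append(
            {
                "cy": cy,
                "cx": cx,
                "a": rng.uniform(r_lo, r_hi),
                "b": rng.uniform(r_lo, r_hi),
                "phi": rng.uniform(0.0, np.pi),
            }
        )

    def _rasterize(p, out):
        r = int(np.ceil(max(p["a"], p["b"]))) + 1
        y0, y1 = int(p["cy"]) - r, int(p["cy"]) + r + 1
        x0, x1 = int(p["cx"]) - r, int(p["cx"]) + r + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - p["cy"], xx - p["cx"]
        c, s_ = np.cos(p["phi"]), np.sin(p["phi"])
        inside = ((dx * c + dy * s_) / p["a"]) ** 2 + (
            (-dx * s_ + dy * c) / p["b"]
        ) ** 2 <= 1.0
        out[y0:y1, x0:x1] |= inside

    dapi = np.zeros(shape, dtype=bool)
    for p in params:
        _rasterize(p, dapi)

    n_human = int(rng.binomial(n_nuclei, human_fraction)) if n_nuclei else 0
    human_idx = np.sort(rng.choice(n_nuclei, size=n_human, replace=False)) \
        if n_human else np.array([], dtype=int)
    hna = np.zeros(shape, dtype=bool)
    for i in human_idx:
        _rasterize(params[i], hna)

    field_obj = NucleiField(dapi_mask=dapi, hna_mask=hna, field_id=field_id)
    truth = SimTruth(
        seed=seed,
        human_fraction=human_fraction,
        human_indices=human_idx,
        n_nuclei=n_nuclei,
    )
    return field_obj, truth


# ---------------------------------------------------------------------------
# marker tables


def simulate_marker_table(
    n_cells: Mapping[str, int] | None = None,
    low_intensity: float = 10.0,
    high_intensity: float = 1000.0,
    log_sigma: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell fluorescence intensities for five gate markers plus PDGFRA.

    Intensities are log-normal around a low or high median depending on the
    population profile (satellite cells are CD56-high and negative for blood
    and endothelial markers; distractor populations express CD11b/CD45,
    CD31/CD34 or PDGFRA). The default medians are separated by
    ``ln(high/low)/log_sigma`` ≈ 11.5 log-SD, i.e. well beyond threshold
    ambiguity.

    Returns a DataFrame with one row per cell, one column per marker and a
    ground-truth ``population`` column.
    """
    if n_cells is None:
        n_cells = {"satellite": 50, "blood": 60, "endothelial": 40,
                   "FAP": 30, "other": 70}
    unknown = set(n_cells) - set(POPULATIONS)
    require(not unknown, f"unknown populations: {sorted(unknown)}")
    require(all(n >= 0 for n in n_cells.values()),
            "cell counts must be non-negative")
    require(0 < low_intensity <= high_intensity, "invalid intensity medians")
    require(log_sigma > 0, "log_sigma must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for pop in POPULATIONS:  # fixed iteration order for determinism
        n = int(n_cells.get(pop, 0))
        if n == 0:
            continue
        high_set = POPULATIONS[pop]
        block = {}
        for marker in MARKERS:
            median = high_intensity if marker in high_set else low_intensity
            block[marker] = rng.lognormal(np.log(median), log_sigma, size=n)
        block_df = pd.DataFrame(block)
        block_df["population"] = pop
        rows.append(block_df)
    if not rows:
        return pd.DataFrame(columns=list(MARKERS) + ["population"])
    table = pd.concat(rows, ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(
    fold_changes: Mapping[tuple, float] | None = None,
    n_reps: int = 3,
    ct_ref_mean: float = 18.0,
    ct_target_mean: float = 26.0,
    noise_sd_ct: float = 0.2,
    seed: int = 0,
) -> tuple:
    """qPCR Ct values for EPS vs control samples with planted fold changes.

    Parameters
    ----------
    fold_changes
        ``{(species, gene): fold}``; the EPS-condition Ct of a gene is the
        control mean minus ``log2(fold)`` plus noise. Defaults to a typical
        contraction-induced myokine pattern (human IL6/CXCL1 fold 4, mouse
        Il6/Cxcl1 fold 8).
    n_reps
        Biological replicates per condition.

    The species reference genes (human RPLP0, mouse GAPDH) are included in
    every sample block with condition-independent Ct distribution.
    """
    if fold_changes is None:
        fold_changes = {
            ("human", "IL6"): 4.0,
            ("human", "CXCL1"): 4.0,
            ("mouse", "Il6"): 8.0,
            ("mouse", "Cxcl1"): 8.0,
        }
    for (species, gene), fold_val in fold_changes.items():
        require(species in REFERENCE_GENES, f"unknown species: {species!r}")
        require(fold_val > 0, f"fold for {gene} must be positive")
        require(gene != REFERENCE_GENES[species],
                "reference genes cannot carry a planted fold")
    require(n_reps >= 1, "need at least one replicate per condition")
    require(noise_sd_ct >= 0, "noise_sd_ct must be non-negative")
    require(0 < ct_ref_mean < 45 and 0 < ct_target_mean < 45,
            "mean Ct values must lie in (0, 45)")

    rng = np.random.default_rng(seed)
    species_present = sorted({sp for sp, _ in fold_changes})
    rows = []
    for condition in ("control", "EPS"):
        for rep in range(1, n_reps + 1):
            sample = f"{condition.lower()}{rep}"
            for species in species_present:
                ref = REFERENCE_GENES[species]
                rows.append(
                    (sample, condition, species, ref,
                     ct_ref_mean + rng.normal(0.0, noise_sd_ct))
                )
                for (sp, gene), fold_val in sorted(fold_changes.items()):
                    if sp != species:
                        continue
                    mean = ct_target_mean
                    if condition == "EPS":
                        mean -= np.log2(fold_val)
                    rows.append(
                        (sample, condition, species, gene,
                         mean + rng.normal(0.0, noise_sd_ct))
                    )
    table = pd.DataFrame(
        rows, columns=["sample", "condition", "species", "gene", "ct_value"]
    )
    require(((table["ct_value"] > 0) & (table["ct_value"] < 45)).all(),
            "simulated Ct out of (0, 45); reduce folds or noise")
    truth = SimTruth(seed=seed, fold_changes=dict(fold_changes))
    return table, truth


# ---------------------------------------------------------------------------
# secretion panel


def simulate_secretion_panel(
    class_map: Mapping[str, str] | None = None,
    basal_pg_ml: float = 20.0,
    fold: float = 20.0,
    lod_pg_ml: float | Mapping[str, float] = 1.0,
    noise_cv: float = 0.1,
    n_wells: int = 4,
    n_media_wells: int = 3,
    seed: int = 0,
) -> tuple:
    """Multiplex secretion panel with planted analyte classes.

    Wells: ``n_wells`` each for EPS-treated and unstimulated hybrid-myotube
    cultures, plus ``n_media_wells`` each of mouse-only conditioned media and
    assay blanks (used for cross-reactivity screening).

    Planted behaviour per class:

    * ``upregulated`` — control wells at ``basal_pg_ml``, EPS wells at
      ``basal_pg_ml * fold``;
    * ``detected_not_upregulated`` — both conditions at basal level;
    * ``not_detected`` — every well below the limit of detection;
    * ``cross_reactive`` — biological wells at basal level, and mouse-only
      media signal far above blank (the mouse homolog binds the human assay).

    Concentrations carry multiplicative log-normal noise with coefficient of
    variation ``noise_cv``. Background (below-LOD) wells are capped at
    ``0.9 * LOD`` so planted detection classes are recovered with certainty.
    """
    if class_map is None:
        class_map = default_panel_class_map()
    bad = {a: c for a, c in class_map.items() if c not in ANALYTE_CLASSES}
    if bad:
        raise ParameterError(
            f"class map must partition analytes into {ANALYTE_CLASSES}; "
            f"got invalid entries {bad}"
        )
    require(len(class_map) > 0, "class map is empty")
    require(basal_pg_ml > 0 and fold > 0, "basal level and fold must be positive")
    require(noise_cv >= 0, "noise_cv must be non-negative")
    require(n_wells >= 2 and n_media_wells >= 2,
            "need at least two wells per condition")

    analytes = sorted(class_map)
    if isinstance(lod_pg_ml, Mapping):
        lod = pd.Series({a: float(lod_pg_ml[a]) for a in analytes})
    else:
        lod = pd.Series(float(lod_pg_ml), index=analytes)
    require((lod > 0).all(), "LOD must be positive")

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    def _noisy(level, n):
        vals = level * rng.lognormal(0.0, sigma, size=n) if sigma > 0 \
            else np.full(n, level)
        return vals

    def _background(analyte, n):
        # sub-LOD machine background; capped below LOD by construction
        base = rng.uniform(0.1, 0.4) * lod[analyte]
        return np.minimum(_noisy(base, n), 0.9 * lod[analyte])

    conditions = (
        [("EPS", n_wells), ("control", n_wells),
         ("mouse_only_media", n_media_wells), ("blank", n_media_wells)]
    )
    rows = []
    for analyte in analytes:
        cls = class_map[analyte]
        for condition, n in conditions:
            if cls == "not_detected":
                vals = _background(analyte, n)
            elif condition == "blank":
                vals = _background(analyte, n)
            elif condition == "mouse_only_media":
                if cls == "cross_reactive":
                    vals = _noisy(basal_pg_ml, n)  # mouse homolog read-through
                else:
                    vals = _background(analyte, n)
            elif condition == "EPS" and cls == "upregulated":
                vals = _noisy(basal_pg_ml * fold, n)
            else:  # control wells, and EPS wells of flat analytes
                vals = _noisy(basal_pg_ml, n)
            for j, v in enumerate(vals, start=1):
                rows.append((analyte, f"{condition}_{j}", condition, float(v)))

    data = pd.DataFrame(
        rows, columns=["analyte", "well", "condition", "concentration"]
    )
    panel = SecretionPanel(data=data, lod=lod)
    truth = SimTruth(seed=seed, analyte_classes=dict(class_map))
    return panel, truth
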