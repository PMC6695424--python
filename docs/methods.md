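# Methods

This note documents the models and procedures implemented by twitchindex,
the defaults and why they were chosen, the numerical decisions that are not
visible from the API, and what the synthetic-data tests do and do not
establish.

## Movement index

**Model.** EPS-evoked twitching is quantified by differential image
subtraction. A per-frame activity trace `a(t)` (mean absolute inter-frame
difference; `a(0) = 0`) operationalises "maximum contraction": frames of
peak activity mark the moments of fastest shape change, which for a
periodic twitch coincide (to within a frame) with peak shortening. From the
first such peak, contraction frames are taken one stimulation period apart
and paired with relaxation frames half a period later; each pair is
subtracted, the absolute differences are overlaid, and the movement index
(MI) is the overlay's mean intensity.

**Numerical choices.**

* *Subtraction sign.* The subtraction is absolute by default: intensity
  differences at moving edges occur in both directions and a signed mean
  would cancel them. A `signed=True` mode exists for diagnostic use.
* *Overlay.* Pixel-wise mean of the per-pair differential images. This
  makes MI equal to the mean of per-pair indices and independent of window
  length in expectation; a `max` mode is available.
* *Frame-index rounding.* Nearest integer with half-up ties
  (`floor(x + 0.5)`), 0-based indices, time `t = index / fps`. At 14.4 fps
  and 1 Hz this yields contraction frames at offsets 0, 14, 29 and a
  relaxation offset of 7 frames (0.486 s).
* *Peak detection.* The activity trace is smoothed with a centred moving
  average of width `round(fps / 4f)` frames; peaks qualify when their
  topographic prominence reaches 25 % of the smoothed trace's
  (max − median) range. Both constants are configurable. Because the moving
  average of a spike-and-decay twitch lags the true activity maximum by up
  to half a window, each detected peak is refined to the raw-trace argmax
  within one smoothing width; ties resolve to the earliest frame. Without
  this refinement the detected anchor sits ~2 frames late at the default
  window width.
* *Non-contractile fallback.* If no peak clears the prominence floor the
  chain is anchored at frame 0 and the result flagged `non_contractile`
  instead of failing — poorly contracting cultures legitimately have a
  (low) movement index.
* *Normalisation.* File input is scaled to [0, 1] by the container's
  bit-depth maximum, so MI is comparable across 8- and 16-bit sources. MI
  is computed over the full frame with no background masking, matching the
  "average intensity of the differential image" definition literally.
* *Field summaries.* Mean ± SE (sample SD / √n) over fields, typically
  three per culture condition; SE is undefined for a single field.

## Synthetic contracting fields

The video generator renders elongated soft-edged ribbons
(`intensity · exp(−(u/L)⁶ − (v/w)⁶)` in ribbon coordinates) on a uniform
baseline, 5 ribbons on 256 × 256 px by default (desk-scale: well under a
second per stack). Contraction shortens each ribbon's half-length by
`amplitude · s(t)` toward its centroid — longitudinal shortening, not
translation — which guarantees frame differences concentrated at the
ribbon ends, as in real twitching myotubes. Gaussian noise (SD 0.01 by
default) is added after warping and intensities are clipped to [0, 1].

The twitch waveform `s(t)` rises linearly over `twitch_rise_s` (default
0.1 s) and decays exponentially with constant `twitch_decay_s` (default
0.3 s), a minimal two-parameter shape with fast-rise/slow-relax kinetics
typical of field-stimulated twitches; the protocol itself fixes only the
1 Hz frequency and the 14.4 fps sampling. Because 14.4 fps does not sample
1 Hz cycles at a fixed phase, the discrete trace is additionally snapped:
the frame nearest each cycle's peak is set to exactly 1, so `max(s) = 1`
is attained each cycle and the argmax sits at `round(peak_time · fps)`
regardless of phase. Voltage (20 V/25 mm) and pulse width (4 ms) are
carried as metadata only; no electric-field, calcium or optics model is
attempted.

A `ParameterError` is raised when the amplitude reaches a ribbon's
half-length (the contraction would collapse the ribbon), the analogue of a
myotube tearing off the field.

## Nuclei fields and counting

The generator places non-overlapping ellipses (semi-axes 4–7 px on
512 × 512 px) by rejection sampling with a minimum centre distance that
guarantees disjoint 8-connected components, then marks a
`Binomial(n, human_fraction)` subset in the HNA channel; the default
fraction 0.1425 reproduces the composition measured for hybrid cultures
(~14 % human nuclei despite 1:1 seeding, human myoblasts growing slower).
Counting is connected components with 8-connectivity; a nucleus is
HNA-positive when ≥ 50 % of its area (configurable) is covered by the HNA
mask — colocalisation is not otherwise defined for mask input. Empty
fields yield an undefined ratio (excluded and reported, never counted as
zero). Real fields contain touching nuclei that component counting would
merge; the generator deliberately avoids overlap, so counting accuracy on
dense clumps is untested by design.

## Satellite-cell gate

The gate is the fixed boolean predicate CD11b < t ∧ CD31 < t ∧ CD34 < t ∧
CD45 < t ∧ CD56 ≥ t with user-supplied per-marker thresholds (no automatic
threshold fitting — the assay reports no cutoffs). CD34 is a negative
selection marker here: human muscle-derived CD34⁺ cells are adipogenic.
PDGFRA (a fibro/adipogenic-progenitor marker) is recorded but never gated.
Doublet and viability gating ("single live mononuclear") are not modelled.
The generator draws log-normal intensities with population medians 10
(negative) and 1000 (positive) at log-SD 0.4 — ≈11 SD separation, so a
threshold of 100 recovers planted labels exactly; gate robustness at
overlapping populations is *not* claimed.

## Relative expression (ΔΔCt)

Per sample, `ΔCt = Ct_gene − Ct_reference` within the species block (mouse
GAPDH, human RPLP0); relative level `2^(−ΔCt)`, rescaled so the
control-group mean is exactly 1 (ΔΔCt convention — the field standard when
no standard curve is reported; raw ΔCt values are retained on the result).
Groups are compared on the rescaled linear levels with a two-sided
pooled-variance Student's t-test (Welch behind a flag), reported as means
± SE with significance at P < 0.05; the fold CI is computed on the ΔCt
(log2) scale with pooled variance and exponentiated. Tests are unpaired;
pairing of replicate experiments is not modelled.

## Secretion panel

Classification precedence: **excluded_cross_reactive** → **not_detected**
→ **upregulated** → **detected_not_upregulated**.

* *LOD censoring.* An analyte is not detected only when every well of both
  biological conditions (EPS and control) is below its LOD; individual
  sub-LOD wells are flagged regardless.
* *Cross-reactivity.* The screen compares mouse-only conditioned media
  against assay blanks: cross-reactive iff
  `mean(mouse) > mean(blank) + k·SD(blank)` (k = 3 by default) *and*
  `mean(mouse) ≥ LOD`. The source assay reported only which analytes
  "emerged as being cross-reactive" (CX3CL1, CCL3, CCL12); the k·SD + LOD
  rule is this package's operationalisation, with k configurable.
* *Upregulation.* Pooled t-test, EPS mean > control mean, P < 0.05, no
  multiple-testing correction by default (mirroring per-analyte reporting
  in this assay class); Benjamini–Hochberg is available behind `bh=True`.
  There is deliberately no "downregulated" class.

**Panel template.** The default class map holds 39 analytes: 24
upregulated (IL-6, IL-8, IL-10, IL-16; CXCL1/2/5/6/10; CCL1, CCL2, CCL7,
CCL8, CCL11, CCL13, CCL16, CCL17, CCL19, CCL20, CCL21, CCL22, CCL25,
CCL27; IFN-γ), MIF detected but flat, 11 below detection and 3
cross-reactive. Two published lists conflict over CCL16 (secreted *and*
not detected); it is placed upregulated here, following the list that
enumerates the secreted chemokines. The assay is nominally a 40-plex but
the published lists account for fewer analytes than that; CXCL12 is
included as a placeholder member completing the below-detection class, and
the panel size follows the class map rather than being forced to 40. The
generator plants basal 20 pg/mL, fold 20 for upregulated analytes, LOD
1 pg/mL, log-normal noise at CV 0.1 and n = 4 wells per biological
condition (matching the source design); background wells are capped at
0.9 × LOD so detection classes are recovered with certainty.

## Pipeline

`run_all` executes simulation → contractility → quantification →
statistics from one JSON config; a single master seed fans out to fixed
per-stage offsets (video 100 + field index, nuclei 300, markers 400, Ct
500, panel 600), so any stage can be reproduced in isolation and a report
is bit-identical given (config, seed). The default template plants twitch
amplitudes 0.5 px (human-only), 4 px (C2C12) and 4 px (hybrid) — the
low/high/high contrast pattern — with 3 fields per condition. Validation
rejects configs that declare both simulation parameters and input paths
for a stage before any computation runs.

## What green tests establish — and what they do not

The simulator provides planted ground truth for every pipeline stage, so
the tests establish *internal correctness*: exactness and invariance
properties of the movement index, agreement with brute-force oracles
(pixel loops, flood-fill labeling, row-wise gating, textbook t
statistics), calibration of the t-test under a true null, and exact or
statistical recovery of planted amplitudes, fractions, folds and analyte
classes. They do not establish performance on real microscopy: optics,
focus drift, uneven illumination, touching nuclei, marker spillover,
amplification-efficiency differences and bead-assay artefacts are all
outside the generated world, and the published quantitative values for the
original cultures derive from undeposited recordings that cannot be
recomputed here.
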