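# twitchindex

Analysis toolkit for *in vitro* exercise experiments on cultured myotubes:
quantifying the contractile activity that electric pulse stimulation (EPS)
evokes in time-lapse videos, measuring the composition of human/mouse hybrid
myotube cultures, and testing species-resolved myokine responses.

Human primary myotubes often contract poorly under EPS; fusing human
myoblasts with mouse C2C12 myoblasts yields hybrid myotubes that twitch
vigorously, and species-specific assays (qPCR with species primers, a
human multiplex cytokine panel) then read out the human contribution
separately. This package implements the quantitative analysis of such an
experiment end to end, together with a synthetic-data generator that makes
every step testable against planted ground truth.

## The movement index

For a stack of frames $I_t$ acquired at rate $f_s$ (default 14.4 fps) under
EPS at frequency $f$ (default 1 Hz):

1. An activity trace $a(t) = \langle |I_t - I_{t-1}| \rangle$ (mean absolute
   inter-frame difference) locates the **first maximum-contraction frame**
   $t_0$ as its first prominent peak.
2. Contraction frames sit one stimulation period apart,
   $c_k = t_0 + \mathrm{round}(k f_s / f)$, and each is paired with the
   relaxation frame half a period later,
   $r_k = c_k + \mathrm{round}(f_s / 2f)$ (≈0.5 s for 1 Hz), over a 3–5 s
   analysis window.
3. Each pair yields a differential image $D_k = |I_{c_k} - I_{r_k}|$; the
   pairs are overlaid as a pixel-wise mean $\bar D$, and the **movement
   index** is the spatial mean intensity of $\bar D$:

$$\mathrm{MI} = \frac{1}{HW} \sum_{x,y} \bar D(x, y).$$

Static scattering structures cancel in the subtraction, so the index
responds only to moving parts: it is exactly zero for a static noiseless
field, invariant under global additive intensity offsets, and linear under
intensity scaling.

The companion modules compute the human-nuclei ratio of hybrid cultures
(connected-component counting on DAPI/HNA mask pairs), the satellite-cell
gate CD11b⁻CD31⁻CD34⁻CD45⁻CD56⁺ on marker tables, ΔΔCt relative expression
(mouse GAPDH / human RPLP0 references), and secretion-panel classification
(LOD censoring, mouse cross-reactivity exclusion, pooled t-test
upregulation calls at P < 0.05).

## Worked example

Simulate one contracting field and analyse it:

```sh
$ twitchindex simulate video --out demo --seed 42
wrote demo/stack.tif (72 frames)
$ twitchindex mi demo/stack.tif --out demo/mi.json --render demo/overlay.png
stack: movement index 0.0116277
```

`demo/mi.json` then holds the full result:

```json
{"field_id": "stack", "movement_index": 0.011627685510480507,
 "per_pair_indices": [0.0118148, 0.0113290, 0.0117391],
 "start_index": 1, "pairs": [[1, 8], [15, 22], [30, 37]],
 "non_contractile": false}
```

The first maximum contraction was found at frame 1; at 14.4 fps and 1 Hz
the three analysed cycles pair contraction frames 1/15/30 with relaxation
frames 7 frames (≈0.49 s) later, and the movement index is the mean
intensity of the overlaid differential images (here dominated by the
simulated camera noise floor plus the twitch displacement of the ribbons).
`demo/overlay.png` is the pseudo-colored movement map.

The full pipeline — three culture conditions (human-only low-amplitude,
C2C12 and hybrid high-amplitude) × three fields, seven nuclei fields,
gating, expression and the 39-analyte secretion panel — runs as:

```sh
$ twitchindex run-all --out run --seed 1
Movement index (mean ± SE over fields):
      HSMM: 0.0113 ± 1.25e-05  (n=3)
     C2C12: 0.01206 ± 5.499e-05  (n=3)
    hybrid: 0.012 ± 0.0001054  (n=3)
Pairwise movement comparisons (pooled t-test):
  HSMM_vs_C2C12: p = 0.000172 *
  HSMM_vs_hybrid: p = 0.00276 *
  C2C12_vs_hybrid: p = 0.616
Human nuclei: 13.31 ± 1.03 % (7 fields, 78–99 nuclei/field)
Satellite gate: 50 of 250 cells selected
...
Secretion panel classes:
  detected_not_upregulated: 1
  excluded_cross_reactive: 3
  not_detected: 11
  upregulated: 24
```

Both high-amplitude conditions separate significantly from the
low-amplitude one while remaining indistinguishable from each other; the
nuclei ratio estimate brackets the planted 14.25 % human fraction; and the
panel classifier recovers the planted analyte classes, including the three
cross-reactive analytes excluded before any up/down call.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed (writing a
run summary next to the output) and emits the JSON object of quantitative
targets. See `docs/methods.md` for the model, parameter defaults and the
limits of what synthetic data can establish.
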