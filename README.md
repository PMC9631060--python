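# nichequant

Quantification pipeline for engineered perivascular-niche (PVN) hydrogel
experiments: glioblastoma (GBM) spheroid invasion, 3D microvascular
morphometry, tumor-cell-to-vessel proximity, marker-positive cell
fractions, temozolomide dose-response, and the companion qPCR and
cytokine-array normalizations.

It is written for researchers who culture GBM cells with brain vascular
cells (endothelial cells, pericytes, astrocytes) in 3D hydrogels and need
the bespoke image- and assay-quantification steps of that workflow as
tested, scriptable code rather than a chain of ImageJ macros and
CellProfiler pipelines. Because such studies rarely deposit raw imaging
data, the package ships a first-class synthetic-scene generator whose
artifacts carry analytically known ground truth, so every stage is
verifiable end-to-end.

## What it computes

**Spheroid invasion** — from a binarized tumor-channel image: the radial
profile I(r) (fraction of occupied pixels at radius r from the spheroid
centroid), the characteristic radii r₂₅/r₅₀/r₇₅ where an isotonic
envelope of I(r) falls to 25/50/75 % of its maximum, the total
fluorescent intensity

    TI = ∫₀ᴿ I(r) · 2πr dr    (µm², equals the foreground area),

the outgrowth area (convex hull of invading cells) and the density
TI / area.

**Vessel morphometry** — a 3D vessel mask is thinned to a medial
skeleton, organised into a spatial graph (endpoints, junctions, branch
paths with anisotropic physical lengths), and summarised as total length
(mm·mm⁻³), branch and junction densities (mm⁻³) and average branch
length (µm).

**Proximity mapping** — an exact Euclidean distance transform of the
vessel maximum-intensity projection assigns each tumor-cell object a
distance (mean over its pixels by default), binned into 0–10, …, 40–50,
\>50 µm; cells under 50 µm count as PVN-resident. Marker⁺ vs marker⁻
subpopulations get paired histograms.

**Marker quantification** — a GBM cell is marker-positive when a marker
object shares ≥ 30 % of its area with the cell; fractions and the
composite ratios EdU⁺/KI67⁺, treated/control, and cPARP⁺/KI67⁺ follow.

**Assay quantification** — growth-rate-corrected drug response
GR(c) = 2^(log₂(x(c)/x₀)/log₂(x_ctrl/x₀)) − 1, fitted with
GR(c) = GR_inf + (1 − GR_inf)/(1 + (c/GEC50)^h) and solved analytically
for GR50; ΔΔCT fold changes 2^(−ΔΔCt) against a baseline condition with
an internal reference gene; cytokine-array spot normalization by
positive-reference spots with group-relative fold changes.

## Worked example

```bash
python examples/01_invasion_profiling.py
```

```
planted:  r50 = 60.0 µm, r25 = 71.0 µm, r75 = 49.0 µm
measured: r50 = 59.2 µm, r25 = 70.1 µm, r75 = 48.9 µm
total fluorescent intensity = 12290 µm² (foreground area equivalent: 12302 µm²)
outgrowth area (hull) = 48946 µm², density = 0.251
```

The scene plants a logistic invasion field (core R0 = 60 µm, decay
s = 10 µm); the measured r₅₀ recovers the core radius within a micron,
r₂₅/r₇₅ land on the analytic crossings R0 ± s·ln 3, and the polar
integral reproduces the foreground area to 0.1 %. The other scripts in
`examples/` walk through vessel morphometry, PVN binning, marker calls,
GR50 fitting and the ΔΔCT/secretome normalizations the same way, each
printing measured-vs-planted values.

The same analyses run from the shell:

```bash
nichequant simulate spheroid --seed 3 --out scene
nichequant invade --images 'scene/*.tif' --spacing-um 1.0 --out results
nichequant vessels --stack stack.tif --spacing-um 5 1 1 --out results
nichequant gr --table viability.csv --out results
```

plus `proximity`, `markers`, `pcr`, `secretome`, a YAML-config driven
`run`, and `compare` for merging per-group metric tables into the tidy
long format external statistics packages consume.

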