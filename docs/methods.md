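# Methods

## Assay model

One activated cell nucleates exactly one ASC speck, so the fraction of
cells carrying an intracellular speck measures pyrin-inflammasome
activity. The package's %ASC statistic divides the pooled
intracellular-speck count by the pooled live-cell count over the five
replicate fields of a sample. With at most one speck per cell the two
possible numerators — specks, or cells-with-specks — coincide; the
implementation counts specks, which is the assay's stated formula, and
this is the one place the name "%ASC (percent positive cells)" and the
arithmetic could in principle diverge (a cell with two detected specks
would be counted twice). Pooling sums counts first and divides once, so
dense fields weigh more than sparse ones; the alternative (mean of
per-field ratios) would weight fields equally and is deliberately not
used.

## Speck detection

Candidates come from multi-scale Laplacian-of-Gaussian detection
(scikit-image `blob_log`) over `num_sigma` scales in
`[min_sigma, max_sigma]`; a blob detected at scale σ is assigned radius
√2·σ, the scale-space optimum for a Gaussian spot of width σ. The
candidate stage uses a floor of 5% of the strongest LoG response rather
than an absolute response threshold, which makes the candidate set
invariant under uniform intensity scaling — required for the relative
threshold to mean the same thing on dim and bright acquisitions.

Each candidate's `peak` is the normalised image intensity at its centre
(not the LoG response). The dual threshold keeps peaks at or above
`max(abs_threshold, rel_threshold * channel_max)`. Thresholding runs
*before* non-maximum suppression: it is cheaper, and suppression
decisions are then made only among above-threshold specks. Because
suppression is greedy in descending peak order, removing the dimmest
candidates can only shrink the surviving set, so the final count is
monotone non-increasing in both thresholds (property-tested).

NMS overlap is the intersection area of the two circular footprints
divided by the area of the smaller circle (a small speck swallowed by a
large one scores 1). Ties in peak are broken by ascending row then
column, making the output deterministic. The greedy pass is verified
exactly against an exhaustive all-pairs implementation on random sets.

### Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| min_sigma / max_sigma | 1 / 4 | px | speck diameters ~0.7–3 µm at 0.5 µm/px |
| num_sigma | 7 | – | 0.5 px scale steps |
| overlap_max | 0.5 | – | adjacent specks rarely overlap >50% |
| abs_threshold / rel_threshold | 0.1 / 0.1 | fraction of full scale | permissive starting point; must be tuned per staining batch |

The intensity thresholds are *operating points*, not constants: the
assay procedure inspects the distribution of candidate local maxima
(`local_maxima_histogram`, or `speckquant detect --histogram`) and
places the cut-off in the valley between the diffuse-background mode and
the speck mode. For fields produced by the synthetic generator's default
conditions that valley spans roughly 0.15–0.65 of full scale, and
`synthetic.tuned_detection_params()` fixes the operating point at an
absolute cut-off of 0.3 — the value used by the test-suite and
acceptance analyses.

## Cell segmentation

The classical backend smooths with a Gaussian (σ = 2 px), thresholds by
Otsu's method, fills holes, and splits touching nuclei by watershed on
the negated Euclidean distance transform, seeded at distance-map peaks
at least 7 px apart (about one small-nucleus radius). Otsu adapts to the
data, so counts are invariant under uniform gain changes. A uniform
image has no Otsu threshold and yields zero cells with a warning.

"Live cell" is operationalised purely by area: segments outside
[50, 5000] px² (at 0.5 µm/px: ~12–1250 µm²) are discarded as debris or
unresolvable clumps. This is a documented simplification — no
morphological or staining-based viability call is made, and the cell
extent used for the intracellular test is the nucleus, not the
cytoplasm, so a speck lying in cytoplasm but off the nucleus is counted
as extracellular. Both choices bias %ASC conservatively.

The star-convex backend (StarDist, pretrained fluorescence model) is
optional at runtime because it needs downloaded weights; when the
dependency is absent the backend raises an error that names the
classical fallback. All tests and shipped analyses use the classical
backend.

## Reference range and classification

The healthy range per stimulation condition is the two-sided Student-t
confidence interval of the mean (default 95%); with typical cohort sizes
(n = 10) the t correction matters. The published ranges
(unstimulated 3.1, CI 1.4–4.8; stimulated 14.7, CI 7.8–21.6) ship as
constants and are used as the default decision thresholds; they are
inputs, not quantities this package re-estimates.

`classify` reports a three-way position (above / within / below, with
boundary values counted as within — conservative for a screening test),
while the clinical flag `flag_overactive` is one-sided: only %ASC above
the upper bound indicates pathology. A %ASC below the lower bound is
statistically "below" but clinically unremarkable, and published cohort
reports treat such samples as unflagged.

## Synthetic fields

The generator emulates the assay's imaging statistics at the level that
matters for counting: non-overlapping soft-edged nuclei (radius
12 ± 3 px, rejection-sampled with a 4 px clearance), a diffuse
cytoplasmic ASC disc around each nucleus at 0.08 of full scale, one
isotropic Gaussian punctum (σ = 2 px, amplitude 0.6) planted well inside
each speck-positive nucleus, extracellular puncta planted on free
background, and additive Gaussian read noise (σ = 0.02, i.e. speck
SNR ≈ 30). The default frame is 1040 × 1392 px at 0.5 µm/px with 370
nuclei, matching the assay's camera and reported mean density; test
analyses use 512 × 512 frames with proportionally fewer cells to keep
runtimes in seconds. With `cell_count_cv > 0` the per-field nucleus
count varies between replicates (the end-to-end analyses use cv = 0.37,
the reported between-field variability of 370 ± 136 cells/frame), which
is what makes the automated-vs-truth count regression informative.

Deliberately not modelled: optical PSF and chromatic effects, uneven
illumination, out-of-focus debris, apoptotic morphology, speck shape
irregularity, and cytoplasm segmentation. Passing the planted-recovery
tests therefore demonstrates the correctness of the counting machinery
under clean imaging, not robustness to every real-world artefact —
threshold tuning and the manual-override path exist precisely because
real fields are messier.

## Numerical and design notes

- Coordinates are 0-based (row, col); a "1392 × 1040" (width × height)
  camera frame has array shape (1040, 1392).
- Intensity normalisation divides by 2^depth − 1; PNG export rescales to
  8-bit rounding half-up, so 8-bit data round-trips losslessly.
- Circle overlap uses the closed-form lens area with arguments clipped
  to [−1, 1] before `acos`; concentric/disjoint cases short-circuit.
- Regression direction: manual on automated. R² is symmetric, and the
  slope then acts as an automated→manual calibration.
- Batch runs are deterministic: fixed row order (sample_id ascending),
  a config hash embedded in every result row, and per-field seeds
  derived arithmetically from the base seed (kept below 2³¹).
- A failed field (missing file, unreadable image) fails its sample with
  a logged reason; the rest of the batch continues, and the CLI exits
  non-zero iff any sample failed.

## Known limitations

- Precision/recall of 1.0 on synthetic fields reflects the generator's
  clean conditions; real micrographs need per-batch threshold tuning.
- The intracellular test uses nucleus labels; specks over cytoplasm but
  not nucleus count as extracellular.
- No sub-pixel localisation beyond the LoG grid (≈1 px accuracy), which
  is ample for counting.
- Only standard grayscale TIFF/PNG input; vendor raw formats must be
  pre-converted.
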