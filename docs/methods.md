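# Methods

## Scope and model

`lipidscreen` analyses high-content RNAi screens with two per-gene
readouts: endocytosed DiI-LDL and filipin-stained free cholesterol (FC).
The pipeline has five stages — synthetic data, per-cell image
quantification, deviation-value statistics, phenotypic profiling, and
secondary-assay rules — each usable on its own.

### Deviation value

For replicate *r* and siRNA *s*, with x̄ the replicate mean of a
parameter and C the set of the 16 negative-control position means of the
same replicate:

    dev(r, s) = (x̄(r, s) − mean(C)) / (2 · err(C))

The error term `err` defaults to the **mean absolute deviation** of the
control means about their mean: the statistic is a z-like score in which
twice the absolute error replaces the standard deviation. The phrasing of
the source procedure admits several estimators; MAD is the closest
literal reading of "twice the absolute error", and `sd` / `sem` are
available behind the `estimator` flag so the choice is auditable rather
than baked in. Per-replicate deviations are averaged arithmetically into
the siRNA's mean deviation ("deviation units").

Consequences used by the tests: control deviations are centred at zero
by construction (to 1e−10); the statistic is odd about the control mean;
it is invariant to rescaling all means by c > 0 (MAD scales with c).

### Region normalization

384-well plates show edge artifacts. Wells are assigned region 1 (edge),
2 (edge neighbours) or 3 (interior) as a pure function of (row, col);
deviation values for FC plate assays are computed against negative
controls **of the same region**. A region with fewer than 2 controls
falls back to plate-wide controls (configurable to raise instead).
Cell-array assays (LDL uptake) use all controls. Randomly placed
controls can leave a region thin (2–4 controls), which widens the
control spread and hence the thresholds; this is inherent to the region
scheme, not a defect.

### Thresholds and calls

Effector bounds are derived from negative-control **and mock** mean
deviations: `upper = max(control means) + 3·SEM`, `lower = min − 3·SEM`,
with `SEM = sd(all per-replicate control deviation values) / √n_replicates`.
The "extreme" anchoring is chosen because it guarantees, deterministically,
that no control passes its own thresholds — the self-exclusion property
the procedure is validated by; a "nearest" mode exists behind a flag.
Boundary equality is not a call (strict inequalities; deterministic
tie-break). Published bounds (e.g. LDL GWAS2 [−0.55, 1.02]) can be
supplied verbatim to reproduce published-style classifications without
raw data. A gene is a hit when ≥ 2 distinct siRNAs are effectors in one
assay; genes with < 2 siRNAs tested are flagged untestable.

An empirical FDR accompanies each call: two-sided add-one empirical
p-values against the pooled control deviation distribution,
Benjamini–Hochberg adjusted per assay/parameter. The original screen's
Table-level FDR computation is not documented anywhere we could follow;
this procedure is this package's own, clearly labelled choice.

## Synthetic data

The generator emulates what the statistics need, not cell biology:

* **Cells** are discs (radius 16–22 px) with nuclear discs (6–9 px),
  placed on a jittered 64-px grid of a 320×320 field (≥ 52 px centre
  separation) so neighbouring perinuclear rings stay disjoint and
  ground-truth attribution is unambiguous.
* **Structures** are hard discs (radius 1.5–2.5 px, Poisson(6) per cell,
  lognormal amplitudes, CV 0.35) placed without overlap; FC spots live
  in an annulus up to 14 px outside the nucleus, LDL spots anywhere in
  the cytoplasm. A spot that cannot be placed after 200 attempts is
  dropped, and the ground truth records only what is rendered.
* **Effects** are multiplicative on the latent draws: `*_structures`
  scales the Poisson mean, `*_total`/`*_concentration` scale amplitudes,
  `fc_area` scales spot area, applied to a penetrant fraction of cells.
  Expected readouts therefore scale exactly with the planted shifts.
* **Noise**: lognormal intensity factors per replicate (CV 5%), position
  (4%) and image (3%); Gaussian read noise of 2% of a 4096-unit dynamic
  range (Poisson shot noise optional); a linear background gradient; and
  a multiplicative plate-edge factor per region (defaults 0.85 / 0.95 /
  1.0 — the artifact's magnitude is this package's choice, as only the
  existence of region normalization is documented).
* **Scale**: absolute intensities are arbitrary camera units; only
  relative effects are meaningful, so tests assert ratios, never
  absolute levels.

What passing tests on this generator do **not** show: robustness to real
cell morphology (spread shapes, touching cells, mitotic figures),
staining heterogeneity, or focus drift. The generator's regular geometry
is deliberately favourable to segmentation; the statistics, not the
segmentation difficulty, are under test.

Screen-level simulation sizes follow the screening design: 384 positions
(16 negative controls, 8 mock, 8+8 positive, 4 transfection controls),
3 biological replicates, 4 images per position, ~18 cells per image.
Test and acceptance runs use these sizes; the acceptance script runs 10
null screens and 5 recovery screens, and renders 5–20 noise-free scenes,
sizes chosen to keep a full run in minutes while medians remain stable.

## Imaging

* Nuclei: Gaussian smoothing (σ 2), Otsu (or fixed) threshold, minimum
  area 40 px², optional distance-transform watershed for touching
  nuclei. Cell regions preserve nucleus labels, so cell count equals
  nucleus count by construction.
* Cell regions: `dilate` = nearest-nucleus assignment within a Euclidean
  radius (exact disc for an isolated nucleus; implemented via the EDT
  with feature indices); `propagate` = Dijkstra geodesic growth over a
  guidance channel with step cost `length · (1 + w·(1 − intensity))`.
  On a flat guidance image propagation reduces to dilation up to a thin
  (≤ 2 px) discretization band at region boundaries — the chamfer metric
  of the 8-connected graph is not exactly Euclidean.
* Structures: local adaptive threshold — pixel > window median +
  max(3 robust sd, 2 intensity units), window 31 px — then connected
  components split along cell boundaries, filtered by area 4–400 px² and
  eccentricity ≤ 0.95 (from second central moments). FC detection is
  restricted to a perinuclear ring (nucleus boundary to +18 px). These
  defaults are this package's calibration of an unpublished parameter
  set and are config-overridable.
* Local background per structure: median of its 31-px window excluding
  detected foreground. Per-structure signal sums are floored at zero;
  `concentration × mask pixels = total` holds identically. Cells
  touching the image border are retained (flag to exclude).
* QC: automated surrogate for visual curation — variance-of-Laplacian
  focus metric on the normalized nuclear channel (threshold 1e−4),
  nucleus-count bounds, saturated-pixel fraction.

On noise-free rendered scenes the extracted totals match ground truth
within 1% (rounding to 16-bit pixels and the background-median estimate
are the only error sources) and structure counts match exactly; this is
asserted over 20 seeds.

## Secondary assays

All rules are conjunctive (effect-size criterion AND t-tests), so
removing any sub-criterion can only add calls. t-tests default to the
Welch form; a flag restores pooled variance. qPCR technical triplicates
are averaged on the CT scale before ΔΔCT; the ΔΔCT fold change is
invariant to per-sample CT offsets, and densitometry normalization is
invariant to rescaling a gel's lanes. Published control standard
deviations (0.21/0.20 for mRNA, 0.13/0.18 for protein) are accepted as
config constants or recomputed from supplied controls. The
"untransfected" GFP threshold is read as the 97th percentile of the mock
GFP distribution (the only reading that yields a threshold), and
"transfected" as > 4× that value; cells in between are intermediate and
excluded from ratios. A discordant two-siRNA result is reported as
"−/+" in the summary matrix.

## Numerical choices and degenerate inputs

* Identical control means → `DegenerateControlsError` (deviation
  undefined), never silent NaN.
* A cell with no structures gets defined zeros, not missing values.
* Missing replicates: mean over available replicates with n recorded;
  an siRNA with no scored replicate is dropped.
* Pixel coordinates are 0-based row-major; images are single-plane
  16-bit; areas in px² (no µm calibration).
* Genomic annotation is 1-based; a `pos_0based` column is rejected at
  load. Locus windows are closed ±50 kb intervals; no liftover.
* All randomness descends from one seed via `SeedSequence.spawn`;
  outputs are byte-identical across runs of the same configuration.

## Known limitations

* The functional-group rules encode the described direction patterns
  (co-correlated / FC-only / inverse / LDL-only / unclassified); an
  optional hierarchical clustering (Euclidean, complete linkage, cut at
  5) is provided for exploration, but neither can be audited against an
  unpublished original assignment.
* `propagate` region growing is O(pixels · log pixels) in Python and
  noticeably slower than `dilate`; fine for fields of view, not for
  whole-plate re-analysis.
* The generator does not model transfection biochemistry, confocal
  z-stacks, or photorealistic textures (non-goals).
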