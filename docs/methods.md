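# Methods

## The quantification problem

A GFP-tagged tandem-SIM (polySIM) reporter derived from the STUbL RNF4
accumulates in bright sub-micron puncta wherever polySUMO chains
concentrate.  Given three-channel confocal fields — DAPI (nuclei), GFP
(reporter) and an RFP/N-cadherin counterstain (cell bodies) — the pipeline
produces, per cell, the number of puncta, their intensities measured on the
raw GFP projection, and the split of puncta between the nuclear and
cytoplasmic compartments; per image it pools these into a mean puncta count
per cell and a nuclear-localization percentage.  Group statistics then
compare conditions (control, SUMO-protease or SUMO2 overexpression,
arsenic, peroxide, starvation, doxorubicin, heat shock).

## Pipeline stages and their parameters

All stages operate on 2-D average z-projections; computation is floating
point, but intensity measurement always returns to the raw projection.

1. **Projection and rescaling.**  Per-pixel mean over z for each channel.
   Images are affinely rescaled to [0, 1] before any thresholding; a
   constant (blank) image rescales to zeros with a warning rather than an
   error, so negative-control fields flow through.
2. **Nuclei.**  The fidelity path is an externally supplied integer label
   mask (e.g. from a dedicated nuclear segmentation model); the built-in
   classical fallback smooths the DAPI projection (sigma 1 px), thresholds
   by two-class Otsu, fills holes and splits touching nuclei with a
   distance-transform watershed (seed separation 10 px).  Nuclei smaller
   than **1200 px^2** (strict inequality) are discarded.
3. **Cell bodies.**  GFP and RFP unit images are averaged pixelwise and
   smoothed (sigma 1 px).  Three-class Otsu thresholds this combined image;
   taking the middle class as foreground means everything above the
   *lower* boundary is foreground, and that boundary is multiplied by the
   correction factor **0.5**.  Foreground is partitioned among nuclear
   seeds by watershed on inverted intensity; each cell is forced to contain
   its nucleus; foreground with no nucleus is dropped.  The watershed
   relief is a grayscale opening (disk radius 5) of the combined image so
   that bright reporter puncta near a shared boundary cannot deflect the
   dividing line — boundaries should follow cell-scale intensity, not
   diffraction-scale spots.
4. **Cytoplasm.**  The tertiary compartment, cell minus nucleus, possibly
   empty.
5. **Spot enhancement.**  Background subtraction by a large Gaussian
   (**sigma 300 px**, clipped at zero), smoothing (**sigma 1 px**), then an
   exact grayscale white top-hat with a disk of radius
   floor(**feature size 4** / 2) = 2 px.  Exact morphology is used, not a
   separable approximation.
6. **Spot identification.**  The enhanced image inherits the [0, 1] scale
   of the rescaled projection; the binarization threshold is the two-class
   Otsu value floored at **0.05** on that scale.  The floor is what keeps
   featureless fields (the binding-dead control) empty: their noise never
   reaches 0.05 of the field's dynamic range, whereas re-normalizing the
   enhanced image to its own maximum would turn the floor into a fraction
   of the noise peak and fill blank fields with false spots.  Components
   are 8-connected.  Clumps are split by
   watershed with two seed families: intensity maxima of a barely-smoothed
   (sigma 0.3) background-subtracted image whose prominence exceeds a
   tenth of the threshold (shot-noise ripples on one spot never clear this
   bar; genuinely bimodal pairs do), plus prominent lobes (>= 0.5 px) of
   the smoothed distance transform for shape-only splits.  Seeds closer
   than **2 px** are suppressed, keeping the brighter; each seed region is
   anchored at its most interior pixel so a symmetric object contributes
   exactly one seed.  Single-pixel watershed fragments are absorbed into
   the adjacent sibling label (they are dividing-line artifacts, not
   objects).  Finally the area-equivalent diameter 2*sqrt(area/pi) must lie
   in **[1, 10] px**, inclusive.
7. **Assignment and measurement.**  A punctum belongs to the compartment
   containing its rounded centroid: nucleus -> nuclear, cytoplasm ->
   cytoplasmic, background -> excluded.  Mean/max/integrated punctum
   intensity and mean cell/nucleus/cytoplasm intensities are measured on
   the raw projection.  Per image, pct_nuclear pools all puncta of the
   image (100 * sum nuclear / sum total) rather than averaging per-cell
   fractions: the image is the replicate unit of the localization analysis.

## Statistics

Localization percentages are compared with a two-sided unpaired
Mann–Whitney U test: exact by full enumeration of rank assignments when
n_a + n_b <= 16 without ties (p = min(1, 2·min(P(U<=u), P(U>=u)))),
otherwise a normal approximation with midrank tie correction and a 0.5
continuity correction.  Counts and intensities across condition × factor
designs use a two-way ANOVA with interaction (Type II sums of squares,
which reduce to the balanced decomposition on balanced designs) with
pairwise factor-level contrasts on the residual mean square, adjusted by
Šidák (Holm available).  The multiple-comparison flavor is a package
choice; commercial packages default differently and do not document which.

## The synthetic scene generator

Because no image data accompany the study conditions, every stage is
validated against simulated fields with exact ground truth.  A scene is a
16-bit, 1024×1024-by-default field with three channels and a thin z-stack
(3 slices, ±0.6 px defocus blur on the outer slices) so the average
projection is meaningful:

- **Nuclei**: non-overlapping rotated ellipses, semi-axes 22–34 px,
  rejection-sampled; DAPI fills them (per-nucleus gain 0.8–1.2×).
- **Cells**: nuclei dilated by 18 px, clipped at the nearest-nucleus
  partition; RFP fills them.  This mirrors a membrane counterstain whose
  job is only to carry cell-scale extent.
- **Puncta**: per-cell counts are Poisson(λ); each punctum is nuclear with
  probability `nuclear_fraction`, placed uniformly in its compartment with
  a 2 px margin and a minimum center-to-center separation of 4 px;
  Gaussian profiles with sigma 0.8–2.0 px and peak 1200–3000 raw units.
- **Noise**: smooth background gradient (amp 100), diffuse GFP inside
  cells (300), Poisson shot noise at 0.25 photons per intensity unit, and
  Gaussian read noise (sd 20), then 16-bit quantization.  Peak SNR of the
  dimmest default spot is well above 10.

Condition presets (λ, nuclear fraction, a peak-scale factor modelling GFP
quenching under oxidative stress) are **invented numbers**; only their
ordering is anchored to the reported biology — protease overexpression
depletes puncta, SUMO2 overexpression and arsenic induce them, the
binding-dead construct shows essentially none, and control puncta are ~90%
nuclear.  Scenes are pure functions of the seed.

What the generator does **not** emulate: optics-accurate PSFs, spectral
bleed-through, cell-to-cell reporter expression variability beyond a flat
gain, clustered/nested spot structure, out-of-focus cells, or segmentation-
confounding debris.  Passing recovery tests therefore demonstrates the
pipeline's internal correctness and its behaviour under controlled
difficulty — not performance on real micrographs.

## Validation experiments and problem sizes

Three standard experiments (in `polysumo.experiments`) are shared by the
tests, the acceptance script and the analysis drivers:

- **Count recovery**: nine 512×512 scenes of 6 cells, λ = 8, easy-regime
  spot widths.  "Spots of 2–6 px diameter" is read as the diameter of the
  thresholded support of a Gaussian spot, ≈ 3.6 sigma at the operating
  threshold, i.e. sigma in [0.6, 1.6] px.  The detected per-cell count
  must equal the truth in ≥ 95% of cells.  Detection runs at 512² with the
  same pixel-scale parameters as full-size fields; nothing in the chain is
  field-size dependent except the sigma-300 background estimate, which is
  flat either way.
- **Localization recovery**: nine full-size 1024×1024 scenes of 30 cells,
  λ = 12, true nuclear fraction 0.9.  Thirty cells pool ~350 puncta per
  image so the binomial sampling error of a per-image percentage (~1.6 pp)
  sits well inside the ±5 pp recovery band; smaller scenes would test the
  binomial noise of the generator, not the pipeline.
- **Differential detection**: control (λ = 5) versus arsenic-stress
  (λ = 15) presets, nine images each, Mann–Whitney on per-image mean
  puncta per cell.

The truth nuclear masks serve as the external-segmentation input in these
experiments, exactly as externally produced masks would in the fidelity
path; the classical DAPI segmenter is validated separately.

## Numerical choices

- **Otsu**: between-class variance maximized over a fixed 256-bin histogram
  on [0, 1] (64 bins only where an exhaustive-search oracle must stay
  tractable); thresholds are reported as bin upper edges; ties break toward
  the smallest threshold(s).  The implementation scores all boundary pairs
  via cumulative moments in one vectorized pass; tests compare it against
  an explicit exhaustive search.
- **Connectivity** is 8-neighbour for spot components (diagonal halo pixels
  of a spot belong to the spot).
- **Degenerate inputs**: blank fields segment to empty masks; a
  single-occupied-bin histogram raises `DegenerateHistogram` where a
  threshold is the contract, and yields an empty result where detection is.
- **Determinism**: no stage uses randomness; scenes are seeded; re-running
  the pipeline byte-reproduces every CSV.
- **Seeds** derived from a base seed use a SHA-256 spread of the scene
  index XORed with the base, kept below 2^31.

## Known limitations

- Spot pairs closer than ~2 effective sigma with adverse brightness ratios
  are below the resolution of maxima-based declumping; at easy-regime
  densities this leaves roughly 2–8% of cells with an off-by-one count
  depending on the draw.  Fitting-based splitting could go further but is
  outside the declumping model used here.
- Very narrow spots (sigma < 0.7 px) lose most of their energy to the
  sigma-1 smoothing and can drop below the global threshold when the field
  also contains bright wide spots.
- The classical nuclear segmenter assumes well-separated, convex,
  uniformly stained nuclei; crowded or textured nuclei need the external
  mask path.
- The cell-body watershed has no intensity gradient to follow between
  abutting cells of similar brightness; its dividing line approximates the
  geodesic midline, which matches the generator's geometry but is only a
  stand-in for boundary evidence real membrane stains would provide.
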