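# Methods

This note documents the models, conventions and design choices behind
`neurocult`, in the spirit of a package reference manual: what each
stage assumes, which knobs matter, and what the synthetic tests do and
do not demonstrate about real data.

## Imaging model and preprocessing

Input images are single-channel 2-D fluorescence tiles (fields of view,
FOVs) acquired daily over a well mosaic; the default physical pixel
pitch is 0.62 µm. Preprocessing follows the common widefield workflow:
32-bit acquisitions are linearly mapped onto the 16-bit range
(round-half-up at the midpoint — the convention is stated because it is
otherwise ambiguous), and intensities are rescaled to their min–max
range. Rescaling outputs the unit interval by default; a 16-bit
full-scale option exists. Both operations preserve the rank order of
pixel intensities, which is the property downstream thresholding relies
on. A constant image rescales to all zeros with a logged warning rather
than an error, because blank tiles occur routinely at well edges.

Dataset layout on disk is `plate/<condition>/day<d>/<well>_fov<i>.tif`
plus a sidecar `manifest.csv` (plate, well, condition, day, fov, path)
and a YAML platemap. Metadata travels in the manifest rather than TIFF
tags so any TIFF writer interoperates. Missing (well, day) pairs are
recorded as gaps, not errors; a well on disk that is absent from the
platemap is an error naming the well, because silently mis-assigned
conditions are worse than a crash.

## Segmentation

The segmenter is a deterministic classical stand-in for a trained pixel
classifier, and the mask-ingestion path (`ingest_masks`) exists
precisely so that externally trained classifiers can replace it without
touching anything downstream (overlaps resolve soma-priority; any value
> 0 is foreground).

Internal pipeline: Gaussian smooth (σ = 0.6 px) → Otsu threshold →
morphological opening with a disc of radius 4 px (≈ half the expected
soma radius). Foreground that survives the opening is a *soma
candidate*; foreground removed by it is neurite. Candidates are
additionally gated by an intensity marker: the image smoothed heavily
(σ = 2.5 px) must exceed a threshold halfway between the foreground
threshold and the maximum somewhere inside the component. The gate is
needed because compact hubs where several fasciculated neurites cross
can pass a pure width criterion, but their local average intensity is
well below a cell body's; width alone cannot distinguish them.

Known limitation: somata far below the nominal radius (≈ 3 px against a
6 px mean, i.e. ~3σ outliers of the generator's radius distribution)
fall under the opening scale and are missed. On the synthetic grid this
caps a few frames at ~0.87 soma Dice while the grid mean sits at
~0.94 soma / ~0.95 neurite; the Dice property test therefore asserts
the grid mean against the 0.9/0.8 thresholds with a 0.8 per-frame
floor. A trained classifier ingested through `ingest_masks` is the
right tool when sub-scale somata matter.

Object extraction uses 8-connectivity. Perimeter is the **pixel-edge
count** (number of unit edges between object and background/border),
not a Crofton-style estimate: the cluster metrics only require a
convention that is exactly reproducible and consistent across
timepoints, and the pixel-edge walk is both. Border-touching objects
are retained since whole wells are tiled.

## Morphometrics

Neurite masks are thinned with iterative Zhang–Suen-style thinning
(`skimage.morphology.thin`), which leaves no 2×2 solid blocks. Neurite
length is the skeleton pixel count — deliberately a chessboard measure,
with diagonal steps uncorrected, because that is the metric's
definition; tests that need rotation stability compare the
√2-corrected length instead. Branch points are skeleton pixels with
≥ 3 skeleton neighbours (8-connectivity); adjacent branch pixels merge
into one branch point (switchable via `merge_adjacent`), because raw
degree counting double-counts thick junctions while the quantity of
interest is the number of junction *points*. Normalised branch points =
branch count / skeleton length ∈ [0, 1]; an empty skeleton yields a
missing value, not zero — zero would claim "no branching", which is a
different statement from "nothing to measure".

## Aggregation indices

`DI = s0 · m_n / a_n` and `CDF = m0 / p_n` with the baseline reference
(s0, m0) fixed per series at its first imaged day; s0 defaults to the
day-1 mean object area so DI(day 1) = 1 exactly, and is user-settable.
In the pipeline the baseline is fixed per (well, FOV) series, so each
FOV is self-normalised before FOVs average into the well value. Both
indices are invariant to object relabelling and ordering. Degenerate
inputs (no somata, zero area or perimeter) yield missing values with a
logged warning rather than infinities.

## Region-based coherency

Coherency of an intensity patch is the eigenvalue contrast
`(λ1 − λ2)/(λ1 + λ2)` of the structure tensor, computed from image
gradients and Gaussian-smoothed with σ = 2 px (configurable). A
gradient-free patch is *defined* to have coherency 0 (the λ1 + λ2 = 0
limit). The value is invariant to global intensity scaling.

The region-based configuration measures only neurites near each soma:
an annulus of reach 30 px (≈ 18.6 µm at 0.62 µm/px) around each object
— implemented as a Euclidean-distance band, equivalent to disc dilation
— is divided into 8 angular sectors about the object centroid. A sector
is scored when ≥ 1% of its annulus pixels are neurite; its coherency is
the tensor averaged over those neurite pixels. Sector values average
unweighted per object, objects average into the image value. All three
geometry constants are configurable; they are declared defaults, not
fitted quantities.

Interpretation note: sector coherency measures *inter-fiber alignment
within the sector*. In very sparse cultures a sector often contains a
single neurite, which is locally coherent regardless of any bundling,
so the metric's response to fasciculation requires fiber densities at
which sectors typically see several neurites. The monotonicity tests
accordingly use a dense culture (18 somata × 5 neurites on 192² px);
at the sparse default density the metric saturates high and loses
contrast — a genuine property of region-local coherency, not an
implementation artifact.

For computational tractability the pipeline evaluates coherency on a
3×3 subset of FOVs uniformly spaced over the well mosaic, fixed across
days: for an axis of length n the picks are `floor((i + 0.5)·n/3)`,
i ∈ {0, 1, 2} — the centres of the axis thirds. Mosaics with < 9 FOVs
are used whole.

## Trajectories, death events, AUC

Per-well daily values are the mean over that well's FOVs (missing FOVs
ignored). Series are normalised by the first-day value; a zero baseline
marks the series missing. The death rule is strict: the first day d
with `(I_d − I_{d−1})/I_{d−1} < −0.10` (the threshold is configurable);
steps with a zero predecessor are skipped with a log note. The AUC is
the trapezoid over the *normalised* series at true day spacing — the
minimal-assumption quadrature, matching the piecewise-linear reading of
a trajectory plot — truncated before the death day (the culture is
non-viable at that timepoint; `include_death_day` flips the
convention). Fewer than two surviving points leave the AUC missing.

## Factorial statistics and network score

The design crosses medium (NB/BPI), laminin (mouse/human) and seeding
density (low/high). Factors are treatment-coded with references NB /
mouse / low, so each main-effect coefficient reads as the effect of
switching that factor on at reference levels of the others. The model
is OLS with the three main effects, the three two-way interactions, and
treatment-coded plate dummies as nuisance covariates; it requires ≥ 2
plates and a full-rank design (rank deficiency raises an error naming
the collinear terms). Benjamini–Hochberg runs across the six effect
p-values of each model. Note the step-up adjustment is monotone but not
idempotent — re-adjusting adjusted p-values inflates them — so only
monotonicity is asserted.

The network score ranks the 8 condition means of the CDF and coherency
AUCs (rank 1 = lowest mean; higher mean AUC ⇒ higher rank ⇒ more
mature network), sums the two ranks per condition, and uses the summed
rank as the score; ties share the mean rank, so genuinely tied
conditions share the top score. The score is invariant to any strictly
monotone transform of either metric's means.

## ROS assay arithmetic

For each FOV z-stack: per-pixel sum along z, restricted to the 2-D
nuclei-mask footprint (the mask applies to every slice — a projected
footprint convention), then the mean over masked pixels; divide by the
nuclei count; subtract the mean normalised intensity of the
negative-control wells. Nuclei are counted by Laplacian-of-Gaussian
blob detection at a fixed physical spot diameter (5.83 µm, converted by
the pixel size, 1.25 µm/px default); the image is pre-scaled to unit
maximum so the count is intensity-scale invariant. This is the same
operational definition as commercial fixed-diameter spot counting, in
an open implementation.

## Synthetic data generator

The generator emulates the phenomena the pipeline must quantify, with
every ground-truth parameter recorded:

- **Somata**: Gaussian-profile discs (profile σ equal to the radius, so
  the rim stays bright and the edge sharp — chosen so classical
  segmentation can recover the discs), radius ~ N(6, 1) px clipped at
  2, at continuous positions. Each day somata move a fraction
  `cluster_attraction` toward their cluster centroid (k-means-style
  assignment to evolving centroids, k ≈ n/4); discs overlapping ≥ 50%
  of the smaller disc merge with conserved area, so the soma count
  never increases and the summed perimeter trends down under
  aggregation (sub-pixel rasterisation can wobble it by a few edges).
- **Neurites**: quadratic Bézier tubes 2–3 px wide anchored to the
  parent soma rim, with an initial length of 30 px at the first imaged
  day (cultures are several days old when imaging starts) growing
  12 px/day by default. Orientations interpolate between isotropic on
  [0, π) and a single bundle direction as `fasciculation_strength` goes
  0 → 1; curvature shrinks with fasciculation since bundled tracts are
  straight. The per-pixel tangent orientation field is recorded.
- **Intensity**: soma amplitude 1000, neurite 600, background 20
  (arbitrary camera units); the whole frame decays multiplicatively by
  `bleach_rate` (default 5%) per day, a death event multiplies all
  later frames by `1 − death_drop`, and Gaussian read noise
  (σ = 2 by default) is added last. Death is frame-multiplicative
  because the death rule it feeds is intensity-based, not per-cell.
- **Determinism**: the generator is a pure function of its spec; one
  seed drives every draw, and all per-neurite randomness is drawn up
  front so geometry events (merges) never shift the random stream.
  Same spec ⇒ bit-identical TIFFs.

What the generator does *not* model: real photon/camera noise
statistics, uneven illumination, focus drift, debris, soma shape
irregularity, neurite thickness variation, or biophysical growth
dynamics. Passing tests therefore demonstrate the *pipeline's*
correctness and sensitivity under controlled conditions — recovery of
injected death days, factorial effects, aggregation and fasciculation
trends — not segmentation performance on real micrographs, which is
what the mask-ingestion path is for.

The factorial AUC generator draws well AUCs from the linear model with
specified coefficients, plate offsets and Gaussian noise under the same
0/1 coding the fitter uses, which makes parameter recovery an
end-to-end check of coding, fitting and inference together.

## Problem sizes used in tests

Synthetic fields are 160–192 px across with ~8–18 somata and 3–5-day
horizons; the determinism and smoke tests run a 2-condition,
1–2-well, 2–4-FOV micro-experiment. These sizes exercise every code
path (aggregation, merging, death, factorial stats) while keeping the
full suite fast; all scale linearly to real 1408×1040 tiles.
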