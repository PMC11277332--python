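# Methods

## Texture model

Texture is summarized by second-order statistics of the gray-level
co-occurrence matrix (GLCM) computed inside a segmented volume of interest
(VOI). The chain is:

**Quantization.** In-mask intensities (Hounsfield units) are binned into
L equal-width levels over the in-mask min–max range:
`level(v) = min(L−1, floor(L·(v−vmin)/(vmax−vmin)))`, default L = 128.
Min–max binning with a fixed level count makes every downstream feature
invariant under positive affine transforms of the raw intensities, which is
the intended behavior for scanner-calibration robustness, but it also means
the features are sensitive to single extreme-valued voxels, which stretch
the range and compress the tissue bulk into fewer levels. A constant VOI
maps to level 0 everywhere and raises a degenerate flag.

**Co-occurrence.** Pairs are counted slice-wise in 2-D. The axial slices
are 3 mm thick while in-plane pixels are ~0.6 mm, so 3-D offsets would mix
very different physical step lengths; restricting offsets to the axial
plane keeps the distance axis physically homogeneous. For each axial slice
intersecting the mask, ordered level pairs with both endpoints in-mask are
counted at the four in-plane directions (0°, 45°, 90°, 135°; diagonal
offsets are (±d, ±d) grid steps) at offset magnitude d ∈ {1,…,5}, in both
directions. Counts are pooled over all slices and angles into a single
matrix per distance and normalized by the total pair count. Pooling counts
(rather than averaging per-slice features) weights each slice by its number
of valid pairs and is robust for slices that barely intersect the mask; a
`per_slice_mean` mode exists behind a config flag. Pooling the four angles
makes the features exactly invariant under in-plane 90° rotations. A
per-angle hook (`angles=(0,)`) exists for testing against enumeration.

**Parameters.** Eleven statistics per matrix: uniformity (energy),
contrast, correlation, variance, homogeneity (inverse difference moment),
entropy, sum average, sum variance, sum entropy, difference variance,
difference entropy, using the symmetric-marginal mean μ (μx = μy by
symmetry) and the 0·log 0 = 0 convention. The logarithm is natural by
default and configurable; changing the base rescales the three entropies
and nothing else. Haralick-style variants differ on "variance"; here
variance = Σ(i−μ)²p(i,j) with μ the marginal mean. When the marginal
variance is zero (single occupied level) correlation is defined as 0 with a
degenerate flag so downstream rank statistics never receive NaN. A distance
with no valid voxel pair raises; during batch extraction it is filled with
convention zeros plus a flag so every patient carries 11 × 5 values.

## Distance reduction

Eleven parameters at five distances give 55 variables for 45 patients;
testing them all inflates the type-I error. Per parameter the 5×5 Spearman
matrix between distances is computed (midranks for ties; a constant column
is flagged and split out, as rank correlation is undefined). A distance is
split out iff its minimum correlation with the remaining distances falls
below ρ* = 0.8, applied iteratively worst-first: remove the distance with
the lowest minimum, recompute over the remainder, stop when all clear the
threshold or only two remain. Ties on the minimum are broken by the lower
mean correlation with the remainder — a rogue distance ties exactly with
its argmin partner on the minimum, but only the rogue is low against
everyone. The surviving distances are averaged per patient into
`<parameter>_M`; split distances stay as `<parameter>_q<k>`. The threshold
is a conventional collinearity screen, configurable and recorded in the
report; there is no universally agreed value for "highly correlated".

## Group comparison

Numeric variables (age + reduced features) are compared across the four
groups with the tie-corrected Kruskal–Wallis H (p from the χ² upper tail,
df = g−1). Variables significant at α = 0.05 get Dunn pairwise z-tests on
the pooled midranks (protected procedure; an ungated mode exists). Dunn
p-values are unadjusted by default, with Bonferroni and Holm available —
the unadjusted default mirrors the plain "followed by the Dunn test"
protocol; users wanting family-wise control should pass `dunn_adjust`.
Categorical manifest fields (sex, tissue, grade) are compared with the
Pearson chi-square test without continuity correction; expected counts
below 5 raise a warning flag rather than switching silently to an exact
test. Summary tables report median [min; max] and mean (sd), sd with the
n−1 denominator (0 with a flag for singleton groups).

## Synthetic cohort

The generator emulates a 45-patient cohort in four groups — BM
(bone/moderately differentiated, n = 5), SW (soft/well, 7), SM
(soft/moderate, 30), SP (soft/poor, 3) — as ellipsoidal VOIs (semi-axes
24×24×3 voxels) centered in 64×64×8 volumes with 0.625×0.625×3 mm spacing.
Voxel model per patient:

    base_hu + in-plane-smoothed white noise
            + 12 extreme-intensity anchor voxels (±400 HU, all groups)
            + sparse ±300 HU speckle on 2% of voxels (BM only)

The anchors emulate the extreme-intensity inclusions (contrast-filled
vessels, calcifications) that dominate the intensity range of real
contrast-enhanced lesions. They matter mechanically: min–max quantization
cancels pure amplitude scaling, so without a fixed range anchor the noise
amplitude would have no effect on the features and, with 128 levels and
~5×10⁴ pairs, the co-occurrence matrix would be sparsity-dominated and
entropy would saturate near log(pair count) for every group. With anchors
pinning the bin width, the fraction of the gray-level axis occupied by the
tissue bulk scales with the smoothed noise sd, and group heterogeneity is
controlled by two dials: noise amplitude (BM 110, SW 45, SM 38, SP 14 HU)
and in-plane smoothing width (BM 0.4, SW 0.8, SM 1.0, SP 1.5 voxels). The
BM speckle adds the high-contrast granularity expected of bone-sited
tumors. These defaults were calibrated once so the group medians order as
the analysis assumes — entropy BM > SW ≥ SM > SP, uniformity and
homogeneity reversed — robustly across seeds, and then frozen. The
no-noise limit (noise_sd = 0) skips anchors and speckle and yields an
exactly constant VOI (entropy 0, uniformity 1 downstream).

Ages are drawn uniformly over 33–93 years independently of group, so the
expected age "finding" is structurally null rather than tuned; sex is drawn
female with probability 0.87 as manifest metadata only. Everything is
reproducible from (config, seed); per-patient streams derive from the
cohort seed plus the patient index, so a patient's phantom does not depend
on cohort composition ahead of it.

What the generator does **not** emulate: CT physics (beam hardening, noise
correlation from reconstruction kernels), anatomy, segmentation error, or
the true effect sizes of the clinical cohort — only orderings and the
null-age structure. Passing tests therefore show that the pipeline detects
heterogeneity orderings of this kind at these sample sizes, not that the
clinical effect sizes are reproduced.

## Monte-Carlo problem sizes

The null type-I calibration regenerates a full cohort per seed, so it uses
a reduced geometry chosen for throughput: 20×20×4 volumes, 7×7×1.5-voxel
VOIs, 32 gray levels, distance 1 only, 2000 seeds. Under the null the
per-patient feature values are i.i.d. across groups whatever the geometry,
so the rank test's type-I error measured this way is the same operating
characteristic as at full size. Directionality recovery runs the default
geometry (all five distances, 128 levels) over 50 seeds. The numbered
analysis scripts use 500 null seeds; the test suite uses 2000.

## Numerical notes and limitations

- GLCM invariants (symmetry, normalization to 1e−9, non-negativity) are
  asserted by the `GLCM` type on every construction.
- Feature CSVs are written at full precision (`%.17g`) and read back with
  pandas' round-trip float parser, so write→read is bit-exact.
- DICOM series require RescaleSlope/Intercept (no silent default); missing
  inter-slice spacing falls back to SliceThickness with a logged warning.
  NIfTI intensities are taken as already in HU (scl_slope/inter applied).
- Volumes are reoriented to canonical axes on load; the axial slice axis is
  always the third array axis.
- Kruskal–Wallis, Dunn and chi-square are implemented from their defining
  formulas (and cross-checked against scipy in the test suite) because the
  Dunn test has no scipy equivalent and the three share the rank/tie
  machinery.
- The reduction rule is one defensible formalization of "highly
  correlated"; with a threshold above 1 it degenerates to splitting all but
  two distances, by construction.
- Small-sample caveat: with group sizes 5/7/30/3 the Dunn z approximation
  is coarse for the n = 3 group; p-values there are indicative only.
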