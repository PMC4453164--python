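# Methods

This note documents the models implemented in `spindlescreen`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Per-cell image analysis

**Nucleus segmentation.** The DNA channel is Gaussian-smoothed (σ = 2 px),
thresholded by Otsu's method, specks below 40 px² removed, and touching
nuclei split by a watershed on the Euclidean distance transform seeded at
distance peaks at least 7 px apart.  A blank or constant image yields zero
nuclei rather than an error.  The label count is the "total cell number"
feature.

**Mitotic gating.** A nucleus is mitotic when its mean PHH3 intensity
strictly exceeds a threshold.  With `phh3_threshold="auto"` the gate is
estimated per field as mean + 3·SD of the lower (interphase) mode of the
per-nucleus PHH3 means, the modes being separated by an Otsu split; at
least 10 nuclei are required for estimation, fewer is an error.  A fixed
numeric threshold can always be supplied instead.

**Cytoplasm segmentation.** Mitotic cytoplasm is grown from nucleus seeds
by a watershed on the smoothed RFP channel restricted to RFP-positive
pixels (Otsu); *all* nuclei act as seeds so neighbouring cells constrain
each other and masks are disjoint.  A mitotic nucleus without surrounding
RFP signal falls back to its own nucleus mask.

**QC.** Mitotic cells are excluded, in order and with strict inequalities,
when (1) the mask touches the field border, (2) roundness `4πA/P²` is below
0.8, or (3) mean tubulin over the mask is below 30 on the 8-bit intensity
scale.  The perimeter is the 4-direction Crofton estimate: close to the
true contour length for smooth masks (a digital disc scores ≈ 0.97) while
heavily penalizing the 1-px-thin fragments the roundness rule exists to
reject.  Every mitotic cell carries exactly one exclusion reason
(`none`/`edge`/`roundness`/`low_tubulin`), so kept + excluded = detected.

**Spindle-pole counting.** "Relative spot intensity" and "splitting
coefficient" are given concrete, scale-invariant definitions here:

1. smooth tubulin with a mask-normalized Gaussian (σ = 2 px) so signal
   outside the cell does not bleed in;
2. candidate poles are 8-connected local maxima inside the mask
   (out-of-mask neighbours ignored; equal-valued plateaus contribute their
   lexicographically smallest pixel);
3. keep candidates with relative spot intensity
   `r = (I_peak − bg)/(I_max − bg) > 0.095`, where `bg` is the median
   smoothed intensity over the mask and `I_max` its maximum;
4. merge insufficiently separated maxima: while any surviving pair's
   path minimum (bilinear samples at `ceil(2·d)+1` points along the
   straight segment) exceeds `0.56 ×` the dimmer peak's intensity, delete
   the dimmest such dim member (ties broken by position).

Both tests are ratios, so multiplying the channel by any positive constant
leaves the pole count unchanged, and translating the field translates pole
positions exactly.  A uniform cell yields zero poles; a mask smaller than
the smoothing kernel footprint yields zero poles with a warning; an empty
mask is an error.  Cells with more than two poles are multipolar.  Cells
with zero detected poles are retained (contributing zero to the mean pole
count) — exclusion happens only through the three QC rules above.  A
brute-force re-implementation of this exact definition serves as an oracle
in the test suite; the two agree exactly on every patch tried.

**Multinucleate cells.** Mitotic nuclei are excluded first.  Interphase
RFP bodies are connected components of the RFP mask united with the nucleus
masks (so orphan nuclei still form bodies); a body is multinucleate when it
contains ≥ 2 nuclei.  Bodies containing a mitotic nucleus are dropped;
bodies touching the border are flagged and left out of the denominator,
applying the same edge rule as for mitotic cells.

**Marker (e.g. HSET) spindle intensity.** Mitotic nuclei are selected by a
DNA-intensity threshold (condensed mitotic chromatin is brighter); the
spindle region is segmented by thresholding the marker channel in a window
around each such nucleus (Otsu, or a fixed threshold).  Mean and integrated
marker intensities are reported; a cell with no supra-threshold marker
signal is recorded as missing, not zero.

**Well summary.** `n_cells` counts all nuclei; `mitotic_index` =
mitotic/total nuclei; `pct_multipolar` and `mean_poles` are computed over
QC-kept mitotic cells; `pct_multinucleate` over non-edge interphase bodies.
Zero kept mitotic cells makes the two spindle features missing (NaN), and
missingness propagates to the gene tables with a warning rather than being
silently zero-filled.

## Screen statistics

**Normalization.** The reference population for Z-scores is all library
*sample* wells of the same plate (background × replicate), per feature —
controls are too few for a stable σ, and plate-wise normalization absorbs
between-plate batch drift.  Z-scores are computed per plate and then
averaged across the duplicate plates (not computed on averaged raw values);
`dZ = Z_NS − Z_chTOG` exactly, so swapping the background labels negates
every dZ.  A feature with zero spread on a plate is a named error.  A
median/MAD variant (`robust=True`) is available.

**Replicate agreement.** Spearman rank correlation with average ranks for
ties; p-values from the t-approximation, or from a permutation null for
small plates (automatically when n < 20).  Rank correlation is the right
tool here precisely because replicate plates can differ by a monotone
batch distortion that destroys Pearson agreement but preserves ranks.

**Hit calling** operates on raw `pct_multipolar`, not Z-scores: a gene's
mean across replicate plates must lie strictly more than `k = 1.5`
standard deviations from the mean of the individual control-siRNA wells
pooled across the two plates of that background (enhancer above,
suppressor below).  Two consequences worth knowing:

* On a single-replicate null screen the gene statistic and the control
  wells share one sampling distribution, so the rule flags
  `2·Φ(−1.5) ≈ 13.4%` of null genes (verified as a property test in the
  many-control-well limit).
* On a duplicate screen the replicate mean halves the gene-statistic
  variance while σ_ctrl keeps the full single-well spread — including any
  between-replicate batch component, which cancels in the gene-vs-control
  deviation.  Under the default generator conditions this puts the
  threshold at ≈ 3 gene-statistic SDs: planted ±3σ effects are recovered
  essentially always while well under 1% of null genes are flagged in
  expectation.  The false-positive rate fluctuates with the σ_ctrl
  estimate (48 control wells), so occasional screens exceed 1%.

**Hit-rate summaries** report suppressor/enhancer counts and
`100·(n_supp + n_enh)/library` to one decimal; `proportion` echoes simple
count ratios (integer-rounded for report-style summaries).

**Genetic-interaction score.** Phenotypes (% multipolar) are normalized to
the reference perturbation (`w = p/p_ref`, reference = 1); the
multiplicative expectation for the double perturbation is `w_A·w_B` and the
score is `ε = w_AB − w_A·w_B`, invariant to rescaling all four phenotypes.
Because severity is the normalized quantity, a double *less* severe than
expected scores negative and is classified alleviating below `−0.25`
(aggravating above `+0.25`; threshold configurable).  Published interaction
scores built on other normalizations can differ in sign and scale; only
the multiplicative-expectation structure is claimed here.

## Clustering

Genes enter the dZ matrix when `|Z_chTOG| > 1` for % multipolar or mean
poles/cell (strict; final averaged Z, not per-replicate).  Two metrics are
implemented: uncentred Pearson distance `1 − Σxy/√(Σx²·Σy²)` (default) and
city-block.  The default is uncentred Pearson because only there is the
similarity cut of 0.7 directly interpretable as `height ≤ 0.3` under
complete linkage; city-block is kept behind a flag with a free distance
cut.  dZ values are not rescaled before clustering.

Agglomeration is complete-linkage, implemented directly (O(n³), ample for
screen-sized gene sets) with a deterministic tie-break: among equally
distant pairs, the pair whose clusters hold the lowest original gene
indices merges first.  The merge list uses the scipy linkage layout and is
verified against exhaustive agglomeration for small n and against scipy on
tie-free data.  Flat clusters are the maximal subtrees with all merge
heights ≤ the cut; ids are contiguous from 1 in first-appearance order;
singletons are allowed.  A similarity cut of 1 separates everything except
exact duplicates; a cut of 0 disables the criterion (one cluster) — note
anti-correlated profiles have similarity < 0, so 0 is a floor on the cut
scale, not on similarity itself.  Raising the cut only refines the
partition, never merges clusters.  Trees export as Cluster-3.0 CDT/GTR
(GTR scores are similarities, `1 − height`) and Newick; re-reading the CDT
reproduces the matrix.

## Synthetic data

**Fields.** Cells are discs (default radius 26 px, roughly a rounded
mitotic HeLa cell at 20× magnification) placed without overlap; overlap
beyond the configured tolerance is a hard error because segmentation truth
would be ill-defined.  Interphase cells render 1–2+ nuclei as Gaussian
blobs (σ = 0.28·r) on a small ring; mitotic cells render one brighter,
tighter blob (condensed chromatin, σ = 0.20·r), matching PHH3 over the
same footprint.  RFP is a filled disc.  Tubulin is a diffuse anisotropic
Gaussian spindle body spanning the poles plus isotropic Gaussian foci
(σ = 2.5 px, amplitude 200) at the pole positions — peak-to-background
≈ 8× after the PSF, a regime where local-maxima counting is reliable but
noise and the merge rule are genuinely exercised.  Poles sit on a ring at
0.6·r with angular jitter bounded so that even six-pole rings stay above
the ~12 px merge-resolution of the default detector settings.  Channels
are blurred with a Gaussian PSF (σ = 1.2 px), offset by per-channel
backgrounds, and corrupted by Poisson shot noise (0.8 photons/intensity
unit) then Gaussian read noise (σ = 2.5); `eight_bit=True` clips and
rounds to 0–255 so absolute thresholds (the mean-tubulin 30 cut) act on
their native scale.  Rendering is 2-D: the screen's fields are analysed as
single planes, so no z-stacks, no 3-D PSF, no chromosomes/kinetochores, no
photobleaching or motion.  Everything is deterministic under the config
seed.

**Screen tables.** Per well: cell count ~ Poisson(1200); mitotic cells ~
Binomial(n, mitotic fraction) with baseline fractions 0.03 (NS) and 0.22
(ch-TOG) — about 36 and 260 mitotic cells per well, the regime of a
sensitized screen at 30 fields/well; multipolar mitotic cells ~
Binomial(penetrance), baseline penetrance 0.03 (NS) and 0.20 (ch-TOG, the
~20% multipolar level of incomplete ch-TOG depletion that allows both
suppressors and enhancers to register); pole counts of multipolar cells ~
3 + Poisson(mean − 3); multinucleate interphase cells ~ Binomial(0.03–
0.04).  Well-to-well penetrance noise is Gaussian (SD 0.03) and replicate
plates carry a multiplicative batch gain on penetrance (defaults 1.0 and
1.4), emulating day-to-day staining/imaging drift between duplicate
plates — the realistic feature that motivates rank-based replicate
correlation and plate-wise Z normalization, and that gives the control
wells their full between-plate spread.  Designated enhancers/suppressors
are planted at ±3× the analytically expected control-well SD (well noise +
binomial counting + batch components), converted back to penetrance units.
Per-cell and per-well truth tables are emitted alongside, and the well
features are exactly recomputable from the truth counts.

**What passing tests do and do not show.** The generators prove the
pipeline's internal correctness — segmentation, counting, scoring and
clustering recover known truth under controlled noise.  They do not
capture real-image pathologies: debris and staining artefacts, strongly
overlapping or apoptotic cells, intensity gradients within a field,
centrosome fragments, or out-of-focus planes.  Thresholds validated here
(PHH3 auto-gate, Otsu segmentation) would need re-tuning on real screens.

## Numerical conventions and limitations

* Coordinates are 0-based `(row, col)` pixel indices; all images are 2-D
  float arrays; masks are boolean.
* All threshold comparisons are strict (`>` / `<`), including QC cuts, the
  PHH3 gate, the spot-intensity gate, hit calling and the gene filter.
* Degenerate inputs: empty fields → zero nuclei; zero kept mitotic cells →
  missing spindle features; zero-spread plate features and all-zero dZ rows
  → named errors; empty gene filter → error (the end-to-end driver skips
  clustering with a warning instead of aborting the whole run).
* Benchmark problem sizes: pole recovery uses 200 mitotic cells per pole
  count condition (1–4 poles) plus two 100-mitotic-cell mixed wells at
  penetrance 0.25; hit recovery uses a 240-gene duplicate screen with 20
  enhancers and 10 suppressors; the null flag rate uses a 280-gene
  single-replicate screen with a 96-well control block.
* Pole counting resolves foci down to ~12 px separation at default
  settings; crowded 5–6-pole cells near that limit can merge, slightly
  biasing mean pole counts (never the multipolar call, which only needs
  "> 2").
* The screen scope is a single duplicate plate pair (NS + ch-TOG);
  multi-batch normalization across plate pairs is out of scope, as are
  multiple-testing control for hit calling and regression-based
  interaction models.
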