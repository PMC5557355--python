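# Methods

This note documents the models and procedures implemented in synaptoquant,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the conventions of
the field leave room.

## Image model and preprocessing

Images are nonnegative intensity arrays with square pixels (default
70 nm/pixel laterally; z-stacks at 0.5 μm steps).  The microscope blur is
modeled as an isotropic 2-D Gaussian point-spread function; the default
sigma of 0.055 μm gives a kernel FWHM of 2.355 σ ≈ 0.13 μm, matching the
lateral resolution of a deconvolved confocal image at this sampling.  No
optical model (NA, wavelength, aberrations) stands behind this kernel: the
Gaussian is a declared surrogate chosen because the downstream object
measurements depend only on the blur scale.

The conditioning chain runs, in order:

1. **Richardson–Lucy deconvolution**, applied per optical slice (the
   2-D kernel makes per-slice application exact for our image model).
   Iteration count defaults to 30, a common plateau for confocal puncta;
   `iterations=0` bypasses the step.  The estimate is not clipped, so
   intensity scales are preserved; flux over interior-supported signal is
   conserved to within 1%.
2. **Maximum-intensity z-projection.**
3. **Unsharp masking** in the standard high-boost form
   `out = clip(img + amount · (img − G_σ(img)), ≥ 0)`; `amount=0` is the
   identity and constants are fixed points.
4. **Outlier-pixel removal**: a pixel deviating from the median of its
   disk-shaped neighborhood (radius 2 px default) by more than a threshold
   is replaced by that median; bright-only by default, since hot pixels are
   the dominant camera artifact.

All stages preserve shape and nonnegativity.

## Puncta detection and synaptic pairing

Detection thresholds the preprocessed image (triangle method by default —
the one automatic method the workflow names; Otsu and fixed thresholds are
available), labels 8-connected components, and removes background in two
passes:

* one-pixel objects are always discarded;
* objects whose equivalent-circle diameter `2·sqrt(area/π)` falls below
  0.335 μm (an *apparent* diameter corresponding to a real diameter of
  roughly 0.2 μm after blurring) are discarded unless a finite
  signal-to-noise gate is configured and the object's SNR — mean intensity
  above the below-threshold background mean, in units of the background
  SD — reaches it.  The default gate is infinite, i.e. a pure size cutoff.
  (Note that with IEEE semantics `inf ≥ inf` would hold, so the gate is
  implemented as "keep small objects only when `snr_min` is finite and
  met".)

Pairing considers only puncta whose geometric centroid lies inside the
dendrite ROI polygon (point-in-polygon on the shapely predicate; overlap
pixels are deliberately not clipped to the ROI).  A red and a green object
form an overlap object when their pixel sets share **strictly more than
60 pixels**; at 70 nm/pixel that is 0.294 μm² (the often-quoted 0.25 μm² is
an approximation — the pixel rule is authoritative here).  A punctum is
*paired* if it participates in at least one overlap object and *single*
otherwise; participation in more than one is tallied separately as a
multisynaptic contact rather than double-counted.  Densities divide counts
by the ROI polygon area.  On images small enough to check exhaustively,
pairing is identical to brute-force pixel-set intersection over all object
pairs; pair counts are non-increasing in the overlap threshold and
symmetric under channel exchange.

Cluster-area distributions keep the raw per-object areas (for KS testing)
plus a fixed-bin-width histogram anchored at zero.  Fluorescence per cell
area divides the integrated signal by the pixel count of a mask obtained by
triangle-thresholding a separate structural channel, so a uniform signal of
value v over the mask reads out as v.

## Spine classification

Spines arrive as morphometric records; detection and measurement from
images (a proprietary tracing step in most workflows) is out of scope.
Records pass a filter (min spine diameter 0.1 μm, max length 3 μm; a
minimum dendrite diameter of 0.25 μm is carried in the configuration for
provenance) and are then labeled by the first satisfied rule among

    stubby:   length < 1  and  0.9 < min_width / mean_width(head) < 1.1
    mushroom: length < 3  and  mean_width(head) / max_width(neck) > 0.75
    thin:     mean_width(head) / length < 0.5

in the precedence **stubby → mushroom → thin**.  The rule regions overlap
(a short, wide-headed spine can satisfy all three), so precedence is part
of the model: stubby's conjunction is the most specific and sequential
rule application is how tracing software applies classifier rules.  The
precedence is configurable and recorded in outputs; spines satisfying no
rule are reported as *unclassified* rather than forced into a class.
Classification is a pure function — idempotent, permutation-invariant, and
checked for 100% concordance against an independent literal evaluation of
the predicates on 10,000 random records.

Densities are counts per μm of measured dendrite and therefore combine
across dendrite segments as (sum of counts)/(sum of lengths), not as a mean
of ratios.

## Arbor graphs and master junctions

A traced arbor is a 1-px-wide skeleton plus a soma mask.  Skeleton pixels
inside the soma are discarded; pixels 8-adjacent to the soma are attachment
points contracted into a single soma vertex, so primary dendrites are the
edges incident to it.  Graph vertices sit at pixels with ≠ 2 skeleton
neighbors; edges carry their pixel polylines with physical lengths (1 or
√2 × pixel size per step).  Complexity metrics are: **nodes** = junction
vertices (degree ≥ 3), **tips** = endpoints (degree 1, soma excluded),
**total length** = sum of edge lengths.  For strictly bifurcating trees
tips − nodes equals the number of primary dendrites.

Pruning to *master* segments and junctions removes terminal twigs shorter
than a threshold (default 2 μm), smallest first; a junction left with
degree 2 is merged away with its edge lengths summed, and removal iterates
to a fixed point.  Soma-attached segments are never removed.  The criterion
is the standard skeleton-cleanup rule; because the wording of such
procedures is also compatible with a single sweep, an alternative
"remove all leaf segments once" mode is provided.  Metrics are
non-increasing in the pruning threshold, and the pruned graph equals a full
re-derivation from the pruned pixel set.

The graph builder assumes a clean single-pixel skeleton (no thick junction
blobs); the synthetic generator guarantees this, and thinned real skeletons
should be inspected for junction clusters before trusting node counts.

## Statistics and qPCR

Group comparisons follow the conventional decision tree: a
D'Agostino–Pearson normality test on each group (valid only for n ≥ 8;
smaller groups force the nonparametric branch by policy) routes to one-way
ANOVA with Tukey HSD post-hoc, or Kruskal–Wallis (tie-corrected H) with
Dunn's post-hoc — z-tests on pooled mean ranks with tie correction,
Bonferroni-adjusted by default (Holm available); the adjustment family is
recorded in output metadata since conventions differ.  Post-hoc tests are
computed only when the omnibus p-value clears alpha (default 0.05).
Mann–Whitney U uses the exact null distribution for small untied samples
and the tie-corrected normal approximation otherwise; the two-sample KS
test reports D = sup|ECDF₁ − ECDF₂| with the asymptotic p-value (exact
small-n p-values are out of scope).  Calibration: over 10,000 null
simulations (three Gaussian groups of 20) both KW and ANOVA reject at
rates within [0.04, 0.06] at α = 0.05.

Relative expression uses the Livak model with implicit amplification
efficiency 2: ΔCt subtracts the housekeeping gene's mean Ct per condition
(technical-replicate means; whether to pool biological replicates instead
is a judgment call the tidy-table layout leaves to the user), ΔΔCt
subtracts the reference condition's mean ΔCt, and fold = 2^−ΔΔCt, so the
reference condition maps to 1 and higher expression gives fold > 1.  The
sign convention is stated explicitly because the exponent is frequently
printed without it.  Fold changes are invariant to any global Ct shift.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions for the whole package.

**Puncta fields** (defaults: 1024×1024 px at 70 nm/pixel, 200 puncta per
channel, spot radii 0.30–0.50 μm, amplitudes 80–150 photons over a
10-photon background, PSF σ 0.055 μm, Poisson shot noise plus 2-count
Gaussian read noise).  A chosen fraction of red/green couples is placed at
a 0.05 μm center offset so true pairs overlap after blurring; all unrelated
puncta keep a minimum separation of 4× the maximum radius so no accidental
pairs arise.  Spots are Gaussian by default (σ = nominal radius); a hard
disk mode exists for pixel-exact oracle tests.  Placement is rejection
sampling with bounded retries; an overcrowded spec raises rather than
degrades.  Not emulated: 3-D optical sectioning beyond independent slices,
chromatic shift, stage drift, uneven illumination, antibody background
texture, or clustered (non-Poisson) spatial statistics of real synapses.
Passing recovery tests therefore demonstrates correctness of the
measurement chain, not robustness to every real-world artifact.

**Trees** grow from a central soma disk along the 8 compass directions
(step 1 or √2 px), so rasterized skeletons are exactly one pixel wide and
every junction has degree 3.  Daughters turn ±45° from straight parents
and ±90° from diagonal parents — the unique turns whose first pixels are
not mutually 8-adjacent.  A daughter whose path would collide with drawn
structure (or the image border) is dropped and the bookkeeping reflects
what was drawn, so generative node/tip/length counts are an exact oracle.
Defaults (4 primaries, branch probability 0.7, segments 3–8 μm, depth 4,
0.16 μm/pixel) give arbors of a few hundred μm, the scale of immature
cultured neurons.  Not emulated: curved segments, variable branch angles,
self-crossings in projection, or soma irregularity.

**Spine tables** draw each morphometric independently and uniformly from
ranges spanning all classifier rule regions (lengths 0.3–3.5 μm, head
widths 0.1–1.0 μm, neck widths 0.05–0.8 μm, minimum widths 0.05–0.6 μm),
then label by literal rule evaluation — duplicated deliberately, and
independently of the classifier module, so the labels are an oracle.  Real
joint distributions of spine features are correlated; the uniform box is a
coverage choice, not a realism claim.

**Ct tables** plant fold changes via Ct(target, condition) =
Ct(target, reference) − log₂(fold) + ε with i.i.d. Gaussian well noise
(default SD 0.2 cycles, triplicate wells) and a condition-independent
housekeeping gene.  No amplification-efficiency variation or pipetting
covariance is modeled, consistent with the efficiency-2 assumption of the
2^−ΔΔCt readout.

All generators are deterministic given spec + seed, and each consuming
module recovers its generator's ground truth exactly in the noiseless
limit.

## Numerical choices and degenerate inputs

* Thresholding an empty image yields an empty object list, not an error;
  a degenerate (zero-area) ROI or an empty sample group is an error.
* Kruskal–Wallis on groups whose pooled values are all identical returns
  H = 0, p = 1 (the tie-corrected statistic is 0/0 there); ANOVA raises on
  zero pooled variance.
* Pruning ties (equal-length twigs) are broken by sorted vertex ids, so
  runs are reproducible.
* Punctum labels are assigned in raster order of each object's first
  pixel; all outputs are deterministic given config + seed.
* Equivalent-circle diameter applies the size cutoff to non-circular
  objects; rasterization makes the cutoff effectively act on the pixel
  count (e.g. 18 px at 70 nm/pixel).
* `inf` survives YAML round-trips as the string `"inf"` in configs.

## Problem sizes used by the validation runs

The test suite and the acceptance script size their simulations to run in a
few minutes on a single core: 100 brute-force pairing cases on 64×64
images, 50 full puncta fields (5 pairing fractions × 10 seeds, 200 puncta
per channel), 10,000 random spine records, 100 random trees, 10,000 null
simulations per omnibus test, 1,000 KS oracle pairs, and 1,000-replicate
noisy Ct tables.  These sizes give Monte-Carlo standard errors comfortably
below the asserted tolerances.

## Known limitations

* No image registration across channels; channels are assumed aligned.
* No 3-D colocalization metrics (Manders/Pearson) — the pairing model is
  object-overlap in 2-D projections, by design.
* The exact signal-to-noise statistic used by legacy interactive
  workflows is not standardized; the SNR gate here is defined, logged and
  off by default.
* Spine detection and neck/head measurement from images are out of scope;
  garbage morphometrics in, garbage classes out.
* The KS p-value is asymptotic and conservative for very small samples.
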