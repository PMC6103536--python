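# Methods

## Model and statistic

The data model is a binarized peak-by-cell matrix: entry (c, j) is 1 iff
open-chromatin region j is accessible in cell c (counts ≥ a threshold,
default 1, are scored accessible — single-cell ATAC signal is near-binary
and the package takes no position on diploid 2-counts beyond the
threshold). A *feature peak set* is any subset of the peak universe
sharing an annotation (TF binding, motif matches). Strand is ignored
throughout; accessibility is strandless.

**Raw variability.** Cells are compared by the angular cosine distance
d = arccos(cos θ)/(π/2), the angle between their binary vectors on the
feature's peaks normalized to [0, 1]. Cells that are all-zero on the
subset have no direction and are excluded (counted and reported); a
computation needs at least three usable cells. The full distance matrix
is embedded by classical scaling: B = −½·J·(D∘D)·J (Gower centering of
elementwise-squared distances), eigendecomposition of B, coordinates =
eigenvectors × √eigenvalues. Raw variability is the mean Euclidean norm
of the embedded cells — the centroid sits at the origin by construction.
Unlike the average pairwise distance, this centroid dispersion scales
linearly with the fraction of a population that deviates, which is what
makes the titration curve (below) concave rather than flat-topped.

Angular cosine distance matrices need not be Euclidean. Negative
eigenvalues are dropped and their relative mass (Σ|λ₋| / Σ|λ|) is
reported on the embedding; dropping them perturbs each *squared* pairwise
distance by at most 2·Σ|λ₋|, which is the tolerance the test suite
asserts. Squared-distance centering is used rather than centering D
itself because only then do Euclidean distances among the coordinates
reproduce the input distances — the property the method relies on when it
interprets the centroid distance on the same scale as the angles.

Numerical choices: cosines are computed as dot/√(‖a‖²‖b‖²) (dot products
of binary vectors are exact integers, so parallel cells get distance
exactly 0) and clamped to [−1, 1] before arccos; eigenvalues are retained
above 1e-9 × the largest; eigenvector signs are fixed (largest-magnitude
component positive) so embeddings are bit-reproducible, and the
dispersion statistic is sign-invariant regardless.

## Background matching and the final statistic

Raw dispersion depends on technical covariates of the peak set — above
all GC content and mean accessibility. Stage one draws, from the peaks
lacking the feature, background sets of the feature's cardinality,
matched **peak-for-peak on GC** (uniform draw without replacement inside
a ±0.02 GC window around each original peak; scarcest windows assigned
first, with restarts on collision dead-ends) and constrained so the
background set's **overall mean accessibility lies within ±0.01 of the
feature set's** (greedy swap repair after the GC draw; swaps stay inside
each peak's GC window). The set-level reading of the accessibility rule
is deliberate: with a 2,000-peak universe whose per-peak accessibilities
spread over [0.05, 0.5], at most a few dozen peaks can sit within ±0.01
of the feature mean, so requiring every single background peak to do so
is infeasible at any realistic feature size; matching the set mean
preserves the covariate being corrected while keeping the draw well
posed. The strict per-peak variant remains available
(`accessibility_match="per_peak"`), as does disabling the constraint
(`accessibility_tolerance=None`, used where mixtures shift accessibility
by design, e.g. model-2 benchmarks). Peaks with missing GC (all-N
sequence) are excluded from candidacy rather than imputed, and ambiguity
codes are excluded from the GC denominator (GC fraction of determined
bases).

bias_corrected = raw / mean(background raws), default 30 iterations.

Stage two draws negative controls: uniform random non-feature peak sets
of equal cardinality (no GC constraint — each control is itself
bias-corrected with its own GC-matched backgrounds, so its GC composition
is normalized internally; distinct controls may overlap one another).
final = bias_corrected / mean(control bias-corrected values). The
controls also yield a Z-score ((observed − mean)/sd, sample sd; reported
missing when the controls have zero spread) and two p-values: the
empirical add-one upper tail (1 + #{controls ≥ observed})/(n + 1) — the
primary value, since no parametric form is assumed — and the
normal-theory tail from the Z-score for comparison. With 30 controls the
smallest empirical p is 1/31 ≈ 0.032.

All randomness flows from one master seed through spawned per-iteration
streams, so increasing an iteration count never shifts earlier draws and
identical seeds give bit-identical results.

## Titration benchmark

Heterogeneity with a known ground truth is synthesized by mixing two peak
blocks across cells: an original block (uniform draw, default 500 peaks)
and a matched block (peak-for-peak GC-matched; model 1 from the full
remaining pool, model 2 from peaks above the 75th percentile of mean
accessibility — percentile computed on the full universe before excluding
the originals). At proportion p, the first round(p·n) cells contribute
their values at the original columns and the rest at the matched columns,
position-aligned; mixing peaks rather than cells keeps cell identities
and their confounders fixed. Subtype A uses the n highest-coverage cells
(default 100), subtype B the lowest (ties broken by cell id). The grid is
p = i/steps, i = 1..steps (default 50).

Per-point variability is bias-corrected by default (raw available). The
background normalization factor is estimated **once per curve** (30
GC-matched draws against the original block, evaluated on the same cells,
pool excluding both blocks, no accessibility constraint) and shared
across proportions: the background distribution does not depend on the
mixing proportion, so re-estimating it at every point would only add
iteration noise to the curve (measured directly: per-point re-estimation
depresses the concavity score from ≈0.93 to ≈0.8 on the desk-scale
fixture) and 50× the cost. A corollary is that the default curve is a
positive rescaling of the raw curve, so the concavity score is identical
between the two flavors.

Curve quality: the U statistic is the Spearman rank correlation
(midranks) of successive differences v_{i+1} − v_i with the decreasing
sequence (m−1, …, 1) — for the default 50-point curve, 49…1; curves whose
differences are all tied up to round-off (exactly linear or constant)
return missing rather than a noise-driven number. LOESS MSE is the mean
squared residual around a local polynomial fit: degree 2, tricube
weights, span 0.75 by default, evaluated at the observed points. No
installed Python library provides degree-2 tricube LOESS, so the fitter
is a small weighted-least-squares implementation; it reproduces exact
quadratics at span 1 and agrees with R's `loess(degree = 2, surface =
"direct")` to ~1e-8 on a frozen test dataset.

## Synthetic universes

The fixture generator emulates the statistical shape the method assumes:
independent Bernoulli accessibility per (cell, peak) with per-peak open
probabilities uniform on [0.05, 0.5], per-peak GC from a Beta(2, 2) bell
rescaled to [0.2, 0.8] (so GC matching is exercised nontrivially), and
synthetic non-overlapping BED coordinates on one pseudo-chromosome.
Defaults are 2,000 peaks × 200 cells, a desk-scale stand-in for the tens
of thousands of peaks in a real universe. Heterogeneity of intensity
h ∈ [0, 1] is injected into a peak block by redrawing it with the two
cell halves' accessibility mass shifted onto disjoint sub-blocks,
q = (1−h)·p + h·c·1[own sub-block] with c chosen so every cell's expected
block total is constant in h: at h = 1 the halves open disjoint peak sets
(cross-half distance exactly 1) without any total-accessibility signal —
heterogeneity invisible to aggregate-signal methods by construction.

What the fixture does **not** emulate: Tn5 insertion-sequence bias,
fragment-length structure, doublets, correlated peak co-accessibility, or
batch structure. Passing tests therefore demonstrate the estimator's
calibration and sensitivity under the stated sampling model, not
robustness to those real-data artifacts (the GC covariate is present in
the fixture but, unlike real data, is independent of accessibility).

## Problem sizes and expected results

The packaged checks run at deliberate desk scale: null calibration uses
the default 2,000 × 200 universe with 50 random 200-peak features and the
full 30 + 30 resampling design (mean final variation within ±0.05 of 1);
the titration uses 500-peak blocks, 100 cells, 50 steps across 10 seeds
(U ≥ 0.9, curve maximum within 0.1 of the 50 % mixture); the
heterogeneity dose-response uses a 1,000 × 120 universe, a 100-peak
block, h ∈ {0, 0.5, 1}, 10 replicates each (mean final strictly
increasing in h). Observed LOESS MSE of the default titration curve is a
few 10⁻⁷ on these sizes.

## Known limitations

- The full eigendecomposition is O(n³) in cells; thousands of cells are
  fine, hundreds of thousands are not (no landmark/approximate MDS).
- Matching needs a candidate pool several times the feature size; small
  universes or extreme-GC feature sets raise a typed "unmatchable peak"
  error rather than silently widening tolerances.
- p-values are per-feature; no multiple-testing correction is applied
  across feature sets.
- GC is computed on the peak interval exactly as given (no summit-window
  convention), and the ±0.01/±0.02 tolerances are fixed conventions, not
  fitted quantities.
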