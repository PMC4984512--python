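# Methods

## Species–area models and conventions

All regression happens in log–log space: the predictor is log₁₀ island
area (km²), the response log₁₀ species richness. Richness of islands
with no recorded species is transformed as log₁₀(S + 1) = 0 (log 0 is
undefined); islands with S ≥ 1 use log₁₀ S. Applying the +1 shift to
every island is available as a flag but is not the default, since it
biases the response of species-poor islands. Zero-richness islands are
always retained — dropping them is a classic source of spurious
small-island-effect detections. Base 10 is used for both axes, so
thresholds are directly interpretable as log₁₀ km².

The five candidate forms and their bracket-indicator equations are in
the README. Two conventions matter:

* Segment membership is half-open: lower segment log A ≤ T₁, middle
  T₁ < log A ≤ T₂, upper log A > T₂. A point exactly at a threshold
  belongs to the lower/middle segment.
* In the left-horizontal form with two thresholds the plateau
  intercept c₁ is an unconditional additive term, so the upper
  segment's literal value is c₁ + c₂ + z₂ log A. The fitter estimates
  the upper line b₀ + z₂ log A by ordinary least squares and stores
  c₂ = b₀ − c₁, keeping the reported parameters consistent with the
  equation as written.

K, the number of estimable parameters used by AIC, counts regression
coefficients plus thresholds plus one residual-variance parameter:
3 (power), 6 (two-slope), 4 (left-horizontal 1), 9 (three-slope),
7 (left-horizontal 2). Counting the thresholds and the variance is
deliberate — a break point estimated from the data consumes a degree
of freedom just as a slope does.

## Threshold search

Conditional on thresholds, every form is linear in its coefficients,
so fitting reduces to least squares:

* power: one OLS line;
* two-slope / three-slope: an independent OLS line per segment;
* left-horizontal 1: OLS of log S on {1, max(0, log A − T₁)} over all
  points (the hinge basis makes the plateau-and-ramp continuous at T₁);
* left-horizontal 2: the hinge fit restricted to points with
  log A ≤ T₂, plus an independent line above T₂.

The search layer then minimises RSS over candidate thresholds.
Continuous break points (the hinges) change the RSS as they slide
between observations, so they are scanned on an inclusive grid from
min log A to max log A in steps of 0.001 log₁₀ units. Discontinuous
break points only act through the induced partition, so their
candidates are the distinct observed log-area values (n distinct areas
give n − 1 candidates with both segments non-empty). The
two-threshold forms use the full two-level minimisation — outer loop
over the discontinuous candidate, inner loop over the other
threshold's candidates — which is exactly what a two-pass
record-the-inner-minimum-then-refine procedure converges to, without
order dependence. T₁ = T₂ is excluded; ties in RSS break toward the
smallest threshold(s), lexicographically for pairs.

A segment must contain at least `min_segment_points` observations
(default 3: a line plus one residual degree of freedom); infeasible
candidates are skipped, and a search with no feasible candidate
returns an explicit no-fit marker rather than raising.

Internally the segment fits use prefix sums of x, y, x², y², xy over
the area-sorted data, making each candidate's RSS O(1) and the whole
two-threshold search O(n²) vector operations; the grid scans are fully
vectorised. The RSS finally reported for the selected fit is
recomputed from residuals, which avoids the catastrophic cancellation
the prefix-sum shortcut can suffer on near-perfect fits.

## Likelihood, AIC, selection

The log-likelihood is the Gaussian profile form with the MLE variance
σ² = RSS/n:

  log L = −(n/2)(ln 2π + ln(RSS/n) + 1)

AIC = 2K − 2 log L, ΔAIC = AIC − min AIC, Akaike weights
ω = exp(−ΔAIC/2) normalised over candidates. Two numerical floors
protect the log: an absolute floor of 1e−300, and a relative floor of
1e−12 × TSS (total sum of squares of the response). RSS below the
relative floor is double-precision cancellation noise, not a real
lack-of-fit difference, so all such "perfect" fits share one floored
likelihood and AIC falls back to the K penalty — on noise-free or
constant data the most parsimonious perfect model wins, as it should.
Floored fits are flagged (`rss_floored`).

## NODF and null models

NODF scores every unordered pair of columns (and of rows): 0 if the
pair's marginal totals tie or the poorer one is empty, otherwise
100 × (shared presences)/(poorer total); the final score averages all
C(cols,2) + C(rows,2) pair scores. Defining "decreasing fill" through
the totals rather than positions makes the metric invariant to row and
column permutation; the canonical sort by decreasing marginal totals
changes presentation only. Zero-total rows and columns contribute 0 to
their pairs rather than being dropped.

Three null models of increasing constraint give the Monte-Carlo
reference distributions:

* **EE** re-places the observed number of presences uniformly without
  replacement — shape and total fill conserved, marginals free.
* **CC** fills cell (i, j) independently with probability
  ½(row fillᵢ + column fillⱼ) — a probabilistic intermediate
  preserving expected row/column fill. The exact algorithm behind the
  "cored–cored" label in the nestedness literature is not uniquely
  specified; this package uses the Bascompte-style cell-probability
  model, the common intermediate-constraint choice, and says so here
  prominently so results are interpreted against the right null.
* **FF** preserves both marginal-total vectors exactly, sampled by
  curveball trades (random row pairs exchange a shuffled subset of
  their non-shared columns). Defaults: burn-in 1000 × (rows + cols)
  trades, thinning 10 × (rows + cols) between ensemble draws from a
  single chain. These are generous for the matrix sizes at hand; both
  are configurable. A matrix whose rows are all full or empty admits a
  single configuration and is returned unchanged with a warning.

Null matrices are scored as generated — degenerate draws (empty rows)
are not resampled, which would bias the null.

Significance uses p = (1 + #{null NODF ≥ observed})/(1 + N), one-sided
toward nestedness with ties counted in the tail; a large p therefore
flags antinestedness. Because reported probabilities in the field do
not always state their tail, the lower-tail counterpart is always
reported alongside. Adaptive ensemble sizing grows the ensemble in
blocks of 100 until a 200-resample bootstrap 95% interval on p is
narrower than 0.02, capped at 10,000.

## Portion sampling

Each iteration draws a subset size n uniformly from {3, …, cols − 1}
(the full column set is excluded by construction), draws n distinct
columns, deletes all-zero rows, assigns NODF = 0 if the remaining
submatrix is filled wholly by ones, and otherwise scores NODF after
the canonical sort. The subset-size distribution is a package choice:
the procedure's published description fixes the range but not the
distribution, and uniform is the least informative option. The
histogram is binned on [0, 100] (50 bins) with density scaled to a
maximum of one. `enumerate_portions` applies the identical per-subset
computation to every subset of size 3 … cols − 1 (refusing above
2²⁰ subsets), giving an exact reference: a 12-island matrix has
Σₖ₌₃¹¹ C(12,k) = 4016 subsets.

Note that subsetting columns of a perfectly nested staircase can tie
row totals, so portions of a perfect nest do *not* all score 100; the
corner subset of the last three columns restores a 3×3 staircase and
does, which is why the enumeration maximum of a square staircase is
exactly 100.

## Synthetic data

`simulate_sar` draws log-areas uniformly on a configurable range
(default −4.4 … 5.0, i.e. ~4 × 10⁻⁵ to 10⁵ km², ten orders of
magnitude, matching archipelago-scale surveys) and adds Gaussian noise
in log-richness — the error structure the least-squares/AIC machinery
assumes. A `log_skewed` option (truncated exponential in log area)
mimics the strong right skew of real island-size distributions, which
matters because threshold recovery depends on point density near the
breaks. With `integerize`, the continuous response is rounded to
integer richness through 10^log S (floored at zero) and the
zero-island transform reapplied, reproducing survey-count
discreteness. What the generator does *not* emulate: spatial
autocorrelation, isolation effects, phylogenetic structure among
species, and observation error correlated with area — so passing
recovery tests demonstrate the estimator works under its own
assumptions, not that real archipelagos satisfy them.

`simulate_matrix` produces staircase (maximally nested; NODF 100 when
square, where strictly decreasing distinct marginals are possible),
uniform-random at a target fill, checkerboard (all marginals tied;
NODF 0 for even dimensions), and noise-degraded nested structures
(independent cell flips), all seeded.

## Problem sizes and defaults

Default problem sizes are chosen for desk-scale work: threshold
recovery is characterised on 50 replicates of 500 islands (the
recovery rate stabilises well before that), null ensembles default to
1000 draws, portion sampling to 10⁴ iterations with exact enumeration
taking over below 2²⁰ subsets. All are parameters, not limits; the
iteration counts used by large published analyses (up to 10¹⁰) are
reachable through the same configuration.

## Known limitations

* No confidence intervals on thresholds; the search returns the
  minimum-RSS point estimate only.
* AICc/BIC are not offered; with n per segment ≥ 3 and the K values at
  hand, AIC is the criterion implemented.
* The CC null is one of several algorithms answering to the
  "intermediate constraint" description (see above).
* Curveball sampling is asymptotically uniform; for pathological
  marginals with tiny configuration spaces the defaults still mix, but
  exact enumeration (provided for small matrices in the test oracles)
  is the gold standard there.
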