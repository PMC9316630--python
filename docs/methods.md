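# Methods

## Data model

An interval-valued dataset is an `n × J` matrix whose entries are closed
intervals, stored as centers `c_ij` and nonnegative radii `r_ij`
(`lower = c − r`, `upper = c + r`). Point data is the `r = 0` special
case. Constructors reject NaNs by default (an explicit
`drop_incomplete` policy drops and logs incomplete rows instead);
negative radii and inverted bounds are always errors, reported with the
offending cell. Conversions between the bounds and center/radius forms
are plain IEEE arithmetic and therefore exact only to one unit in the
last place of the bound magnitudes; the `center_radius` CSV dialect
writes the stored representation with `%.17g` and round-trips
bit-exactly (readers use round-trip float parsing).

## The overlapping-ratio distance

Per feature, `OR(I, I′) = |I ∩ I′| / |I|`; per observation pair, the
distance is the average over features and both directions of
`1 − OR`, so `D ∈ [0, 1]`, `D` is symmetric with zero diagonal, and
`S + D = 1` with the corresponding similarity. Because intersections and
widths rescale together, `D` is invariant under any per-feature map
`x ↦ a·x + b` with `a > 0`; this replaces feature standardization.

Degenerate (zero-width) intervals follow the `width → 0` limit:

* `OR(point, I′) = 1` if the point lies in the closed interval `I′`,
  else 0;
* `OR(I, point) = 0` whenever `|I| > 0` (the intersection has width 0);
* two points agree (`OR = 1`) iff equal.

Intersections are measured as widths of closed intervals, so *touching*
intervals (`[0,1]`, `[1,2]`) have `OR = 0` in both directions. These
rules keep the distance total on all valid inputs — real diagnostic
data does contain zero radii (26 cells of the 569-patient dataset).

**Saturation.** `D = 1` for *every* fully disjoint pair, however far
apart: the distance carries information only while intervals overlap.
Two consequences matter in practice. First, radii must be comparable to
the spacing between observations for the method to resolve structure;
when typical half-widths are much smaller than between-observation
gaps, most entries of the distance matrix equal 1 and complete linkage
degenerates into tie-breaking. Second, point data (`r = 0` everywhere)
reduces `D` to the fraction of unequal coordinates — constant 1 for
continuous data — so HC-ID on point data is *not* equivalent to
Euclidean hierarchical clustering on the same points, and no bounded
overlap-based rule can make it so (complete linkage is invariant under
monotone transforms of the dissimilarity, and this 0/1 distance is not a
monotone transform of the Euclidean one). The conventional baseline
exists precisely for that regime.

## Linkage

Agglomerative complete linkage on a precomputed distance matrix (the
engine never recomputes distances; the interval and Euclidean pipelines
share it). Conventions: leaves are numbered `1..n` and the cluster born
at step `t` is `n + t`; ties on the minimal inter-cluster distance are
broken by the lexicographically smallest id pair, making runs
deterministic; merge heights are non-decreasing (asserted). The update
is the Lance–Williams complete-linkage rule `d(a∪b, k) =
max(d(a,k), d(b,k))`, implemented as an `O(n³)` active-matrix scan —
exact and comfortably fast at the hundreds-of-observations scale this
package targets (the 569-observation analysis runs in about a second).
Flat partitions undo the last `k − 1` merges and relabel clusters
`1..k` by decreasing size (ties by smallest member), so cluster 1 is
always the majority cluster. Dendrograms export to Newick with branch
lengths `parent height − child height` (an ultrametric tree), to a merge
table, and to scipy's linkage format for plotting.

## Diagnostic evaluation

Evaluation is strictly post hoc: the clusterer never sees labels. Each
of the two clusters is mapped to the diagnosis class of its internal
majority; if both clusters have the same majority the accuracy-maximizing
one-to-one mapping is used and a warning raised (an uninformative
clustering then scores about the majority-class share). From the
resulting TP/FP/FN/TN:

* proportions (sensitivity, specificity, PPV, NPV, accuracy) use
  Clopper–Pearson exact 95% intervals (beta quantiles, closed at the
  0/1 boundaries);
* likelihood ratios use the log-method interval
  `exp(ln LR ± z·SE)` with `SE(ln LR+) = √(1/TP − 1/(TP+FN) + 1/FP −
  1/(FP+TN))` and the FN/TN analogue for LR−;
* if any cell is zero, all four cells get +0.5 (Haldane–Anscombe) before
  the likelihood ratios and their intervals are computed — this keeps
  LR+ finite when FP = 0 — while proportions always use raw counts;
* a measure with an empty margin is reported as NaN, never dropped.

Printed reports round to 3 decimals; internal values are full
precision. One rounding caveat: for the reference confusion matrix
130/34/82/323 the LR− point estimate is 0.42751, which prints here as
0.428 while tables that truncate print 0.427; the interval
(0.360, 0.508) is identical either way.

## Synthetic data

`generate(specs, seed)` draws, per group, centers from one multivariate
normal and radii from another, radii taken in absolute value (the
simplest way to keep half-widths nonnegative without reshaping the
distribution near zero). All draws flow from a single
`numpy.random.default_rng(seed)` stream: one seed pins the dataset.

Defaults of the stock designs, and why:

* `three_group_specs()` — 3 × 100 bivariate observations, group means on
  an equilateral triangle of side 6, unit center covariance, radii
  `|N(3.5, 0.3²)|` per axis. Separation of six within-group standard
  deviations makes the clouds visually disjoint. The radius scale is
  deliberately of the order of the within-group *diameter*: as derived
  above, overlap carries information only at that scale, and with these
  values HC-ID at `k = 3` recovers the partition (ARI ≥ 0.9) in 20/20
  seeds while much smaller radii (e.g. mean 0.4) drive the median ARI
  to ~0.04.
* `wdbc_like(n_pos=212, n_neg=357, separation=1.5)` — two unequal
  groups of ten positive lognormal-scale features (log-sd 0.3,
  equicorrelation 0.5; the malignant-like minority shifted up by
  `separation` log-sd), radii `center × |N(0.5, 0.05²)|` so larger
  measurements carry proportionally larger uncertainty. The 50%
  relative half-width again sits at the informative scale relative to
  the ~35% between-subject spread; at `separation = 4` the two groups
  are recovered with ARI > 0.9 in 20/20 seeds, and at `separation = 0`
  accuracy collapses to the majority-class share.

What the generators do *not* emulate: the real dataset's heavy-tailed
per-feature distributions, its se-type radii (typically a few percent
of the center, i.e. *below* the informative overlap scale), and
feature-specific correlation structure. Passing synthetic tests
therefore demonstrates the machinery and the method's behavior in its
informative regime, not that se-sized uncertainties suffice for
recovery on real measurements.

## Findings on the real diagnostic data

Run `python scripts/reproduce_wdbc.py` (the dataset ships with
scikit-learn; no download). Two results, both recomputed by the test
suite or that script:

* The conventional pipeline — unscaled Euclidean distances on the ten
  `worst` features, complete linkage, `k = 2` — reproduces the published
  conventional-approach evaluation *exactly*: predicted malignant
  proportion 2.99% (printed reference 2.98%) with confusion counts
  17/0/195/357, hence sensitivity 0.080, specificity 1.000 and
  LR+ 58.826 under the zero-cell correction. This validates the whole
  chain (loader, distances, linkage, cut, mapping, intervals) against an
  independent published computation, and settles the open question about
  standardization: the reference baseline used unscaled distances.
* The interval-valued pipeline as defined by the formulas above yields a
  predicted malignant proportion of 44.64% on the same data, where the
  published interval-valued analysis reports 28.82%. Systematic variants
  (unclipped intersection widths, Jaccard/Dice/product/norm
  combinations of the two directed ratios, doubled radii) do not
  reproduce that figure either; the original computation appears to
  differ in a detail not recoverable from its description. The
  discrepancy is reported openly rather than tuned away.

## Known limitations

* Saturation at `D = 1` for disjoint pairs (see above): no resolution
  between far-apart observations, and complete linkage on a saturated
  matrix is decided by tie-breaking.
* A single radius per cell assumes symmetric uncertainty around the
  center; asymmetric intervals must be pre-converted (any
  `[lower, upper]` input is accepted, but the metric only sees widths
  and positions, not provenance).
* The triangle inequality is not guaranteed for the OR distance and is
  not asserted anywhere.
* Diagnostic evaluation is defined for two clusters and binary truth
  only; `k > 2` cuts are clustering-only.
* Exact-tie merge order is deterministic but convention-dependent;
  partitions on tie-heavy inputs (e.g. all-zero radii) are sensitive to
  observation order in a way tie-free inputs are not.
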