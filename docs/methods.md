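# Methods

## The problem

Quantitative ethnobotany often asks which plant families contribute
*more* medicinally used species than their sheer size would predict.
Large families trivially contain many useful species; the interesting
signal is over-representation relative to family size.  This package
implements a three-way consensus test of family-level enrichment for a
flora summarised as per-family counts: `T`, the number of species of
the family recorded in the flora of a stratum (national or regional),
and `M`, the number of those species with at least one medicinal-use
citation.  Families with fewer than `min_family_size` species (default
10) are excluded before analysis to suppress small-sample noise.

## The three statistics

**Relative regression residual.**  An ordinary least-squares line of
`M` on `T` across families provides the null prediction
`P = slope·T + intercept`.  The statistic

    R = (O − P) / P

is the residual scaled by the prediction (`O = M` observed).  `R = 0`
is a perfect fit; `R = −1` means no medicinal species at all.  Values
inside a symmetric band (halfwidth 0.5 by default) are regarded as
noise; a family is flagged when the *unrounded* `R` strictly exceeds
the halfwidth.  Strict comparison on the unrounded value matters
because reported tables round to two decimals and a printed `0.50` can
sit on either side of the boundary.  The fit is always the package's
own OLS on the supplied table.  Predictions must be positive for `R` to
be defined; a family whose prediction is non-positive (possible for
tiny `T` under some fits) is returned as an invalid, unflagged result
rather than a silent number.

**Exact binomial upper tail.**  Under the proportional null each
species is medicinal independently with the flora-wide probability
`q = ΣM / ΣT` pooled over the *filtered* table, so a family's count is
`Binomial(T, q)`.  The reported probability is the upper tail

    p = P(X ≥ M) = (1 − CDF(M)) + PMF(M),

evaluated through the binomial survival function (`sf(M−1)`) so tails
below 1e-30 retain full relative precision.  A family is flagged when
`p < α` strictly (default 0.05).  No multiple-testing correction is
applied on the default path — the method is used here as a descriptive
screen, and corrected flags (Holm or Benjamini–Hochberg) are available
separately for analyses that need family-wise control.

**Beta-posterior credible interval.**  With a `Beta(a, b)` prior on the
family's medicinal proportion, the posterior after observing `M` of `T`
is `Beta(M + a, T − M + b)`.  The default prior is uniform
(`a = b = 1`); this choice reproduces published interval tables at both
extremes of family size, and with `T ≥ 10` the prior's influence is
minor.  The interval is equal-tailed (quantiles at `(1−level)/2` and
`1−(1−level)/2`), matching spreadsheet `BETA.INV` usage, not an HPD
interval.  A family is flagged when the interval's lower bound strictly
exceeds a flora-wide reference proportion.

The reference proportion has two modes.  `fixed` (default 0.2362)
replicates the published Thai national analysis.  `computed` derives
the reference from the data as the lower bound of the pooled posterior
`Beta(ΣM + a, ΣT − ΣM + b)` — the conservative choice for new
datasets.  A remark on the fixed constant: pooling the packaged
national table gives the posterior `Beta(2070, 7029)` with 95% interval
(0.2189, 0.2362); the published constant coincides with the pooled
interval's *upper* bound to four decimals, so the fixed default can be
read as "enriched families must clear even the upper end of the
flora-wide uncertainty".

**Consensus.**  The default rule flags a family as a Most Important
Medicinal Family (MIMF) only when all three methods agree.  The three
statistics have complementary biases — the residual favours large
families, the binomial and Bayesian rules are more sensitive in small
ones — and the intersection is what survives all of them.  `any` and
`per_method` rules are available for sensitivity tabulations.

## Strata and missing regional totals

Each stratum (the national pool or one of seven regional codes C, E, N,
NE, P, SE, SW) is analysed independently: its own OLS fit, its own
pooled `q`, its own threshold.  Regional species totals are sometimes
unknown; these are encoded explicitly (`total_species = None`, never
0), and resolved before analysis by substituting the national total for
the same family — a conservative choice that can only shrink the
regional proportion.  Substitution fails loudly if the family has no
national record or the substituted total would be exceeded by the
regional medicinal count.

## The packaged national table

The package ships a 115-family national table for Thailand (columns
`T` and `M`; ΣT = 9,097, ΣM = 2,069, all `T ≥ 10`), checksummed at load
time.  Published statistics derived from this table are reproduced by
the pipeline where the published source is internally consistent: the
credible-interval columns are matched for all 115 families within
0.0005, and the per-family binomial tails agree in rank and
significance.  Two published surfaces are *not* exactly recoverable
from the printed inputs: the published regression coefficients (and
hence a handful of borderline residual classifications) and the
published expected-count column correspond to a slightly different
count vector than the one printed — the printed `M` column pools to
2,069 whereas the published binomial columns imply a pool of 2,065, and
no OLS fit of the printed counts yields the published prediction
column.  The package always computes from the inputs it is given rather
than hard-coding unpublished coefficients, so its regression flag count
(18) and consensus count (16) on the packaged table differ from the
published 22 and 19 by exactly the borderline families affected.

## Synthetic data

The generator emulates the structure the analysis assumes, with
ground-truth labels for benchmarking:

- family sizes from a truncated lognormal (`μ = 3.0`, `σ = 1.2`,
  truncated to [10, 1200]), mimicking the heavy right tail of real
  floras (national range 10–1,099), or optionally a log-series;
- medicinal counts `Binomial(T, q_f)` with `q_f` the baseline
  proportion (default 0.227, the national pooled value) for null
  families;
- a designated enriched subset (default one sixth of families) whose
  *odds* of a species being medicinal are multiplied by an effect
  factor (default 3).  Acting on odds keeps `q_f` in (0, 1) without
  clipping (an explicit cap at 0.99 guards absurd effects) and makes
  effects compose multiplicatively;
- regional tables by binomial thinning of the national species pool
  (per-region retention probability) with hypergeometric medicinal
  counts among retained species, so `M ≤ T` holds by construction; a
  configurable fraction of regional totals is masked as unknown to
  exercise the substitution rule.

All draws come from one `numpy` generator seeded explicitly per call;
no global state.  What the generator does *not* emulate: citation-level
structure (informant × species use reports), taxonomic or phylogenetic
correlation of enrichment, and spatial correlation between regions
beyond the shared national pool.  Passing benchmarks on synthetic data
therefore demonstrates correct operating characteristics under the
model's own assumptions, not robustness to the biases of compiled
ethnobotanical surveys.

## Operating characteristics verified by the test suite

- binomial tails agree with explicit summation to 1e-6 relative
  (T ≤ 200); beta quantiles agree with CDF bisection to 1e-8;
- OLS agrees with the closed-form normal equations to 1e-10 relative;
- under a pure null (1,000 families, effect 1) the binomial flag rate
  stays below α + 3·SE — the discrete one-sided test is conservative;
- equal-tailed 95% intervals cover a true proportion 93–97% of the
  time for T ≥ 30 (uniform prior);
- with baseline 0.2 and a sixfold odds effect (enriched proportion
  0.6, T ≥ 50, 200 enriched of 1,000 families) every method's
  sensitivity exceeds 0.9.

Simulation sizes (1,000 families, single replicates at fixed seeds)
keep the full suite around five seconds while leaving comfortable
Monte-Carlo margins on each bound.

## Numerical choices

- Band and threshold comparisons are strict (`>`, `<`) on unrounded
  values; ties are not significant (`p = α` fails, `ci_low =
  threshold` fails, `R = halfwidth` is neutral).
- Display rounding (predictions and expected counts to integers,
  half away from zero; probabilities in `X.XXE-YY` scientific notation
  below 1e-3; interval bounds to 4 decimals) happens only in the
  serialisation layer; all decisions use unrounded values.
- `R² = 1 − SSres/SStot`, defined as 1 when the response is constant.
- Degenerate inputs raise typed errors: fewer than two families or
  constant `T` (regression), empty or all-zero tables (pooling),
  proportions outside (0, 1) (binomial test).

## Known limitations

- The OLS-of-counts null ignores heteroscedasticity (variance grows
  with `T`); the residual statistic inherits that known bias toward
  large families, which is precisely why the consensus rule exists.
- The binomial and Bayesian rules share the same pooled-proportion
  null and are strongly correlated; the consensus is effectively
  "regression ∧ (count-based pair)".
- `q` and the computed threshold are estimated from the same table
  being tested (as in the original method); for small strata this
  makes the tests slightly conservative for truly enriched families.
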