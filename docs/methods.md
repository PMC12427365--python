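# Methods

This note documents the statistical procedures `survscan` implements,
the conventions chosen where the field admits more than one, the design
of the synthetic-data generator, and the limitations of both.

## Survival core

**Kaplan–Meier.** The product-limit estimator is computed over distinct
*event* times only; times at which only censorings occur shrink
subsequent risk sets but add no step. The risk set at time $t$ contains
all samples with follow-up $\ge t$, so a sample censored exactly at an
event time is still at risk there (events before censorings at tied
instants — the standard convention).

**Log-rank test.** The unweighted two-group test with hypergeometric
variance; see the README for the formulas. Conventions: two-sided
p-value from the upper tail of $\chi^2_1$; no continuity correction, no
stratification, no Fleming–Harrington weights; variance terms at event
times with risk sets of size 1 are set to zero (0/0 guard); a zero total
variance yields statistic 0 and p = 1. The test suite checks both
estimators against lifelines on hundreds of randomized small instances
with ties and censoring (agreement within 1e-8) and verifies the null
rejection rate of a single test is nominal (n = 100 per group, 2,000
simulations, 99% binomial CI around 0.05).

## Min-p cutoff scan

Candidate cutoffs for a gene are the unique observed FPKM values `v`
with $P_{20} \le v \le P_{80}$, where percentiles use linear
interpolation between order statistics (the numpy default; at small n a
different percentile convention shifts the window, which is why the
convention is stated). The "high" group is `expression > cutoff`; the
`>=` rule is available via `ScanConfig.high_rule`. Cutoffs leaving
either group below `min_group_size` (default 2, so the log-rank variance
is defined) are dropped. Ties among equal minimal p-values resolve to
the smallest cutoff, making the scan fully deterministic.

Genes are excluded *before* testing when their median FPKM is below 1
(unexpressed), or when no valid candidate cutoff exists (degenerate,
e.g. constant expression). Exclusions are reported with their reason,
never silently dropped.

The scan is vectorized: per cohort, the distinct-event-time tables
($d_j$, $n_j$) are computed once; per gene, all candidate cutoffs are
evaluated simultaneously as a (cutoffs × samples) membership matrix with
cumulative-sum and segmented-reduction updates of $n_{1j}$ and $O_{1j}$.
A 1,000-gene, 349-sample cohort scans in a few seconds on one CPU. The
vectorized path is property-tested for exact agreement with the scalar
`logrank_test`.

**No multiplicity correction, by design.** The screening rule this
package reproduces reads the minimal p against raw thresholds (0.001
for discovery; 0.05/0.10 for two-cohort validation). The package
therefore ships a calibration module instead of a correction:
`null_scan_calibration` measures the null exceedance of best-p at
0.05/0.01/0.001 with Clopper–Pearson intervals. At the default window
and n = 349 the inflation at 0.05 is roughly 7× nominal. Permutation
("min-p adjusted") p-values are deliberately out of scope.

**A recovery subtlety.** Under perfect separation (high group dies
strictly first, no censoring), the minimal p is *not* guaranteed at the
exact separating cutoff: neighbouring splits have p-values of the same
order and the variance term can favour a split one sample off. The
recovery tests therefore assert partition recovery to within one sample.

## Two-cohort validation

Tier logic with strict inequalities: `both_significant` iff p < 0.05 in
both cohorts; `single_relaxed` iff exactly one p < 0.05 and the other
p < 0.10; `not_validated` otherwise. The outcome label (`Better` /
`Poorer`) comes from the discovery cohort's observed-vs-expected events
in the high-expression group at its best cutoff; disagreement between
cohorts is flagged (`direction_concordant`) rather than dropped. Genes
excluded in either cohort are omitted with a logged count. Records sort
by tier, then discovery p, then gene id.

Because tiers are computed from best-cutoff p-values, the dual-threshold
rule inherits the min-p inflation: in the seeded regression test
(discovery n = 349, validation n = 81, 480 null genes), ~24% of null
genes reach `both_significant ∪ single_relaxed`, while 100% of genes
with a planted hazard ratio of 3 do. Dual-cohort agreement raises the
bar but does not restore nominal error control.

## Specificity classifier

Categories and rules (fold = 5, detection threshold FPKM 1, both
configurable): NotDetected — all cancers below detection; Enriched — the
top cancer at least fold× every other cancer (and itself detected, a
configurable requirement); GroupEnriched — a group of 2–7 cancers whose
mean is at least fold× every non-member (and the mean detected);
Enhanced — some cancer at least fold× the mean over *all* cancers
(including itself — the literal reading of the rule); ExpressedInAll —
every cancer above detection; Mixed — the remainder. Fold comparisons
are computed by multiplication, never division, so zero-valued
comparison cancers satisfy the condition automatically.

**Precedence.** First match wins in the order NotDetected → Enriched →
GroupEnriched → Enhanced → ExpressedInAll → Mixed. Testing Enhanced
before ExpressedInAll follows the Human Protein Atlas convention this
taxonomy mirrors; under the naive listing order a gene detected in all
cancers could never be Enhanced. The listing order remains available via
`precedence="listed"`.

**Top-k search is exact.** For the GroupEnriched rule it suffices to
examine the groups formed by the k highest-expressing cancers,
k = 2..7: any other size-k group has a smaller-or-equal mean and a
larger-or-equal non-member maximum, so it cannot satisfy the rule unless
the top-k group does. The suite verifies this against brute-force
enumeration of all 2–7-subsets on hundreds of random genes.

**Reachability of Enhanced at small cancer counts.** With fold = 5 and
the precedence above, a gene can only be Enhanced if it escapes Enriched
(some second cancer above one fifth of the top value) and every
GroupEnriched group (via the fold condition or the group-mean detection
threshold). These escapes put a floor of about $1.2\,v_{\max}$ on the
sum over cancers, so the Enhanced condition
$v_{\max} \ge 5\,\overline{v}$ can only hold with slack up to roughly
$n/6$ for $n$ cancers. At $n \le 8$ the category is nearly unreachable
and cannot be planted with a 1.5× safety margin (cap ≈ 1.28); at the
17-cancer width the taxonomy is designed for, margins up to ~2.6 are
attainable. `simulate_pan_cancer` computes the cap and raises an
explanatory error for infeasible requests; the planting tests use
17 cancers at margin 1.5 and 8 cancers at margin 1.2.

## Synthetic-data generator

The generator's defaults mirror the discovery setting the screen is
meant for: n = 349 samples (validation cohorts use n = 81), 30% right
censoring, planted hazard ratio 3 (log_hr = ln 3) at the median (50th
percentile) cutoff. Expression is i.i.d. log-normal with log-mean 1 and
log-sd 1 — median FPKM ≈ 2.7, safely above the exclusion threshold, with
the right skew typical of FPKM data. The baseline hazard (0.02 per time
unit) is arbitrary since the pipeline is unit-agnostic.

**Planted effects share one risk partition.** Survival is a property of
the patient: one survival time is drawn per sample, and every gene is
screened against the same clinical table — which induces the realistic
positive dependence among genes' null min-p values. Prognostic genes are
planted through a latent per-sample risk indicator (hazard
$h_0 e^{\log HR}$ for the high-risk fraction); each planted gene's
log-normal draws are permuted so its top order statistics land on the
high-risk samples. Marginals stay log-normal (planted and null rows are
statistically indistinguishable one gene at a time), dichotomization at
the recorded `true_cutoff` reproduces the risk groups exactly, but
planted genes are mutually correlated — the unavoidable price of a
single patient-level outcome.

**Censoring** is administrative: a single censoring time is solved by
root-finding on the marginal survival function of the hazard mixture
(Weibull-generalized; shape 1 = exponential by default). The realized
censored fraction is then checked against the draw; if sampling noise
puts it more than 2.5 points off target the censoring time is
re-anchored at the empirical $(1-\text{target})$-quantile of the drawn
event times, keeping the realized fraction within the ±5-point contract
for every seed while remaining a pure function of the configuration.

**Pan-cancer planting** constructs each category to clear its defining
inequality by the requested multiplicative margin while *failing* every
earlier-precedence category, using near-equal group members, bounded
second maxima, and detection-threshold escapes as needed. Infeasible
requests (GroupEnriched with < 3 cancers; Enhanced beyond the slack cap;
Mixed with margins that collide the detected/undetected bands) raise
errors naming the constraint.

**What the generator does not emulate:** TCGA's actual marginal
distributions, batch structure, or gene–gene correlation beyond the
shared-survival construction; informative censoring; time-varying
hazards beyond the Weibull shape. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under its stated model, not
that real cohorts satisfy that model.

## Problem sizes used in tests

The suite runs the survival-core oracle comparison on 200 randomized
instances (n ≤ 30), null calibration with 2,000 log-rank simulations,
min-p inflation on one 1,000-gene × 349-sample null cohort (fractions at
0.05/0.01/0.001 pinned as seeded regressions), hazard-ratio recovery on
200 planted genes, specificity recovery on 60 planted genes, top-k
agreement on 500 random genes, and a two-cohort run with 500 genes per
cohort — sizes chosen to exercise the study-scale configurations while
keeping the full suite around a quarter of a minute of compute.

## Known limitations

* Best-cutoff p-values are selection-biased; they are screening scores,
  not calibrated error rates. Use the calibration module to interpret
  them.
* No Cox regression, no covariate adjustment, no competing risks; the
  pipeline models exactly one binary split per gene.
* The expression/clinical readers fail fast on missing values; no
  imputation is provided.
* The event-time indicator must be coded 1 = event, 0 = censored; the
  readers validate domain but cannot detect a flipped coding.
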