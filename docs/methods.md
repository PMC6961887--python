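# Methods

## qPCR calibration

A standard curve is an ordinary least-squares fit of threshold cycle on
log₁₀ input copies over a dilution series (typically 10²–10⁷ copies of a
full-length 16S amplicon from a reference organism), in the conventional
qPCR orientation Ct = intercept + slope·log₁₀(copies) with uniform
weights. The amplification efficiency is `E = 10^(−1/slope) − 1`; a slope
of −1/log₁₀2 ≈ −3.32 corresponds to perfect doubling (E = 100%), and
well-behaved 16S assays typically land between 91% and 98% (slopes around
−3.4 to −3.6). A fitted curve with non-negative slope is physically
meaningless; it is flagged invalid (with a warning) rather than dropped
silently, and refuses to quantify.

Sample quantification inverts the curve, `copies = 10^((Ct −
intercept)/slope)`, and scales to copies per gram of wet feces by the
extraction stoichiometry: the reaction holds `template_ng` of an eluate of
`dna_yield_ng` extracted from `feces_mass_g` grams, so `copies/g =
copies_rxn · (dna_yield_ng/template_ng) / feces_mass_g`. The eluate is
assumed to represent the whole aliquot; no extraction-efficiency
correction is applied.

### Replicate QC

Assays run in triplicate. Aggregation first drops non-detects (missing
Ct), counting them. A replicate is removed as a clear outlier when it
deviates from the mean of the others by more than `outlier_k` (default 2)
times their standard deviation. Two numerical guards make this rule
well-defined for triplicates: the standard deviation is floored at the
acceptable spread (0.5 Ct) — within a sample standard deviation of an
n = 3 set no point can exceed 2 SD, and without the floor the rule would
eject the extreme point of *any* evenly spaced triplicate — and at most
one replicate may be removed per set, requiring at least three finite
values. After removal, a surviving range above 0.5 Ct raises a spread
flag. Flags propagate into downstream tables as warnings; flagged samples
are reported, never excluded, because the acquisition protocol does not
prescribe exclusion.

Comparative-Ct quantification for functional genes (e.g. the
butyryl-CoA:acetate CoA-transferase gene) uses `fold = (1+E)^(Ct_ref −
Ct_target)`; the reference Ct is always supplied explicitly by the caller,
since the anchoring choice (reference sample vs reference gene) is a study
design decision.

## Quantitative profiling

Relative abundances are reads divided by per-sample totals; zero-read
samples are rejected by name, not imputed. An optional prevalence filter
removes taxa whose share of the grand-total read count is strictly below a
threshold (default 0.01%, the conventional cutoff for likely-erroneous
reads); it runs before normalization, and retained taxa are renormalized
over themselves (the filter is off by default in the library API and on by
default in the CLI pipeline). Absolute abundances are `A_st = r_st · T_s`,
which conserves the load: each sample's taxa sum to its qPCR total.

Copy-number correction divides by each taxon's genomic 16S copy number
(`c_t ≥ 1`), matched case-insensitively by exact name at the taxon's
finest classified rank. Because copy-number tables are incomplete, missing
taxa resolve by policy: `error` (strict), `table_mean` (default, with a
warning — silent omission would bias community sums), or `ancestor` (walk
up the lineage to the nearest rank with an entry). Correction changes the
unit state from `copies_per_g` to `genomes_per_g`; the two states are
tracked explicitly (and written into file headers) so mixed-unit
arithmetic fails loudly. The per-sample *total* load deliberately stays in
16S copies/g — only taxon abundances are corrected.

Rank aggregation sums values over taxa sharing a label at the requested
rank; taxa unclassified there are grouped under `unclassified_<parent>`.
Totals are conserved at every rank. Functional-group sums (e.g. the
dominant butyrate-producing genera Subdoligranulum, Faecalibacterium,
Anaerostipes, Butyrivibrio and Roseburia) report unmatched member names
rather than ignoring them.

## Differential-abundance testing

Abundances are count-like and right-skewed, and the right distribution
varies per taxon, so each taxon's model is chosen from its own data:

- zero fraction > 0.3 (configurable) → a zero-inflated family; the
  dispersion decision is then made on the non-zero observations so
  structural zeros do not masquerade as overdispersion;
- within a family, the Dean–Lawless/Cameron–Trivedi score test of Poisson
  equidispersion against Var = μ + αμ² (one-sided, level 0.05 by default)
  switches Poisson → negative binomial;
- fewer than 8 observations default to Poisson with a warning;
- a `lognormal` route (OLS on ln(x + pseudo-count)) serves continuous
  absolute abundances.

The 0.3 zero fraction and 0.05 test level are this package's
operationalization — the underlying guidance names the model families but
no decision rule — and both are exposed in `ModelSelectionRule`.

Fits are maximum likelihood via statsmodels (GLM-Poisson, NB2,
zero-inflated Poisson/NB2 with an intercept-only inflation component). The
reported effect is the binary intervention covariate's coefficient (a log
rate ratio) with a Wald test. Two calibration refinements apply:

- Wald statistics from ML fits are referred to a t distribution with
  residual degrees of freedom rather than the normal — the normal
  reference is anti-conservative in small samples when a dispersion
  parameter is estimated.
- For repeated-measures designs, passing `groups` (e.g. subject IDs)
  switches Poisson/NB fits to a cluster-robust sandwich covariance with a
  t(G−1) reference, G the number of clusters. This matters because NB
  maximum likelihood run alongside many subject fixed effects
  underestimates dispersion (an incidental-parameters effect we measured
  as ~10% null rejections at nominal 5%), whereas the sandwich variance is
  valid under arbitrary within-cluster correlation and overdispersion
  (measured null rejection ~4%).

Zero-inflated fits that fail to converge fall back to the uninflated
family, recorded in the result's notes; non-convergence is reported via a
flag, never an exception. Offsets are log totals, so count models can test
composition-style shares at varying sequencing depth; multiplying all
totals by a constant provably leaves the covariate coefficient unchanged.
Across taxa, p-values receive Benjamini–Hochberg q-values by default
(Bonferroni and none selectable); BH is delegated to statsmodels and
cross-checked in the test suite against a brute-force step-up oracle.

## The compositionality simulator

The generative model works in absolute abundance:

```
A[s,t,j] = exp(b_j + u_sj + e_stj) · (F if j = target and t in window)
```

with per-taxon lognormal baselines `b_j ~ N(log 1e9, 1)` (spanning roughly
three decades around a gut-like 10⁹/g), subject-by-taxon random effects
`u_sj ~ N(0, 0.5)`, residual noise `e_stj ~ N(0, 0.3)`, and a
multiplicative intervention effect F on a single target taxon during the
window. Defaults: 20 subjects × 6 timepoints (2 pre, 2 during, 2 post),
50,000 reads/sample, presets of 91 taxa ("complex", gut-like) and 10 taxa
("simple", low-diversity). These values are chosen to reproduce the
compositional phenomenon under realistic cohort dimensions, not any
specific dataset. Sequencing is emulated by row normalization plus
multinomial sampling at fixed depth; sequencing error, chimeras and
taxon-specific amplification bias are *not* modeled, so passing tests
demonstrate the compositional artifact and the estimators' calibration,
not robustness to those real-data complications.

One root seed drives everything; per-replicate generators are derived from
(seed, replicate, stream) tuples, so any replicate is reproducible
independently of execution order.

The false-positive experiment tests every taxon twice per replicate:

- **absolute space** — OLS on log abundances with subject fixed effects
  (exact under the generative model, so its rejection rate doubles as a
  self-check of the experiment's nominal level);
- **relative/count space** — Poisson quasi-likelihood on the multinomial
  counts with a log-depth offset, subject fixed effects, and
  cluster-robust (subject) standard errors, per the rationale above.

Non-target taxa are untouched by the intervention in absolute terms, so
any rejection among them is a false positive; the target's rejection rate
measures power. With the default 10-taxon community and a 4-fold effect,
the target holds ~10% of the community, the total load rises ~30% in the
window, and every other taxon's share drops by that factor — far larger
than the residual noise, which is why most non-target taxa test
"significantly negative" in relative space while the absolute-space rate
stays at α.

## Numerical and interface choices

- Exact-identity invariants (load conservation, unit-copy-number
  correction, curve inversion) hold to 1e−9 relative error and are tested
  at that tolerance.
- Files are UTF-8 TSV/CSV, `.` decimals, `NA` or empty for missing;
  lineages use the `k__;p__;…` convention; abundance files carry their
  unit state in a `# units:` header line. Writers and readers round-trip
  byte-stably, and pipeline outputs contain no timestamps, so reruns on
  identical inputs are byte-identical.
- Taxon-name matching is case-insensitive exact — no fuzzy matching, so
  every join is auditable.
- The pipeline never drops a sample or taxon silently: every exclusion
  and QC flag lands in `report.json` with a reason.

### Problem sizes

The Monte Carlo experiments run at sizes chosen to make their sampling
error small relative to the effects being measured: 200 replicates × 9
non-target taxa (1800 tests per space) for the false-positive rates, 1000
null replicates per model family for type-I error, 100 seeds at n = 500
per group for estimator recovery. Binomial 99% intervals at those sizes
are the acceptance bands used in the tests.

## Known limitations

- qPCR-based load shares the biases of any PCR method (primer coverage,
  amplification efficiency differences between the reference organism and
  the community, inhibitors); these are not modeled.
- The NB Wald test at n = 100 remains slightly anti-conservative (~6.7%
  measured at nominal 5%) even with the t reference; likelihood-ratio
  tests would tighten this at extra cost.
- The zero-inflation component is intercept-only; covariate-dependent
  zero inflation is out of scope.
- The simulator's subject effects are independent across taxa; real
  communities have correlated dynamics (shared environmental drivers),
  which would broaden both spaces' error rates.
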