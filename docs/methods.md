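# Methods

This note documents the models, estimators and numerical choices behind
`msydemog`, and what its synthetic-data tests do and do not establish
about real data.

## The setting

The data are haploid resequencing calls over a single non-recombining
locus (the X-degenerate MSY regions, L = 3,724,156 bp after depth
filtering) in samples of about n = 20 males per population. Because the
locus does not recombine, every population sample carries exactly one
genealogy; all inference rests on the shape of that genealogy as reflected
in the derived site frequency spectrum (SFS), in classical diversity
statistics, and in mutation counts along a phylogeny.

A generation time of 30 years converts between generations and years
throughout.

## Demographic models (simulator)

Five single-population histories are expressed, backwards in time, as
contiguous epochs of constant or exponentially changing haploid effective
size N(t):

| model | history (forward in time) | parameters and uniform priors |
|---|---|---|
| M1 | constant | N: 20–20,000 |
| M2 | ancient constant NA, reduction over LEX gens to NBOT, constant to present | NA: 1,001–20,000; NBOT: 20–1,000; LEX: 5–634; T2: 0–30 |
| M3 | as M2, then expansion from NER to NC over the last T2 gens | NA: 1,001–20,000; NER: 20–1,000; NC: 1,001–20,000 |
| M4 | as M2 with an expansion instead (NA small, NC large) | NA: 20–1,000; NC: 1,001–20,000 |
| M5 | expansion to NEE, then reduction to NC | NA: 20–1,000; NEE: 1,001–20,000; NC: 20–1,000 |

Sizes are haploid male effective numbers — the locus is uniparental, so no
ploidy scaling is applied. The onset of the first change is T1 = T2 + LEX,
a derived quantity, never sampled: the stated LEX and T2 priors jointly
respect the Last Glacial Maximum bound of ~666.7 generations (20 ky / 30 y),
which is the only reading under which the priors and the bound are
mutually consistent. "Exponential" change interpolates log-linearly in
size between the epoch's endpoint sizes, the standard constant-rate
meaning; the size function is therefore continuous across interior epoch
boundaries (a property test asserts this).

The per-site per-generation mutation rate is drawn once per simulated
dataset from Normal(3.01 × 10⁻⁸, 1.25 × 10⁻⁹) truncated at zero; the s.d.
is the stated 95% CI half-width (2.77–3.26 × 10⁻⁸) divided by 1.96.
Per-dataset drawing propagates rate uncertainty into the reference table.

### Coalescent engine

With k lineages at time t the pair-coalescence intensity is
k(k−1)/2 · 1/N(t). Waiting times are drawn by time rescaling with the
inverse cumulative intensity in closed form within each epoch — linear in
the constant case, exponential-integral in the growth case — carrying the
residual exponential deviate across epoch boundaries. Time is continuous;
there is no discretisation. Each replicate consumes its own
`SeedSequence`-spawned substream, making batches reproducible and
embarrassingly parallel in principle.

Mutations follow a finite-sites 4-state model without
transition/transversion bias: a Poisson(μ·L·total branch length) number of
hits, each assigned to a branch proportionally to length and to a uniform
position on [1, L]; a hit replaces the current base by one of the other
three with equal probability. Repeat hits at one position are resolved by
walking the tree root-to-tips applying hits oldest-first, so back
mutation and triallelism arise naturally at their (tiny) expected rates.
The derived SFS keeps biallelic sites only — sites fixed derived, or with
more than one derived base, are dropped, since an SFS category is defined
by a single derived allele count.

The simulator is validated against closed forms (E[T₂] = N,
E[TMRCA] = 2N(1−1/n), E[S] = θ·a₍n−1₎, E[ξᵢ] ∝ 1/i) and distributionally
against msprime (two-sample KS on TMRCA and S under matched constant and
exponential-growth scenarios), which never appears outside the tests.

## ABC

Summaries are the derived SFS restricted to the categories with at least
one observed polymorphic site (the mask comes from the observed data and
is applied identically to simulations), each retained category scaled by
its median absolute deviation across the reference table; zero-MAD
categories are left unscaled. Distances are Euclidean.

* **Rejection** keeps the n_accept nearest rows; boundary ties are broken
  by row order after a seeded shuffle.
* **Model choice** fits a multinomial logistic regression of the model
  label on scaled summaries over the kept rows and evaluates it at the
  observed summary. The fit is L2-regularised, which keeps it defined
  under perfect separation; a model absent from the kept rows is reported
  with probability zero and a warning. Rejection proportions serve as the
  cross-check.
* **Parameter adjustment** transforms each bounded parameter by
  logtan — y = ln tan(u·π/2) with u the position within the prior — and
  fits a weighted linear regression of y on the scaled summaries, with
  Epanechnikov weights 1 − (d/δ)² and bandwidth δ equal to the rejection
  tolerance. The adjusted sample is the fit at the observed summary plus
  residuals, back-transformed; the back-transform guarantees the posterior
  respects the prior support, with extreme values kept strictly inside the
  open interval rather than saturating in floating point. R² per parameter
  is the weighted fraction of variance explained; a singular design falls
  back to the unadjusted rejection posterior with a flag. Point estimates
  are reported as both the weighted median and a weighted-KDE mode, since
  either convention is found in practice; T1 is recomposed from the
  adjusted T2 and LEX samples rather than regressed directly.
* **Power analysis** simulates pseudo-observed datasets (pods) from each
  model's prior, runs model choice, and reports the confusion matrix of
  argmax decisions; **parameter recovery** reports the fraction of pods
  whose 95% equal-tailed credible interval covers the generating value.

### Problem sizes

The package defaults are deliberately scaled down from production sizes:
reference tables of 20,000 simulations per model with 1% acceptance
(200 rows), and 200 pods for power and coverage, keep a full validation
run in minutes on one core while preserving the acceptance fraction of
the 10,000-in-1,000,000 convention. All counts are plain arguments, so a
full-size run is a parameter change, not a code change. At these sizes
the validation run measures credible-interval coverage of ~0.94–0.95 for
M1's N and model-choice true-positive rates around 0.9 for a
well-separated constant-vs-expansion pair (constant N ~ U(500, 2,000)
against an expansion from U(50, 200) to U(5,000, 20,000), roughly
100-fold).

## Diversity statistics

* **S** counts sites with ≥ 2 distinct non-missing alleles. Missing calls
  are handled per site; pairwise differences are pairwise-complete without
  rescaling (the motivating call sets are ~99.8% complete, so the
  distinction is cosmetic there).
* **Singletons** are interpreted per individual: a singleton site has
  exactly one individual carrying a non-modal allele, the count is
  attributed to that carrier, and the median and sample s.d. are taken
  across individuals. This is the only reading that produces half-integer
  medians at even n and s.d. values exceeding the median, both of which
  occur in real cohort tables.
* **Tajima's D** uses the standard normalising constants
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); it is not computable at S = 0 and is
  reported as NaN there. An independently coded constant-by-constant
  oracle agrees to 10⁻¹⁰.
* **Fu's F_S** takes θ = π and computes S′ = P(K ≥ k_obs) under the Ewens
  sampling formula. Unsigned Stirling numbers of the first kind are
  generated by the recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| held in
  log space with log-sum-exp — naive products overflow by n ≈ 20 at
  realistic θ. F_S = ln(S′/(1−S′)); S′ = 1 (k_obs = 1) is reported as not
  computable. The Ewens machinery is checked against a Chinese-restaurant
  simulation of E[K] and the pmf's unit sum to 10⁻¹².
* **Significance** for D and F_S comes from a constant-size coalescent
  null conditioned on the observed S (fixed-S placement of infinite-sites
  mutations, multinomial over branch lengths), making the null free of θ;
  p is the lower-tail fraction of simulated statistics. Simulation-protocol
  differences relative to other implementations shift p-values slightly,
  so only the point statistics are comparable across tools.
* **Cline tests** are Pearson correlations with
  t = r√((m−2)/(1−r²)) and a two-sided t p-value (cross-checked against
  the closed-form CDF and scipy's own test).

## Rho dating

ρ of a clade is the mean over tips of summed branch mutation counts from
the clade root; sd follows the Saillard branch-weight estimator
sd² = Σ_b (n_b/n)²·l_b (the alternative ρ reference offers no variance, so
the branch-weight form governs). The scaled rate is 1/(μ·L) years per
mutation — 268.5 (246.3–291.9) for μ = 1.0 (0.92–1.09) × 10⁻⁹ and
L = 3,724,156 — reported at 0.1-year precision with the exact value
retained. TMRCA = ρ·rate is reported rounded to the nearest 10 years with
halves rounded up; that rule reproduces both 65 × 268.5 = 17,452.5 → 17,450
and 10 × 268.5 = 2,685 → 2,690, and unrounded values are always kept
alongside. Newick branch lengths are read as mutation counts; a missing
length is an error (silently zeroing a count would bias ρ downward), and
non-integer counts (consensus-tree averages) are accepted with a warning.

## What the synthetic data does and does not show

The generator emulates a single non-recombining haploid locus under
panmixia with the stated priors: no recombination, no migration or
population structure, no selection, no sequencing error or missingness,
and a uniform mutation rate along the locus. Passing tests therefore
demonstrate internal statistical correctness — the simulator matches
coalescent theory and an independent engine, the estimators match their
closed forms and oracles, ABC is calibrated under its own prior — but not
that any particular real population satisfies the modelling assumptions.
In particular, population structure inflates apparent effective-size
signals, and single-locus data intrinsically yield wide posteriors: the
T1 (onset-of-change) credible interval remains more than half as wide as
its prior interval in the scaled-down validation runs, so timing
conclusions should not be drawn from single-locus ABC alone.

## Numerical and degenerate-input conventions

* Epochs with zero width (T2 = 0) are omitted; the most ancient epoch is
  always constant.
* Exponential-epoch inversion uses the closed-form log expression; a rate
  numerically equal to zero degrades to the constant-epoch branch.
* logtan clamps inputs at machine-epsilon distance inside the bounds with
  a warning instead of returning infinities; its inverse clips the unit
  coordinate to the open interval.
* Rejection tolerance zero (exact duplicate of the observed vector) gives
  uniform regression weights.
* p-values and posterior probabilities are exact fractions of their
  finite samples; probabilities are renormalised to sum to one after the
  absent-model zero-fill.
* All stochastic entry points take either an integer seed or a
  `numpy.random.Generator`; batch operations spawn one substream per
  replicate from a root `SeedSequence`, and the pipeline manifest records
  the root seed plus sha256 digests of every input and output.

## Known limitations

* Single population, single locus: no migration, admixture or
  multi-locus composite likelihoods.
* The SFS discards triallelic sites rather than decomposing them; at
  MSY-realistic rates this loses a negligible fraction of sites.
* The fixed-S significance null mirrors one convention among several;
  p-values are not byte-comparable across tools.
* Haplogroup assignment itself (marker-based clade calling) is out of
  scope; `haplogroup_frequencies` tabulates externally provided
  assignments.
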