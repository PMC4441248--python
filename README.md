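# msydemog

Demographic inference from single-locus Y-chromosome resequencing data.

The male-specific region of the Y chromosome (MSY) is a single
non-recombining haploid locus, so a population sample of resequenced MSY
regions carries one genealogy whose shape reflects the history of the male
effective population size N<sub>e</sub>. `msydemog` provides the pieces
needed to exploit that signal for a cohort of ~20 males per population
sequenced over ~3.7 Mb:

* **Coalescent simulation** of haploid genealogies under five piecewise
  demographic models (constant size; bottleneck; bottleneck-then-expansion;
  expansion; expansion-then-reduction), with finite-sites 4-state mutation
  and priors bounded by the Last Glacial Maximum (~20 kya at 30 y per
  generation).
* **Approximate Bayesian computation (ABC)** on derived site-frequency-
  spectrum summaries: rejection sampling, multinomial logistic-regression
  model choice, and local-linear regression adjustment of parameters after
  a *logtan* transformation, with per-parameter R² and credible intervals,
  plus power analysis on pseudo-observed datasets.
* **Diversity statistics** per population: segregating sites *S*,
  per-individual singleton counts, Tajima's *D*, Fu's *F*<sub>S</sub>
  (via the Ewens sampling formula), coalescent-null p-values, and Pearson
  correlation of diversity with latitude/longitude.
* **Rho-statistic TMRCA dating** of clades in mutation-count trees:
  for a clade, &rho; is the mean number of mutations from the clade root to
  its tips; with a scaled rate of 1/(&mu;·L) years per mutation,
  TMRCA = &rho;/(&mu;·L), with the Saillard branch-weight standard
  deviation sd² = &Sigma;<sub>b</sub> (n<sub>b</sub>/n)²·l<sub>b</sub>.
* **Cohort I/O**: haploid multi-sample VCF ingest/export, call-set
  concordance (false positive/negative rates), and a reproducible
  pipeline driver with a JSON manifest.

The intended users are population geneticists analysing targeted
resequencing of uniparental loci, and anyone needing a compact, tested
reference implementation of single-population rejection/regression ABC.

## Worked example

Date a clade whose 13 tips each sit 65 mutations below the clade root,
using the scaled rate derived from 1.0 (0.92–1.09) × 10⁻⁹ mutations per
site per year over 3,724,156 bp:

```python
>>> from msydemog import parse_mutation_tree, rho, scaled_rate, tmrca_from_rho
>>> rate = scaled_rate(1.0e-9, 3_724_156, (0.92e-9, 1.09e-9))
>>> rate.years_per_mutation, rate.low, rate.high
(268.5, 246.3, 291.9)
>>> tree = parse_mutation_tree("(" + ",".join(f"t{i}:65" for i in range(13)) + ");")
>>> est = tmrca_from_rho(rho(tree), rate)
>>> est.reported
(17450.0, 16010.0, 18970.0)
```

So the clade's TMRCA is 17,450 years ago, with a 16,010–18,970 range
driven entirely by the mutation-rate confidence interval.

Simulate a reference table and fit ABC posteriors:

```python
>>> import numpy as np
>>> from msydemog import model_spec, simulate_batch
>>> from msydemog.abcfit import ABCPosterior
>>> spec = model_spec("M1")                       # constant N, U(20, 20000)
>>> table = simulate_batch(spec, 5000, n=20, seed=11)
>>> xi = [c for c in table.columns if c.startswith("xi_")]
>>> est = ABCPosterior(priors={"N": spec.priors["N"]}, n_accept=0.01)
>>> post = est.fit(table[xi], table[["N"]]).posterior(table[xi].iloc[0])["N"]
>>> round(post.median), round(post.ci_low), round(post.ci_high)  # doctest: +SKIP
(17635, 10975, 19734)
```

The posterior median sits near the generating value of that row
(N ≈ 17,811) and the 95% credible interval stays inside the prior support,
but remains wide — the expected behaviour for a single locus.

The same operations are exposed as a CLI
(`msydemog simulate | stats | correlate | rho | abc-fit | abc-power |
concordance | run`); `msydemog run --config run.yaml` executes an
end-to-end pipeline and writes a manifest with seeds and file digests.

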