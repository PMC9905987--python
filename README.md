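# phacksim

Monte-Carlo simulation of **p-hacking strategies** and their impact on
false-positive rates.

p-hacking is any measure a researcher applies to turn a non-significant
hypothesis-testing result significant by exploiting undisclosed analytic
flexibility. Because each extra undisclosed test adds another chance of a
type I error, the family-wise false-positive probability grows toward
1 − (1 − α)^m over m (independent) tests while the reported analysis still
claims level α. `phacksim` implements twelve such strategies as
reproducible simulators on synthetic null data (zero true effect, so every
significant result is false positive by construction), for the two designs
where these practices are most studied: the independent-samples *t* test
and univariate linear regression.

The package is aimed at meta-scientists, methodologists and instructors who
want to quantify how much a given practice inflates error rates, how
severity depends on the researcher's aggressiveness (number of tweaks) and
the data environment (correlation structure), and what proposed remedies
(α = 0.005, effect-size reporting, default Bayes factors) actually buy.

## The strategies

| label | strategy | design | aggressiveness knobs |
|-------|----------|--------|----------------------|
| s1 | selective reporting of the dependent variable | t test | k DVs, inter-DV correlation r |
| s2 | selective reporting of the independent variable | t test / regression | k IVs, correlation r |
| s3 | optional stopping (data peeking) | t test | N_min, N_max, step size |
| s4 | outlier exclusion (12 detection techniques, threshold escalation) | regression | k methods sampled |
| s5 | opportunistic covariate control | t test → ANCOVA | k covariates, r_Z, r_ZY |
| s6 | scale redefinition via alpha-if-item-deleted | regression | k items, r, max deletions m |
| s7 | variable transformation (log, reciprocal, √) | regression | targets, normality gate |
| s8 | discretization (median / tertile / cut-the-middle splits) | regression | — |
| s9 | alternative hypothesis tests (Welch, Wilcoxon, Yuen) | t test | trimming set |
| s10 | favourable imputation (10 missing-data methods) | regression | k methods, missingness ρ |
| s11 | subgroup analyses on incidental binary groupings | t test | k grouping variables |
| s12 | incorrect rounding of p-values | any | rounding level |

Each strategy consumes one synthetic null dataset and emits the ordered
list of candidate tests a researcher would have computed (planned analysis
first). A p-hacking attempt **succeeds** when any candidate p < α — which
makes the false-positive rate independent of the *reporting strategy*
(first significant / smallest / smallest significant p), a distinction the
package keeps explicit: reporting rules reshape the distribution of
reported p-values, effect sizes and p-curves, never the success rate.

Strategies can be chained into workflows (two built-in scenarios with
per-stage incorrect rounding), compared across significance thresholds with
common random numbers, and summarized through p-curves (ten 0.01-wide bins
over (0, 0.1]), Cohen's d / R² distributions, and the default JZS Bayes
factor for the two-sample t test (Cauchy(0, √2/2) prior on the
standardized effect).

## Worked example

```python
import phacksim as ph

res = ph.run_grid("s1", {"n": 50, "k_dv": [1, 3, 10], "r_dv": 0.3},
                  iterations=2000, seed=7, rules=("first_sig",))
print(res.table[["n", "k_dv", "r_dv", "fp_rate", "mc_se"]].to_string(index=False))
```

```
 n  k_dv  r_dv  fp_rate    mc_se
50     1   0.3   0.0405 0.004408
50     3   0.3   0.1385 0.007724
50    10   0.3   0.3425 0.010611
```

With one dependent variable the planned t test is calibrated (4.1% ≈ α);
picking the best of 10 outcomes correlated at r = 0.3 already yields a
false positive in a third of all null studies.

Chaining strategies on the same dataset (alternative tests, then 5 DVs at
r = 0.6, then 3 covariates, then 3 subgroup splits, with incorrect rounding
at p < 0.051 at every stage):

```python
wf = ph.run_workflow(ph.builtin_scenario("ttest"), iterations=2000, seed=7)
print(wf.table.to_string(index=False))
print("rounding share:", round(wf.rounding_share, 3))
```

```
 stage   label  cumulative_fp
     0 planned         0.0460
     1      s9         0.0645
     2      s1         0.1760
     3      s5         0.2010
     4     s11         0.3180
rounding share: 0.03
```

The cumulative rate climbs from 4.6% to 31.8%; 3% of the successes exist
only because of rounding. For the Bayesian mitigation check,
`ph.bf_jzs_ttest(0.0, 50, 50)` → `0.2108`: a null result at N = 50 per
group carries ~5:1 evidence for the null.

A CLI wraps the same machinery:

```bash
phacksim list                     # strategies, outlier & imputation rosters
phacksim grid --config cfg.yaml --out severity.csv
phacksim workflow --scenario regression --out workflow.csv
phacksim compare-alpha --config cfg.yaml --out alpha.csv
phacksim pcurve --pvalues ps.csv --out pcurve.csv
phacksim fixtures --out-dir fixtures/
```

## Further reading

`docs/methods.md` documents the simulation model, the declared outlier and
imputation rosters, numerical conventions, and known limitations.
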