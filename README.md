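# varaux

Design-based estimation of a finite-population variance under simple random
sampling without replacement (SRSWOR), using **dual auxiliary information**:
a correlated auxiliary variable *x* and the population ranks of *x*.

The package implements eight point estimators of `Sy²` (the usual sample
variance, ratio, difference, two-coefficient difference-type,
exponential-ratio, regression-exponential, dual-auxiliary
regression-exponential, and a ratio-in-regression exponential estimator with
dual auxiliary terms), together with:

- **moments** — ranks, mixed central moments `v_rst` (divisor N−1),
  scale-free moment ratios `lam_rst` and their starred versions
  `lam_rst − 1`, and the sampling factor `lam = 1/n − 1/N`;
- **estimators** — the eight sample-level estimators;
- **theory** — closed-form first-order bias / MSE / PRE for every estimator,
  optimal coefficients (published closed forms where sound, exact quadratic
  minimization elsewhere), and an exact 3×3 minimizer for the proposed
  estimator's MSE surface (the published minimum-MSE closed form is also
  exposed, flagged as inconsistent — it can go negative and does not match
  the minimum of its own quadratic);
- **efficiency** — the pairwise strict-inequality conditions under which the
  proposed estimator beats each competitor;
- **simulation** — reproducible bivariate-normal population generators
  (N = 5000; `x ~ N(5, 10)`, `y = x + N(2, 8)` or `x + N(1, 3)`), SRSWOR
  draws, and Monte-Carlo comparison of empirical vs first-order MSEs.

Two published summary-parameter blocks (N = 69 fish-abundance survey
populations) ship with the package, so all numerical comparisons run with no
external data.

## CLI

```sh
# first-order bias/MSE/PRE table on a bundled parameter set
varaux theory --fixture population1
varaux theory --fixture population1 --strict-printed   # literal published minimum

# the same from your own data (CSV with numeric columns y, x)
varaux summarize --population pop.csv --n 15
varaux theory --population pop.csv --n 15
varaux theory --params params.yaml                     # printed-parameter block

# pairwise efficiency conditions
varaux compare --fixture population2

# one SRSWOR draw and a point estimate
varaux estimate --population pop.csv --n 15 --seed 1 --estimator proposed

# Monte-Carlo study on a generated population
varaux simulate --population-id 2 --n 250 --replicates 10000 --seed 1
```

Global flag `--log-level INFO` logs the input source, design, seed,
coefficient provenance and any printed-formula inconsistency flags.
Identical configuration + seed yields byte-identical reports.

## API sketch

```python
import varaux as va

m, d = va.load_fixture("population1")      # MomentSet, DesignSpec
va.var_usual(m, d).mse                     # 4.725398e+14
va.mse_grover_kaur(m, d).pre               # 1018.52...
r = va.mse_proposed_exact(m, d)            # exact quadratic minimum
r.mse, r.coefficients.w8                   # 4.4158e+12, 0.8261

pop = va.generate_population(va.SimulationSpec(population_id=2, seed=1))
s = va.draw_srswor(pop, n=250, seed=2)
va.est_proposed(s, m.Sx2, m.Srx2, r.coefficients.w8,
                r.coefficients.w9, r.coefficients.w10)
```
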