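# gsacc

Predict the expected precision (reliability, squared accuracy) of genomic
estimated breeding values (GEBV) from breeding-scheme design parameters:
reference population size `N`, marker count `M`, heritability `h2`, and the
allele-frequency spectrum of the SNP panel.

The package provides

* **closed-form predictors** (`gsacc.closed_form`): the classic
  one-locus-at-a-time predictor and its error-variance-corrected root
  (`eq2`, `eq3`), first- and second-order Taylor approximations of the exact
  expectation (`eq5`, `eq6`, `eq7`, `eq8`), a single-shared-prior-variance
  variant (`eq9`), a Goddard-style comparator, and a marker-coverage
  adjustment;
* **allele-frequency laws** (`gsacc.freq_models`): uniform and U-shaped
  distributions on `[f_min, 1 - f_min]` with densities, exact inverse-CDF
  samplers and the moments `E[2f(1-f)]`, `E[1/(2f(1-f))]`;
* **Taylor machinery** (`gsacc.taylor_terms`): the expected diagonal of
  `D^-1 E D^-1 E` and the generic second-order precision for arbitrary
  shrinkage diagonals;
* **a validation simulator** (`gsacc.genomic_sim`): Hardy–Weinberg genotype
  panels in linkage equilibrium, the exact Monte-Carlo precision
  `1 - lambda tr[F E[(X'X + Lambda)^-1]]`, SNP-BLUP, and a full
  phenotype-level empirical precision;
* **a multi-trait generalisation** (`gsacc.multitrait`): first-order GEBV
  covariance `N Vg (N Vg + M Ve)^-1 Vg` and selection-index precision.

## CLI

```sh
# closed-form predictions over a design grid
gsacc predict --N 5000 --M 500 --h2 0.1,0.3,0.5,0.7 --fmin 0.05 --method eq2,eq3,eq5,eq7

# Monte-Carlo "true" precision for one scenario
gsacc simulate --N 5000 --M 500 --h2 0.3 --fmin 0.05 --dist uniform \
    --var-model equal --replicates 100 --seed 1

# reproduce the published validation grids (uniform / U-shaped frequencies)
gsacc table2 --replicates 100 --seed 1 --out table2.tsv
gsacc table3 --replicates 100 --seed 1 --out table3.tsv

# precision versus reference population size
gsacc sweep --N 1000,2000,5000,10000 --h2 0.3 --method eq2,eq5,eq7
```

All output is TSV on stdout or `--out`; logging goes to stderr
(`--log-level debug|info|warning`). `predict` also accepts a flat
key-value `--config` file; flags override file values.

## Notes

* Phenotypic variance is normalised to 1 throughout (`sigma_g^2 = h2`).
* `h2 = 1` (lambda = 0) is allowed and short-circuits the Taylor forms to 1.
* Monte-Carlo estimators spawn independent per-replicate sub-streams from
  the global seed, so results are replicate-order independent.
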