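# combatcor

Batch-effect correction for log-scale expression data, with downstream
differential-expression inference that accounts for the sample correlations
the correction itself creates.

## The problem

High-throughput expression studies are processed in batches, and batch
effects — systematic shifts and scale changes shared by samples run
together — must be removed before analysis. Two-step workflows (adjust the
data first, analyse the "clean" matrix afterwards) are popular because they
produce a corrected matrix usable by any downstream tool. But subtracting an
*estimated* batch mean ties every sample in a batch to every other one: the
corrected values are correlated. Analyses that treat them as independent
underestimate residual variation and report exaggerated significance —
dramatically so when the biological groups are spread unevenly across
batches. With scale (variance) batch effects the bias can flip sign and
*diminish* significance instead.

`combatcor` implements

* the empirical-Bayes **location/scale batch correction**
  (`combat_fit` / `combat_adjust`) for the model

  ```
  Y_ijg = alpha_g + X1 beta_g + gamma_ig + delta_ig * eps_ijg
  ```

  with normal priors on the per-batch shifts `gamma_ig` and inverse-gamma
  priors on the squared scales `delta_ig^2`, plus a mean-only regression
  adjuster (`meanonly_adjust`);

* the **induced correlation matrix** of two-step-adjusted samples,

  ```
  M = (I - H12)(I - H12)',
  H12 = X2 (X2' P1perp X2)^(-1) X2' P1perp,   P1perp = I - X1(X1'X1)^(-1)X1'
  ```

  which depends only on the group design `X1` (intercept + group indicators)
  and batch design `X2`, not on the genes. `M` is rank deficient (batch-mean
  removal kills `B - 1` directions), so its zero eigenvalues are replaced by
  `theta = zeta * (sum of retained eigenvalues)`; the noise fraction `zeta`
  is recommended in `[0.1/n, 1/n]` (`recommended_zeta_range`);

* **GLS differential expression** on the corrected data: whiten `X1` and
  each gene by the Cholesky factor of the repaired matrix `M~`, run OLS
  t-tests on the group coefficient with `n - rank([X1, X2])` residual
  degrees of freedom, and control FDR by Benjamini–Hochberg
  (`gls_de`, `combatcor_pipeline`);

* a **simulation and benchmarking layer** (`simulate_dataset`,
  `benchmark_grid`, `zeta_sweep`, `score`) that generates data from the
  hierarchical model above on stock unbalanced/balanced five-batch designs,
  with a matched batch-free benchmark, and measures FPR/TPR, discovery
  counts and observed FDR for every analysis route.

## Worked example

The stock unbalanced design has 57 samples in five batches with
cancer/control counts 11/0, 14/4, 0/4, 0/5 and 15/4 — group and batch are
heavily confounded.

```python
from combatcor import (SimScenario, balance_report, run_method, score,
                       simulate_dataset, unbalanced_design)

design = unbalanced_design()
print("balanced design?", balance_report(design).is_balanced)

scenario = SimScenario(design=design, mean_level="small", var_level="small", seed=1)
sim = simulate_dataset(scenario)   # 20,000 genes, 2,000 truly DE

naive = score(run_method("combat_naive", sim.Y, design), sim.truth)
aware = score(run_method("combatcor", sim.Y, design, zeta=0.01), sim.truth)

for m in (naive, aware):
    print(f"{m.method:>22}: FPR {m.fpr:.1%}  discoveries {m.n_discoveries}"
          f"  power {m.power_q:.1%}  observed FDR {m.observed_fdr:.1%}")
```

Output:

```
balanced design? False
          combat_naive: FPR 18.7%  discoveries 3297  power 99.2%  observed FDR 39.8%
  combatcor(zeta=0.01): FPR 5.9%  discoveries 2085  power 97.5%  observed FDR 6.5%
```

Reading: ordinary per-gene t-tests on the corrected matrix call 18.7% of the
18,000 null genes significant at alpha = 0.05 (nominal: 5%), and nearly 40%
of their q < 0.05 "discoveries" are false. Feeding the induced correlation
matrix into GLS restores the error rates while keeping power above 97%.

## Command line

`combatcor` exposes `correct`, `diffexp`, `simulate`, `benchmark` and
`zeta-sweep` subcommands over TSV/CSV matrices (genes x samples with a
`gene_id` column) and phenotype tables (`sample`, `group`, `batch`):

```sh
combatcor simulate --design unbalanced --n-genes 2000 --seed 1 --outdir sim/
combatcor correct  --expression sim/expression.tsv --phenotype sim/phenotype.tsv --outdir fit/
combatcor diffexp  --expression sim/expression.tsv --phenotype sim/phenotype.tsv \
                   --method combatcor --zeta 1% --outdir de/
```

Every run writes a `manifest.json` sufficient to reproduce it. Exit codes:
0 success, 2 input validation, 3 numerical failure (confounded design).

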