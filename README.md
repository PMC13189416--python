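# temponmf

Temporal decomposition of time-series bulk RNA-seq into metagene
**behaviors** by non-negative matrix factorization.

When a progenitor cell line is driven toward two fates — e.g. a
GCSF-conditioned neutrophil arm and an IL3 macrophage arm, sampled densely
after induction (hourly at first, then every 4 h, then every 8 h out to a
week) — most regulated genes change expression only *transiently*, in
pulses that endpoint-vs-endpoint differential expression never sees.
`temponmf` classifies genes by their entire trajectory instead: the
replicate-averaged, max-scaled gene × timepoint matrix X (GCSF block then
IL3 block) is factored as

    X_gt ≈ Σ_m W_gm · H_mt ,   W, H ≥ 0,  m = 1..M,

so each row of H is a shared temporal pattern (a behavior, interpretable
as a metagene's expression) and each gene is a non-negative mixture of a
few of them.  The package provides the full surrounding pipeline for
analysts of such time courses:

- **io_normalize** — expression/sample-sheet readers, median-of-ratios
  size factors, low-expression filtering (floor 5), replicate averaging,
  per-gene max-scaling, the two-condition sampling grid;
- **qc_outliers** — replicate outlier z-scores on top-4 PC scores,
  timepoint correlation matrices (1 − r distance), hierarchical clustering;
- **nmf_behaviors** — multiplicative-update NMF with the Frobenius-gap
  stopping rule, rank selection by successive-approximation RMSE, restart
  robustness analysis, cumulative per-gene reconstruction;
- **behavior_analysis** — dominant-behavior assignment, peak-based
  behavior ordering, display sorting, top-500 gene lists (expression floor
  3) for ontology tools, TF co-expression clustering, DEG-table filtering
  (padj < 0.05, |log2FC| > 0.58);
- **binding_enrichment** — TF-binding enrichment in proximal (±1 kb) and
  distal (±50 kb minus proximal) TSS windows with a one-sided Fisher's
  exact test;
- **synthetic_data** — a generator that emulates the study design
  (sampling grid, pulsatile behaviors, sparse weights, lognormal replicate
  noise, planted outliers, toy peak/TSS geometry) so the whole pipeline is
  testable without sequencing data;
- **cli** — a `temponmf` console script orchestrating the stages over a
  YAML config with a run manifest.

See `docs/methods.md` for the model, parameter meanings and numerical
choices.

## Worked example

Generate the default synthetic study (2,000 genes, 5 planted behaviors,
3 replicates, multiplicative noise CV 0.1), run the pipeline, choose the
rank, and check recovery:

```python
import numpy as np
from temponmf import synthetic_data as synth, io_normalize as ion, nmf_behaviors as nmf
from temponmf import behavior_analysis as ba

ds = synth.make_dataset(seed=20240101)
s = ion.size_factors(ds.expression)
filt = ion.filter_low_expressed(ion.normalize(ds.expression, s), floor=5.0)
tm = ion.average_replicates(filt, ds.sheet, share_baseline=False)
X = ion.max_scale(tm)
print(f"matrix: {X.values.shape[0]} genes x {X.values.shape[1]} timepoints "
      f"({X.n_gcsf} GCSF + {X.n_il3} IL3)")

res = nmf.sweep_M(X, range(2, 11), nmf.NMFConfig(seed=1000, theta=1e-4))
print("successive RMSE:", {m: round(v, 4) for m, v in res.rmse_successive.items()})
print("local minima:", res.local_minima)

model = nmf.fit(X, nmf.NMFConfig(M=5, seed=1, theta=1e-4))
frac, r = ba.dominant_recovery(model, ds)
print(f"behavior match r: {np.round(r, 3)}; dominant-behavior recovery: {100*frac:.1f}%")
```

prints

```
matrix: 2000 genes x 57 timepoints (29 GCSF + 28 IL3)
successive RMSE: {2: 0.1063, 3: 0.0687, 4: 0.0428, 5: 0.0057, 6: 0.0071, 7: 0.01, 8: 0.0119, 9: 0.0135}
local minima: [5]
behavior match r: [0.992 0.997 0.998 0.994 0.997]; dominant-behavior recovery: 100.0%
```

Reading the output: the RMSE between reconstructions at consecutive ranks
drops steeply until five behaviors are in the model and has its local
minimum at M = 5 — adding a sixth behavior changes the reconstruction
least there, identifying the planted rank (the exact minimum location
varies slightly with the initialization seed).  The converged rank-5 fit
recovers all five planted temporal patterns (Pearson r ≥ 0.99 after
matching) and assigns every dynamic gene its true dominant behavior.

The same analysis from the shell:

```sh
temponmf --outdir out --seed 1 all        # simulate + full pipeline
temponmf --outdir out fit --m 10 --theta 0.05
temponmf --outdir out sweep --m-min 2 --m-max 15
temponmf --outdir out robustness --runs 100
```

Each run writes its artifacts (W/H tables, sweep and robustness TSVs,
assignments, top-gene lists, enrichment report) plus a `manifest.json`
with the config echo, seed and input checksums.

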