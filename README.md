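# ecmap

Voxel-wise **eigenvector centrality mapping** (ECM) of fMRI runs, with
spatial ICA decomposition of the centrality maps, dual-regression task
GLMs, and component-wise and voxel-wise group inference.

## The scientific problem

Functional brain networks communicate through *hubs* — regions whose
connectivity makes them disproportionately influential. How hub importance
changes when a person engages a working-memory task, and how it matures
across late childhood and adolescence, are central questions in
developmental cognitive neuroscience. `ecmap` implements an analysis
chain for cohorts with two fMRI runs per subject (rest and an n-back
task):

1. **ECM.** For each run, build the graph on in-mask voxels with edge
   weights `|r_ij|` (absolute Pearson correlation of voxel time series —
   positive and negative connections weigh equally) and compute each
   voxel's eigenvector centrality: the leading eigenvector `x` of the
   nonnegative matrix `A`, `A x = λ x`, so a voxel is central when it is
   strongly connected to other central voxels. The V×V matrix is never
   materialized; blockwise products keep memory at O(block_rows × V).
2. **Spatial ICA.** Stack all runs' EC maps (runs × voxels) and decompose
   into K spatially independent component maps with per-run subject
   weights; canonicalize signs/order, exclude artifact components, and
   cluster components by weight correlation.
3. **Dual regression + GLM.** Extract per-component time series from the
   task runs by spatial regression and fit a block-design GLM (0/1/2-back,
   instructions, responses, double-gamma HRF). Task engagement is
   `(β₁ᵦ + β₂ᵦ)/2 − β₀ᵦ`; behavior is summarized by hit rate, false-alarm
   rate, and d′ = z(hit) − z(FA).
4. **Inference.** Per component: paired task effects on centrality, age
   effects, task×age interactions, behavioral associations, activation
   effects, and the centrality–activation correlation, all FDR-corrected
   (Benjamini–Hochberg, q = 0.05). Voxel-wise: the same contrasts with
   threshold-free cluster enhancement (TFCE, E = 0.5, H = 2) and
   permutation-based family-wise error control (max statistic over both
   signs).

Real developmental cohorts of this kind are access-restricted, so the
package ships a **synthetic-cohort generator** that plants known network
structure — a hub whose cross-network coupling rises under task and with
age and predicts d′, a sensory network suppressed under task, artifact
sources, and binomial in-scanner behavior — giving every pipeline stage a
ground truth to recover. See `docs/methods.md` for the model.

## Worked example

```python
from ecmap import (CohortConfig, PipelineConfig, run_pipeline)

config = PipelineConfig(
    out_dir="results/demo",
    synthetic=CohortConfig(n_subjects=12, grid_dims=(14, 14, 9),
                           k_networks=5, n_artifacts=2, seed=7),
    ica_k=9,
    n_perm=200,
)
bundle = run_pipeline(config)

hub_rows = bundle.stat_table.query("family == 'task_effect'")
print(hub_rows[["component", "t", "p", "q", "significant"]].head(3))
r, p, n = bundle.ec_activation
print(f"centrality-activation correlation: r={r:.2f} (p={p:.1e}, n={n})")
```

Output from this exact configuration:

```
   component         t         p         q  significant
0          0  3.319243  0.006840  0.020521         True
1          1  0.099898  0.922223  0.973882        False
2          4 -0.124291  0.903327  0.973882        False
centrality-activation correlation: r=0.65 (p=1.6e-01, n=6)
```

The first row says component 0's centrality is higher during the task than
at rest across the 12 subjects (paired t = 3.3, FDR-significant at
q = 0.05); the last line says components whose centrality rises under task
also tend to activate more — the coordinated connectivity/activation
pattern the planted cohort encodes (at n = 12 subjects and 6 retained
components the correlation is large but not yet significant; the
validation battery demonstrates it at n = 40). `results/demo/` holds the
EC maps, ICA maps and
weights, the full statistics table, clustering, and voxel-wise TFCE maps,
plus a provenance manifest; rerunning the same config reproduces every
output byte-identically.

The same pipeline runs from the shell:

```bash
ecmap run-all --config config.yaml          # or: simulate / ecm / decompose / stats / voxelwise
ecmap run-all --config config.yaml --seed 3 --n-perm 1000
```

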