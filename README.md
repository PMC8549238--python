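# dietnet

Dietary-network analysis for nutrition epidemiology: from a subjects ×
food-groups intake table (g/d) to sparse conditional-dependence networks,
overlapping food communities, per-subject dietary-pattern scores, and
obesity odds ratios across score tertiles.

Classic data-driven dietary-pattern methods (PCA, factor analysis, cluster
analysis) summarize intake but hide *which* foods are eaten in relation to
which. `dietnet` instead fits a Gaussian graphical model (GGM): the sparse
precision matrix Ω of the standardized intakes is estimated by the
graphical lasso,

    max over Ω ≻ 0 of  log det Ω − tr(SΩ) − λ Σ_{i≠j} |ω_ij|,

and edges carry partial correlations ρ_ij = −ω_ij/√(ω_ii ω_jj) — the
association between two food groups *given all others* (|ρ| ≥ 0.20 is
flagged strong). Overlapping link communities (edge clustering by
neighborhood Jaccard similarity, dendrogram cut at maximum partition
density) group the edges; connected assemblies of communities with ≥ 3
foods form dietary networks, each with a central food (the one in the most
communities). Subjects are scored on each network as Σ loading · z-intake
with first-principal-component loadings, scores are split into tertiles,
and logistic regression (crude and covariate-adjusted) estimates odds
ratios of general adiposity (BMI ≥ 30 kg/m²) and abdominal adiposity
(waist circumference or waist-to-hip ratio above sex-specific cutoffs)
across tertiles, with a P for trend.

Because cohort intake data are rarely public, the package ships a
synthetic-cohort generator with planted precision structure, realistic
covariates, and outcome effects tied to planted network scores, so the
whole pipeline is testable against a known ground truth. See
`docs/methods.md` for the full model description.

## Worked example

```python
from dietnet import compute_sample_size
from dietnet.pipeline import PipelineConfig, run_pipeline

# design-stage sample size: 65% expected prevalence, 4% margin, alpha 0.05
print(compute_sample_size(0.65, 0.04, 0.05))   # -> 546

cfg = PipelineConfig(synthetic={"n_subjects": 850}, outdir="run", seed=1)
bundle = run_pipeline(cfg)
m = bundle["manifest"]
print(f"lambda={m['lambda']:.4f} edges={m['n_edges']} "
      f"communities={m['n_communities']} D={m['partition_density']:.3f}")
# -> lambda=0.0805 edges=76 communities=16 D=0.789

t = bundle["association_table"]
print(t[(t.outcome == "central_whr") & (t.model == "adjusted")])
```

prints (three of the 18 rows per network):

```
  network     outcome    model tertile   n  odds_ratio  ci_low  ci_high  p_trend
network_1 central_whr adjusted      T1 284        1.00    1.00     1.00     0.71
network_1 central_whr adjusted      T2 283        0.94    0.67     1.33     0.71
network_1 central_whr adjusted      T3 283        0.94    0.66     1.32     0.71
```

Reading this: the EBIC-selected penalty (λ ≈ 0.08) kept 76 conditional-
dependence edges among the 35 food groups, which clustered into 16 link
communities at partition density 0.79; subjects in the top tertile of this
network's score had 0.94 times the odds of abdominal adiposity (WHR
definition) of the bottom tertile after covariate adjustment, with no
evidence of a monotone trend (P = 0.71) — as expected here, since this
synthetic run ties the WHR outcome to a different planted network.
`run/` contains every intermediate artifact (edge list, partial-correlation
matrix, communities, GraphML network export, scores, descriptive tables,
association table, manifest with seed and config hash).

The same stages are available from the shell:

```bash
dietnet simulate --n-subjects 850 --seed 1 --outdir cohort
dietnet preprocess cohort/grouped_intake.csv --out z.csv
dietnet ggm z.csv --edges-out edges.csv
dietnet communities edges.csv --out communities.json
dietnet run --seed 1 --outdir run       # full pipeline in one step
```

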