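# richnet

Longitudinal rich-club analysis of functional brain connectivity networks.

`richnet` is for researchers asking whether an intervention changes the
*rich-club organisation* of a subject's functional connectome — the dense
core of hub regions that carries much of the brain's integrative traffic —
and whether that change tracks clinical improvement. It takes two-session
(pre/post), two-group cohorts of ROI time series, builds thresholded
functional-connectivity networks, and runs the full chain of graph-theoretic
and nonparametric statistics that this study design calls for. A synthetic
cohort generator with a planted core effect makes every stage testable end
to end.

## The model

For each scan, functional connectivity between regions *i, j* is the Pearson
correlation `r_ij` of their time courses; edges are kept when they pass
family-wise error control (Bonferroni, `p < α/E` over the `E = n(n−1)/2`
edges, α = .05) and `r_ij > 0`, and keep `r_ij` as weight. Given an a-priori
rich-club node set *R* (default: 14 bilateral hub regions of the 90-region
AAL parcellation — dorsolateral superior frontal gyrus, insula, hippocampus,
precuneus, superior parietal gyrus, putamen, thalamus), every edge is

- **rich**: both endpoints in *R*,
- **feeder**: exactly one endpoint in *R*,
- **local**: neither endpoint in *R*,

and the three connectivity values are the weight sums per class, so that
rich + feeder + local = overall strength exactly. Alongside: global
efficiency `E_glob = <1/d_ij>`, small-worldness `σ = γ/λ` against
degree-preserving rewired nulls, nodal degree/strength/efficiency/
betweenness, two-tailed Wilcoxon signed-rank tests of every pre/post
contrast (exact for small n, FDR q < .05 across nodes for nodal metrics),
Spearman correlations of rich-club connectivity change against symptom-score
change, and a network-based statistic (NBS): edgewise paired t, primary
threshold t = 3, components sized in edges, max-component null from 5000
subject sign-flip permutations.

See `docs/methods.md` for the full account, defaults and limitations.

## Worked example

```python
import richnet as rn

cohort = rn.generate_cohort(rn.CohortSpec(seed=42))   # 90 regions, 14+15 subjects
model = rn.LongitudinalRichClubAnalysis(cohort, config=rn.AnalysisConfig(seed=0))
results = model.fit()
print(results.summary())
results.save("out/")   # report.json + TSV tables, byte-identical on re-run
```

prints (abridged):

```
Group: treatment  (n = 14)
  Wilcoxon signed-rank, post vs pre (two-tailed):
    overall_strength     W =     0.00   p = 0.0011   (n = 14, approx)
    rich_connectivity    W =     0.00   p = 0.0011   (n = 14, approx)
    feeder_connectivity  W =    41.00   p = 0.4899   (n = 14, approx)
    local_connectivity   W =    45.00   p = 0.6603   (n = 14, approx)
  NBS: largest component 98 edges, p = 0.0002  (5000 permutations, t > 3 positive)

Group: no-treatment  (n = 15)
    rich_connectivity    W =    56.00   p = 0.8424   (n = 15, approx)
  NBS: largest component 8 edges, p = 0.3593  (5000 permutations, t > 3 positive)

Spearman: rich-club connectivity change vs score change (treatment group)
    madrs    rho = -0.886   p = 0.0000   (n = 14)
    mcsds    rho = -0.477   p = 0.0846   (n = 14)
```

Reading this: the generator planted a +0.15 correlation increase on the
14-node core for the treatment group's post session, and the pipeline
recovers exactly the expected pattern — rich-club connectivity rises
significantly in the treatment group only, feeder/local connectivity are
unchanged, the NBS isolates one large strengthened subnetwork, and subjects
whose rich-club connectivity rose most show the largest MADRS-like score
drops (negative Spearman rho).

The same pipeline runs from files: `richnet simulate --out cohort/ --seed 1`
writes per-scan TSVs plus a manifest, and `richnet run-all --config
analysis.yaml` (or `run_longitudinal_analysis(AnalysisConfig(manifest=...))`)
analyses any cohort in that layout. Per-stage subcommands (`fc`, `metrics`,
`richclub`, `nbs`) operate on single files.

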