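# crossclust

Joint analysis of gut-microbiome genus abundances and fecal NMR
metabolites by **spectral co-clustering of their cross-omic Spearman
correlation matrix**.

Microbiome–metabolome studies routinely produce two paired tables per
cohort: 16S-derived genus counts and NMR-derived metabolite abundances.
The question is which *subsets* of genera and metabolites co-vary — e.g.
which bacteria travel with the short-chain fatty acids, and how those
groups respond to diet. `crossclust` answers it with a tested,
reproducible pipeline:

1. **Prevalence filtering** — genera detected at ≥ 0.1 % relative
   abundance in ≥ 10 % of samples are kept (metabolites: detected as > 0
   in ≥ 10 % of samples), with per-sample data-loss and per-phylum shift
   accounting.
2. **Compositional transform** — a +1 pseudocount followed by the
   centered log-ratio (clr) transform,
   `clr(x)_j = ln x_j − (1/D) Σ_d ln x_d`,
   so genus abundances enter correlation free of closure effects.
3. **Cross-omic correlation** — Spearman's ρ between every raw
   metabolite and every clr genus, giving an *m × n* matrix *A*.
4. **Bipartite spectral co-clustering** (Dhillon's normalized-cut
   partitioning): shift *A* to nonnegative values (r → (r+1)/2), form
   `A_n = D₁^{−1/2} A′ D₂^{−1/2}`, embed rows and columns with the
   singular vectors u₂…u_{l+1}, v₂…v_{l+1} (l = ⌈log₂ k⌉), and jointly
   k-means the stacked embedding `Z = [D₁^{−1/2}U_l ; D₂^{−1/2}V_l]`.
   Every metabolite and every genus lands in exactly one of *k*
   biclusters; the number of biclusters is selected by scanning k with
   Silhouette and Calinski–Harabasz scores on both axes.
5. **Summaries and inference** — per-sample bicluster abundances (raw
   sums for metabolites; clr of within-bicluster relative-abundance sums
   for genera), log₂ fold changes and Mann–Whitney U contrasts between
   diet groups, Spearman heatmaps against external biomarkers, PCA
   ordinations with 95 % group ellipses, and optional cross-validated
   gradient-boosted classification of the diet factors.

A synthetic generator plants coupled genus–metabolite blocks behind a
2×2 diet design (high/low fat × prebiotic supplement, n = 10/group, 226
genera of which ~66 survive the filter, 38 metabolites, 5 blocks), so
every stage is testable end-to-end without external data, and recovery
of the planted structure is measured with the adjusted Rand index.

## Worked example

```python
from crossclust import simulate, CrossOmicsCocluster

counts, mets, design, bio, truth = simulate.generate(
    simulate.SimConfig(sigma=0.05, seed=1))
res = CrossOmicsCocluster(counts, mets, design, biomarkers=bio).fit(
    k_grid=range(2, 11), seed=1)
print(res.summary())
```

```
Cross-omic spectral co-clustering
==============================================
samples                      40
genera in / kept            226 / 66
metabolites in / kept        38 / 38
mean data loss (genera)     0.106 %
pseudocount max shift      0.0426 pp
biclusters (k)                5  (data-driven)
shift mode                 half
seed                          1
----------------------------------------------
bicluster   metabolites   genera
        0            11       14
        1             4       10
        2             6       16
        3            10       14
        4             7       12
----------------------------------------------
silhouette (met / gen)   0.975 / 0.960
Calinski-H (met / gen)   17434.1 / 15947.4
```

The filter kept 66 of 226 genera while discarding only ~0.1 % of total
relative abundance per sample, the +1 pseudocount moved no relative
abundance by more than 0.043 percentage points, and the score scan over
k = 2…10 selected the five planted biclusters, whose sizes match the
generator's ground truth exactly. Group contrasts then recover the
planted diet effect — e.g. the block-0 metabolites (a 1.5-SD latent
shift toward the low-fat diet) come out at log₂ fold change ≈ −1.4 with
`**` stars (Mann–Whitney p < 0.01) for HFD vs LFD:

```python
res.contrasts(pairs=[("HFD", "LFD")]).head(3)
#        axis        feature  bicluster  ...  log2fc     U        p stars
#  metabolite  metabolite_01          0  ...  -1.357  14.0  0.00729    **
#  metabolite  metabolite_02          0  ...  -1.349  15.0  0.00911    **
#  metabolite  metabolite_03          0  ...  -1.336  14.0  0.00729    **
```

`res.plot_heatmap(...)` renders the block-ordered correlation heatmap;
`res.biomarker_heatmaps()`, `res.pca()` and `res.classify()` provide the
downstream association analyses.

## Command line

```bash
crossclust simulate --seed 3 --out sim/
crossclust run-all --counts sim/counts.csv --metabolites sim/metabolites.csv \
    --design sim/design.csv --biomarkers sim/biomarkers.csv --seed 3 --out run/
```

`run-all` writes every stage output (filtered tables, clr matrix,
correlation matrix, selection trace, bicluster model, block-ordered
matrix, summaries, contrasts, biomarker heatmaps, PCA, figures) plus a
`manifest.json` recording the configuration and every data-driven
decision; a rerun with the same configuration reproduces all numeric
outputs byte-for-byte. Stage subcommands (`preprocess`, `correlate`,
`bicluster`, `summarize`, `associate`, `plot`) allow cheap partial
re-runs.

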