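# Methods

## The model

`crossclust` treats the paired tables of a microbiome–metabolome cohort
— genus counts **G** (samples × genera) and metabolite abundances **M**
(samples × metabolites) — as the two vertex sets of a weighted bipartite
graph whose edge weights are cross-omic Spearman correlations. The
analysis partitions that graph into *k* biclusters, each pairing a
subset of metabolites with a subset of genera whose abundances co-vary
across samples, and then asks how those biclusters relate to the
experimental design (a 2×2 dietary-fat × prebiotic-supplement layout)
and to external biomarkers.

### Preprocessing

Genus counts are compositional: only relative abundances within a
sample are meaningful, and rare taxa are dominated by detection noise.
The pipeline therefore:

* drops genera whose within-sample relative abundance reaches the
  detection limit (default 0.1 %) in fewer than a prevalence fraction of
  samples (default 10 %); metabolites are filtered the same way with
  detection meaning "> 0". The boundary case (prevalence exactly at the
  threshold) is **kept**; the filter never rescales retained cells.
* reports, per sample, the *data loss* — the summed relative abundance
  of dropped features, identically 1 minus the kept-feature sum — and,
  when a genus → phylum map is available, the per-phylum
  relative-abundance shift in percentage points. The shift is emitted in
  two variants (kept features renormalized to sum to one, and raw),
  since either convention is defensible and the difference is exactly
  the data loss.
* adds a +1 pseudocount to the retained counts so the log transform is
  defined, recording the largest relative-abundance displacement this
  causes (fractions of a percentage point at realistic depths), and
  applies the centered log-ratio transform
  `clr(x)_j = ln x_j − mean_d ln x_d` (natural log; the zero-sum
  property is base-independent). clr rows sum to zero and are invariant
  to per-row multiplicative scaling — both are enforced and tested.

Pseudocount and clr apply only on the correlation path; filtering and
reporting always use raw counts.

### Cross-omic correlation

Spearman's ρ (mid-ranks for ties; two-sided p from the large-sample t
approximation when requested) is computed between every **raw**
metabolite column and every **clr** genus column. Metabolites are
deliberately not standardized — rank correlation is invariant to any
strictly increasing transform, which the tests verify. Constant columns
are an error, never a silent NaN.

### Spectral co-clustering

The m × n correlation matrix *A* is partitioned with Dhillon-style
bipartite spectral graph partitioning:

1. *A* has negative entries, which the normalized-cut derivation does
   not allow. The default `shift="half"` maps r → (r+1)/2 — strictly
   monotone, so the strongest positive correlations remain the heaviest
   edges and block-diagonal structure forms around them, while negative
   correlations become light edges and surface as cross-cluster
   checkerboard cells. `shift="none"` is available for matrices with
   positive margins.
2. `A_n = D₁^{−1/2} A′ D₂^{−1/2}` with D₁, D₂ the diagonal row/column
   sums of the shifted matrix.
3. Rows and columns are embedded with the singular vectors
   u₂…u_{l+1}, v₂…v_{l+1} of A_n, l = ⌈log₂ k⌉, stacked as
   `Z = [D₁^{−1/2}U_l ; D₂^{−1/2}V_l]`, and jointly clustered by
   k-means (k-means++ initialization, `n_init = 10` restarts, best
   inertia wins, seed threaded through). The first m labels are the
   metabolite partition, the rest the genus partition — every row and
   column belongs to exactly one bicluster. Labels are canonicalized by
   first appearance, so the partition is deterministic given
   (A, k, seed, n_init).

**Degenerate spectra.** On an exactly block-diagonal matrix with
constant blocks every block contributes singular value √v, so with equal
constants the leading value is k-fold degenerate and any ⌈log₂ k⌉-dim
slice of that subspace may collapse two blocks. The embedding therefore
never cuts inside a run of singular values tied within 1e-8 relative —
it extends to the end of the tie. Noisy matrices have distinct spectra,
where the standard ⌈log₂ k⌉ applies unchanged. This restores exact
recovery (adjusted Rand index 1.0 on both axes) on all noise-free
constant-block matrices, which the acceptance suite checks for
k ∈ {2, 3, 5} at study-scale sizes.

sklearn's `SpectralCoclustering` implements the same normalized-cut
construction; it is used in the tests as an independent oracle (label
agreement ARI = 1 on clean block matrices), never as the implementation.

### Choosing the number of biclusters

For each k in a grid (default 2–38, truncated to min(m, n)), the model
is fitted and the induced partitions are scored on each axis of *A*
separately: the metabolite partition in the space of row vectors of *A*
(each metabolite's correlation profile across genera) and the genus
partition in the space of column vectors. Scores are the mean Silhouette
(singletons contribute 0; a single cluster is undefined and recorded as
missing) and the Calinski–Harabasz variance ratio (a perfect clustering
is reported as +inf with a warning). Scoring on matrix coordinates
rather than the spectral embedding makes the scores measure coherence of
the interpretable correlation profiles; the embedding alternative would
co-adapt the score to the model's own representation.

The chosen k maximizes the mean of the four min-max-normalized score
curves, with two numerical safeguards:

* CH curves are log-transformed before normalization. CH spans orders of
  magnitude on these matrices (≈60 at k=2 to ≈20 000 at the true k), and
  raw min-max would let a relatively tiny spike at large k outrank a
  plateau at the true k.
* Ties in the combined score (identical partitions reached at several k
  give scores equal up to float summation order) break toward the
  smallest k within 1e-9.

The full score trace is always returned and written to disk so the
automatic choice can be overridden by inspection.

## Summaries and group contrasts

Per-sample bicluster summaries follow the two scales of the upstream
analysis: metabolites are summed raw (totals are conserved exactly),
genus relative abundances are summed within each bicluster and the k
block sums are clr-transformed (rows again sum to zero; a zero block sum
falls back to half the smallest positive block sum, logged). Mean
centering for plotting happens only at plotting time.

Group contrasts report log₂ of the ratio of group arithmetic means (the
common convention for such tables; the package defines it explicitly
since several conventions exist). A zero group mean is replaced by
ε = ½ · (smallest positive value of the feature), flagged in the output;
two zero means — or any negative mean, as can occur for clr-scale
summaries — yield an undefined (NaN) fold change while the rank test
still applies. Genus contrasts use the relative-abundance scale,
metabolite contrasts the raw scale.

The Mann–Whitney U statistic counts pairs with a_i > b_j (ties count ½)
and is reported as min(U_a, U_b). The two-sided p-value is exact
(complete enumeration of rank assignments, via scipy's exact method)
when n_a + n_b ≤ 16 with no ties, otherwise the normal approximation
with tie and continuity corrections. The acceptance suite verifies the
exact path against an independent brute-force enumeration for every
group-size split with n_a + n_b ≤ 10, and the null star rate (p < 0.05
on null features at n = 10 vs 10) is calibrated to 5 % ± 2 pp — slightly
conservative (~4–5 %) because the U distribution is discrete.
Significance stars are `*` for p < 0.05 and `**` for p < 0.01; no
multiple-testing correction by default (stars mirror raw p), with
Benjamini–Hochberg available behind a flag.

## Biomarker associations, PCA, classification

Biomarker heatmaps are Spearman ρ (pairwise-complete over missing
cells; biomarkers with < 3 observed values are excluded with a warning)
between each biomarker and each bicluster summary, starred as above.
Heatmap rows are ordered by average-linkage hierarchical clustering on
1 − r distance between biomarker correlation profiles; the linkage
choice is a presentation decision recorded in the output metadata.

PCA standardizes features by default (flag available; constant features
are dropped with a warning when standardizing), fixes each component's
sign so its largest-magnitude loading is positive, and draws per-group
95 % ellipses from the 2-D score covariance at the χ²(2) 0.95 quantile.

Classification of the diet factors (overall group, fat, supplement)
uses a pluggable classifier — gradient-boosted trees (xgboost) by
default, fitted on raw metabolites plus clr genera, optionally
restricted to one bicluster's members — under stratified 5-fold
cross-validation, reporting fold-averaged accuracy and macro-F1 and
fold-averaged feature importances. The classifier is off-the-shelf by
design; the package's contribution is the harness, scopes and
transforms around it.

## The synthetic generator

The generator emulates the study layout the pipeline targets, with
defaults chosen once to mirror that design:

| parameter | default | rationale |
|---|---|---|
| samples | 4 groups × 10 | 2×2 fat × supplement design |
| genera | 226, of which 66 abundant | pre/post-filter counts of a real 16S genus table |
| metabolites | 38 | NMR panel size |
| blocks (k) | 5 | metabolite blocks 11/4/6/10/7, genus blocks 14/10/16/14/12 |
| loading λ | 1.0 | latent factor enters log-intensities at unit weight |
| noise σ | 0.10 | per-feature log-scale noise; recovery benchmarks use 0.05 |
| library size | log-normal, mean 5·10⁴, sdlog 0.3 | realistic 16S depth spread |
| rare-baseline offset | −8 | keeps the filter-retained set equal to the 66 planted genera |

Per sample s and block b a latent factor
z_bs ~ N(δ_f·fat_s + δ_x·xos_s, 1) couples all features of the block.
Genus log-intensities (baseline + λz + noise) pass through a softmax and
a multinomial draw at the sample's library size, so the planted blocks
must survive the compositional steps (relative abundance, pseudocount,
clr) exactly as real signal would; metabolites are log-normal with the
same latent term; biomarkers are noisy linear readouts of single block
latents (e.g. liver triglycerides read block 4, which carries a fat
effect). Default group effects place a −1.5 fat effect on block 0, a
−1.0 supplement effect on block 3, and (+1.0, −0.5) on block 4,
echoing the qualitative pattern such studies report (an SCFA-like block
higher on low-fat diets; supplement-suppressed amino-acid blocks).
The remaining 160 genera are rare background (no block term) that the
default filter removes — about 70 % of genera, as in real tables.

**What the generator does not emulate:** phylogenetic correlation among
genera, overdispersion beyond the multinomial, block overlap, technical
batch structure, or realistic metabolite measurement error. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the planted model, not performance guarantees on real data.

**Recovery accounting.** Planted-block ARI is computed on features the
generator assigned to a block; any feature without a ground-truth block
(label −1) is excluded, as is standard for planted-structure
benchmarks. At σ = 0.05 the pipeline recovers the planted partition
essentially perfectly (mean ARI > 0.99 on both axes over 20 seeds) and
the k scan picks 5 in ≈ 95–100 % of seeds; the rare miss is a k-means
merge of two blocks whose latent factors correlate by chance through
the shared design effects. Detection power for the planted 1.5-SD fat
effect on a block's summed abundance is ≈ 0.8 per contrast
(theoretical Mann–Whitney power ≈ 0.86 at d = 1.5, n = 10/group, minus
mixture-noise dilution).

## Numerical and design choices

* Canonical table orientation is samples × features; the reader absorbs
  either on-disk layout via an orientation flag. IDs are matched
  case-sensitively after whitespace trimming. Missing biomarker cells
  are NaN in memory, empty fields on disk; counts and metabolites may
  not be missing.
* Validation is strict and never repairs: duplicate IDs, negative or
  non-integer counts, non-finite values and misaligned samples raise
  errors naming the offending IDs/cells.
* k-means empty clusters are handled by sklearn's internal relocation
  (equivalent to restart re-initialization); assignment ties break by
  lowest cluster index via label canonicalization.
* Pipeline outputs are written with fixed float formatting ("%.12g");
  two runs with the same configuration and seed are byte-identical on
  all numeric outputs (the manifest records paths and therefore
  differs across output directories).
* Problem sizes in the validation suite (20 seeds for recovery, 1000
  replicates for calibration and clr invariants, 100 tables for filter
  conservation, complete enumeration up to n = 10) were chosen to give
  tight Monte-Carlo error at interactive runtimes.

## Known limitations

* The half-shift treatment of negative correlations is one defensible
  choice; published bicluster memberships obtained with a different
  treatment of negative entries may differ at the margins. The shift
  mode is a first-class parameter and is recorded in the manifest.
* Silhouette/CH-based k selection assumes the correlation profiles form
  compact clusters; highly unbalanced or overlapping blocks can shift
  the optimum. The full trace is always emitted for manual override.
* Fold-change ε replacement for zero group means is arbitrary up to a
  constant; affected rows are flagged.
* The exact Mann–Whitney path requires tie-free data; tied data fall
  back to the corrected normal approximation even at small n.
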