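# Methods

`microguild` implements a guild-level analysis of gut-microbiome ASV count
tables for repeated-measures designs (several genotype groups, the same
mice sampled at two timepoints).  This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## The guild algorithm

A *guild* is a group of ASVs whose abundances move together across
samples, treated as one ecological unit.  Guilds are discovered in four
steps on the rarefied count table:

1. **Prevalence filter.**  ASVs present (count > 0) in at least 25% of
   samples are retained (`inclusive=True`; a strict `>` variant exists
   because the boundary matters when the sample count makes the threshold
   an integer, e.g. exactly 9 of 36).  The fraction of total reads
   retained is reported.
2. **Co-abundance distance.**  Pairwise repeated-measures correlations of
   `log10(relative abundance + 1e-6)` are computed by subtracting each
   mouse's mean from both variables and pooling the centered values into
   one Pearson correlation.  Subject centering removes between-mouse
   (and hence between-genotype) level differences, so the correlation
   reflects how two ASVs co-vary *within* a mouse over time — without it,
   any two ASVs that differ between genotypes in the same direction would
   appear correlated.  The distance is `1 − r ∈ [0, 2]`.
3. **Ward clustering** of the ASVs on that distance, using Lance–Williams
   updates on squared distances ("ward.D2" semantics, scipy's `ward`),
   with deterministic lowest-index tie-breaking.
4. **Recursive PERMANOVA gates.**  From the root of the dendrogram, each
   node's left and right clades are compared by PERMANOVA on the node's
   distance submatrix (9999 permutations, split when `p < 0.001`).  A node
   that fails the gate — or has fewer than `min_leaves_to_test = 3`
   leaves — becomes a guild.  Every decision (clade sizes, pseudo-F, R²,
   p, exact flag, verdict) is logged.

### PERMANOVA details

`SS_total = (1/N) Σ_{i<j} d²_ij`, `SS_within` is the analogous per-group
sum, `pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a))`.  Labels are
permuted as a multiset.  When the number of distinct labelings is at most
`n_perm`, all of them are enumerated and the p-value is the raw fraction
of labelings with `F ≥ F_observed` (the observed labeling counts itself,
so `p > 0`); otherwise `n_perm` permutations are sampled and the
`(hits + 1)/(n_perm + 1)` estimator is used.  `F` comparisons use a
relative tolerance of 1e-12 so analytically tied labelings (e.g. a
constant distance matrix) count as ties despite float rounding.
`SS_within = 0` yields `F = +∞` with the p-value still taken from the
permutation distribution.

A consequence worth knowing: a balanced node with 10 leaves has only
C(10,5) = 252 distinct labelings, so the smallest achievable exact p is
2/252 ≈ 0.008 — the 0.001 gate *cannot* split small clades.  The gate
only becomes active for clades of roughly 16+ leaves, which is the
regime the algorithm is designed for (hundreds of prevalent ASVs).

## Diversity statistics

Rarefaction subsamples each sample without replacement
(multivariate hypergeometric) to a fixed depth, default 17,000 reads;
shallower samples are dropped with a warning, never resampled.  Shannon
diversity is reported in bits (base 2, the QIIME 2 convention; the base
is a parameter).  Weighted UniFrac is the unnormalized variant
`Σ_b l_b · |P_A(b) − P_B(b)|` over tree branches, computed on rarefied
relative abundances; a feature carrying abundance but absent from the
tree is an error, not a silent zero.  PCoA is classical scaling: Gower
double-centering `−½ C D² C`, symmetric eigendecomposition, coordinates
scaled by √λ on the positive axes only, and proportions explained
relative to the positive-eigenvalue sum (negative eigenvalues, routine
for non-Euclidean distances like UniFrac, yield no axes).

## Group comparisons

Guild abundances are compared across genotypes at each timepoint with a
tie-corrected Kruskal–Wallis test followed by Dunn's post hoc
(`z = (R̄_i − R̄_j)/√((N(N+1)/12 − T)(1/n_i + 1/n_j))`, two-sided normal
p, Bonferroni-adjusted over the pairs tested by default; Holm and
unadjusted variants available).  Pairwise outcomes are summarized as a
compact letter display built by insert-and-absorb: groups share a letter
exactly when their adjusted p ≥ α, including intransitive patterns,
deterministically in group order.  Within-genotype timepoint contrasts
use the Wilcoxon matched-pairs test; two-group contrasts use
Mann–Whitney; guild–phenotype monotone association uses Spearman.  Exact
null distributions are used at small sample sizes without ties (U: both
n ≤ 8; W: n ≤ 25), normal approximations with tie correction otherwise.
Per-guild tests are reported at α = 0.05 without across-guild FDR
correction (an optional switch exists and is off by default).

## Weight association

Body weight is regressed on guild relative abundances with a random
forest: 500 trees, bootstrap resampling, `⌊p/3⌋` candidate features per
split (the R regression conventions).  The ensemble is a thin first-party
bagging loop over scikit-learn regression trees, which keeps per-tree
out-of-bag (OOB) index sets explicit and makes a 500-tree fit cheap at
these sample sizes.  Feature importance is OOB permutation importance:
the mean increase in OOB squared error when one predictor's values are
permuted.

Model selection follows the rfcv recipe with leave-one-out CV, with one
deliberate strictness: predictor rankings are recomputed from importance
*inside every training fold*, so the CV error curve never sees the held
-out sample.  Candidate sizes halve from p down to 1; `k*` is the curve's
argmin with ties going to the smaller model; the reported guild set is
the top-`k*` by full-data importance.  Validation is the Pearson r (and
t-based p) of LOO-predicted versus measured weight; a model trained at
one timepoint can be applied unchanged to the other timepoint's guild
abundances for cross-timepoint validation.

## The synthetic benchmark

The generator emulates a 3-genotype × 6-mice × 2-timepoint fecal 16S
study.  Guild g has latent log abundance
`λ_gs = μ_g + γ_g,group + δ_g,time + u_g,mouse + ε_gs`, member ASV i adds
an ASV offset and noise `η_is = λ_gs + a_i + e_is`, proportions are the
softmax of η over all ASVs, and counts are multinomial at depth 17,000.
Noise ASVs get independent λ with per-sample dropout 0.92, so they fall
below the 25% prevalence threshold essentially always (in expectation
they appear in ~8% of samples; over many replicates, rare chance
crossings of the threshold are possible and are then correctly retained
by the presence-based filter).

Default magnitudes, chosen once as the study conditions: genotype
effects γ up to ±0.6 natural-log units with the three causal guilds
(2, 5, 7) given pairwise linearly independent genotype profiles; diet
shifts δ up to ±0.6; σ_mouse = 0.3, σ_sample = 0.6 (guild-level
per-sample variation, the main co-abundance signal), σ_asv = 0.3
(within-guild divergence), ASV offsets σ = 0.5.  Guild 1 is a dominant
stable guild (μ 3.4 vs 2.0, ~35% of reads at study scale), mirroring the
skewed guild-size distributions of real communities; this also buffers
the compositional denominator so that the causal guilds' relative
abundances are not forced into strong negative cross-correlation, which
would otherwise let a single guild proxy the whole weight signal.  Body
weight is `25 g + genotype offset + diet gain (10 g at week 11) +
Σ β_g · (guild g's relative abundance) + N(0, 0.5²)` with
β = (70, −65, 60) g per unit relative abundance — each causal guild
contributes ~2–4 g of weight variation, against 0.5 g of residual noise.
Two scales are packaged: `default_params()` (8 guilds × 8 ASVs + 40
noise ASVs = 104 features) for recovery benchmarks, and
`paper_scale_params()` (24 guilds × 8 + 600 noise = 792 features,
~190 prevalent) matching the size of a real 36-sample table.

What the generator does **not** emulate: taxonomic structure, phylogeny–
abundance correlation (the tree is random unless `guild_coherent_tree`),
overdispersion beyond the log-normal latent layer (no Dirichlet
component), sequencing-depth variation across samples, batch effects,
or nonlinear guild–phenotype links.  Passing recovery benchmarks
therefore shows the algorithms are correct and well-calibrated under the
stated model — not that real guilds of this effect size are always
recoverable from 36 samples.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from the master seed plus the
stage name (SHA-256), so whole-pipeline runs are byte-reproducible and
stages can be re-run standalone.  The packaged benchmarks use problem
sizes chosen to keep a full test cycle comfortable on one CPU: guild
recovery over 20 generator seeds, PERMANOVA calibration on 1,000 null
datasets × 999 permutations, forest recovery over 10–20 seeds, and the
determinism check on one full-size (792-ASV) run; the acceptance script
reports medians over 5 replicates where a single draw would be noisy.

## Known limitations

- The exact-enumeration PERMANOVA enumerates label multisets; for nodes
  just above the `n_perm` boundary the sampled estimator is used even
  though enumeration might be feasible with more time.
- Dunn's test uses the normal approximation regardless of group size (as
  standard); letters at very small n are conservative.
- The rfcv curve at n = 18 is noisy; the selected model size varies
  between seeds even when the causal set is stable.  Medians over seeds
  are the meaningful summary.
- `FittedModel` holds live tree objects; persistence across processes is
  out of scope (re-fit from the seed instead).
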