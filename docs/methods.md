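# Methods

## Two-component deconvolution

Each mixed sample is modeled on the raw FPKM scale as
`Y_ig = π_i R_ig + (1 − π_i) T_ig`: `R_ig` a draw from gene *g*'s reference
law, `T_ig` from its purified disease law, `π_i` the per-sample
contamination proportion. The reference law's raw moments `(m_g, v_g)` are
estimated from the reference samples (the log2-scale `(μ_g, σ_g)` are also
reported, with `σ` floored at 0.05 to avoid degenerate likelihoods). A
single component is evaluated through a moment-matched log-normal
(Fenton–Wilkinson) density of `Y + 1`; the +1 pseudocount keeps zeros
finite and is exact for the affine mixture because the weights sum to one.

Two structural commitments make `π` identifiable where a naive
maximum-likelihood scheme is not:

* **Constant CV.** The purified law shares the gene's log-scale
  dispersion, so its raw variance is tied to its mean:
  `v_T = v_g (m_T/m_g)²`. Without this tie the purified variance is a free
  parameter that absorbs the contamination entirely (the likelihood is
  maximized at `π ≡ 0` for any start — a ridge along
  `π_i ↦ (π_i − α)/(1 − α)` with compensating purified parameters). The tie
  is exact under the generator (shared log-dispersion) and matches the
  standard mean–variance relationship of expression data.
* **Known reference variance.** `v_g` enters the per-sample variance as
  `π_i² v_g (1 + 1/n_ref)`; the `1/n_ref` term accounts for the sampling
  error of the estimated reference mean (without it the estimate is
  attenuated toward 0 by errors-in-variables).

Estimation: (1) per-sample *relative* contamination by a weighted
errors-in-variables regression of each sample's deviation from the cohort
mean on the (reference − purified) mean profile, restricted to clear-signal
genes (`D² > 4·se²`); (2) the remaining scalar — the cohort mean level — by
a 1-D profile likelihood on a 0.01 grid over [0, 0.8]; (3) two rounds of
per-sample weighted least squares against the fitted purified profile,
then a guarded alternating refinement: purified-mean updates are accepted
per gene only when they increase that gene's likelihood, and `π` is
re-maximized exactly on the grid {0, 0.01, …, 0.95} per sample, so the
objective is non-decreasing by construction (asserted in tests). Finally a
per-sample boundary likelihood-ratio test sets `π̂ = 0` unless the best
grid point beats `π = 0` by at least 5 nats (~p < 0.002 for a 1-df
boundary test): contamination must be decisively supported, which makes
deconvolution of an uncontaminated cohort an exact identity.

Purification: `T_ig = max(ε, (Y_ig − π̂_i m_g)/(1 − π̂_i))`, `ε = 0.01`.
Using the raw reference mean `m_g` (not `2^μ_g`, which is biased low for a
log-normal) makes `π̂ m_g + (1 − π̂) T` reconstruct `Y` exactly wherever no
clamping occurred.

Under the default study conditions (500 genes, 40+40 samples,
`π ~ U(0.2, 0.6)`, 20% planted DEGs at ±1 log2) the estimator achieves a
mean absolute error of ~0.04 in `π` and restores planted group
fold-changes to within 0.06 log2 of truth. The planted-DEG fraction is the
main information source for the absolute contamination level; cohorts with
very few truly changed genes identify `π` only weakly.

## Differential expression

Per gene, three statistics — Welch *t*, Wilcoxon rank-sum (centered at its
null expectation so the two-sided |s| rule is meaningful; average ranks on
ties), and the difference of medians — are each calibrated by the same set
of `n_perm = 1000` random label permutations, with the add-one estimator
`p = (1 + #{|s_perm| ≥ |s_obs|})/(1 + n_perm)`, so p-values live on the
grid {1/1001, …, 1} and can never be 0. Per-gene permutation streams are
seeded by a stable SHA-256 hash of (master seed, gene id): results are
independent of gene order and reproducible gene by gene.

The three p-values are combined by Fisher's method against χ² with 6 df.
The three statistics are computed on the same data, so the independence
assumption behind Fisher's reference distribution does not hold exactly;
the combined p is mildly anti-conservative on its own. The DEG rule —
raw-scale fold-change `(mean_mixed + 1)/(mean_ref + 1)` beyond 1.25 in
either direction *and* combined p < 0.01 — keeps the realized null call
rate near 1–2% at the default sample sizes because the fold-change filter
dominates. No multiple-testing correction is applied beyond the fixed
threshold, mirroring common practice for this fixed-rule design.

## Maximal information coefficient

MIC follows the canonical MINE estimator: for each grid shape `(a, b)`
with `a·b ≤ B = max(4, n^0.6)` (the floor keeps the 2×2 grid admissible at
any n), one axis is equipartitioned into `b` rows (ties kept together) and
the other is partitioned into ≤ `a` columns by dynamic programming.
Because the row partition is fixed, maximizing mutual information equals
minimizing the column-additive conditional entropy `H(rows|columns)`; cut
points are restricted to clump boundaries (maximal runs of same-row
points; cuts never split tied x-values) and capped at `clump_factor·a = 15a`
superclumps. Both orientations are searched and the normalized maximum
`I/log₂ min(a,b)` over all shapes is returned. The DP is exact given the
row partition — verified against brute-force enumeration of all admissible
column partitions at small n — and the kernel is numba-compiled (~1 ms per
pair at n = 100). Value ties are broken by stable input index, making the
statistic deterministic and invariant under strictly monotone transforms.

DCGP calling compares a pair's MIC computed within each condition's
samples separately; |ΔMIC| > 0.4 calls the pair, with "up" meaning
stronger dependence in the mixed condition. Self-pairs are reported
(MIC = 1) but never called. At n = 100 per condition the null MIC averages
~0.23 with essentially no mass beyond 0.4, so the 0.4 rule has a very low
false-positive rate without per-pair significance calibration.

## Repertoire diversity

Processing order is fixed: collapse identical junction sequences per
sample (counts summed) → keep the top 10,000 unique sequences by count
(ties broken lexicographically for determinism) → keep in-frame junctions
(length divisible by 3, no TAA/TAG/TGA in frame 0 anchored at the junction
start; sequences containing N are dropped) → count (V, J) combinations.
Alpha diversity is the Shannon index (natural log) over a sample's
combination abundances; beta diversity is presence/absence Sørensen
dissimilarity with the Baselga partition β_sor = β_sim + β_sne
(turnover + nestedness). Group contrasts use two-sided label-permutation
tests (difference of group means for alpha; difference of mean
within-group pairwise dissimilarity for beta).

## Localization-change prediction

For each protein and condition, the evidence vector over the 10
compartments sums MIC(protein, partner) over annotated interaction
partners per compartment, L1-normalized (so scaling all MICs leaves
features unchanged); proteins with no annotated partners are excluded and
listed. An RBF-kernel SVM with sigmoid-calibrated probabilities is trained
on the reference-condition features of annotated proteins (compartments
with fewer than 5 training proteins are dropped; 5-fold CV accuracy is
reported from the uncalibrated margin classifier). The per-protein change
score is `max_l |P_mixed,l − P_ref,l|`. Significance: the null change-score
distribution is built by pooling both conditions' samples, permuting them
into pseudo-conditions of the original sizes, and recomputing features and
profiles for a random subsample of proteins (default 12 proteins × 100
permutations); a protein is "changed" iff its score exceeds the null's
95% quantile (quantile 1.0 is a degenerate bound — the changed set is
empty by definition). Partners of a truly relocated protein legitimately
shift their own evidence, so planted-run call counts exceed the planted
count; the false-positive rate is defined on relocation-free cohorts,
where it tracks 1 − quantile.

## Evaluation

PCA proportions are eigenvalue ratios of the covariance of centered
log2(x+1) sample vectors over a gene subset. AUC uses the rank-sum
identity (equal to concordant-pair counting with half-credit ties,
verified against an O(n²) oracle). The repeated-CV naive Bayes uses
Gaussian class-conditionals on log2(x+1) features, stratified 10-fold
splits reshuffled per repeat (per-repeat seeds derived by counter from the
master seed), pooling out-of-fold scores into one AUC per repeat and
reporting mean ± sd; "10-times cross-validation" is read as 10-fold, and
the mean over repeats is reported rather than the best.

## Synthetic cohorts: what they emulate, and what not

* **Expression cohort** — per-gene log-normal expression
  (`log2(x+1) ~ N(μ_g, σ_g)`, `μ_g ~ U(2,8)`, `σ_g ~ U(0.3,0.8)`, plus
  `noise_sd = 0.2` measurement noise), mixed samples contaminated by fresh
  reference draws with `π_i ~ U(0.2, 0.6)`, and DEGs planted at ±1 log2 in
  20% of genes — a fraction chosen to match the share of called DEGs among
  high-variance genes in published COPD reanalyses (~30%). Defaults:
  1000 genes, 40+40 samples.
* **Co-expression cohort** — planted pairs are `y = f(x) + ε`
  (linear/quadratic/sinusoidal, `noise_sd = 0.1`) in exactly one condition
  and independent in the other; latents are mapped affinely to a positive
  FPKM-like scale, which leaves MIC unchanged.
* **Localization network** — proteins assigned evenly to the 10
  compartments; edges drawn with between/within odds equal to
  `coexpr_between/coexpr_within` (0.15/0.85 by default, overall density
  0.06); expression is one latent factor per compartment per condition
  with loading `√coexpr_within`. Relocated proteins follow the source
  factor in the reference condition and the destination factor in the
  mixed condition, and are wired to partners in both compartments — a
  relocating protein interacts in both states; without destination-side
  partners the partner-weighted features could not register the move.
  Annotations record the source compartment.
* **Repertoire** — per-sample V–J abundances
  `p ~ Dirichlet(c/K)`, counts `~ Multinomial(reads, p)`; the mixed group
  uses the larger concentration (more even, higher diversity), mirroring
  the marginally higher clonotype diversity reported for mild disease.
  Out-of-frame junctions (default 20%) get a length not divisible by 3 or
  an in-frame stop codon.

None of the generators models batch effects, library-size variation,
isoform structure, count-level noise (FPKM values are continuous), read
errors, or germline V/D/J sequence context. Passing the recovery tests
shows the estimators work when their structural assumptions hold; it does
not certify performance on real cohorts, where contamination is not a
clean two-component mixture and annotation noise is substantial.

## Numerical choices and edge cases

* All sub-stream seeds derive from the master seed by SHA-256 hashing of
  string tokens (never Python's `hash`), and stay below 2³¹.
* Deconvolution: π grid step 0.01 capped at 0.95 (division blow-up as
  π → 1); purified floor ε = 0.01; reference σ floor 0.05; variance floors
  1e-12 inside likelihoods; boundary LRT gain 5 nats.
* CV filter uses sample sd (n−1) over all samples on the raw scale; genes
  with zero mean are excluded; an empty result is a warning, not an error.
* MIC returns 0 with a warning for constant inputs; inputs shorter than 4
  are rejected.
* Permutation tests return p = 1 with a warning when all values are
  identical; empty overlap directions report NaN percent, not 0.
* Test and analysis problem sizes (500-gene cohorts, 100-protein networks,
  100-permutation nulls, 20–50 CV repeats) are chosen so each stage's
  sampling noise is well below its acceptance margin while the full suite
  stays fast; defaults in the API are the larger study-scale values
  (1,000 permutations, 500 repeats, top-10,000 reads).

## Known limitations

* The contamination level is identified mainly by genes that truly differ
  between conditions; on cohorts with few DEGs the level estimate degrades
  gracefully toward the boundary-test null (π̂ = 0) rather than inventing
  contamination.
* Fisher combination of three correlated tests is anti-conservative as a
  p-value; it is used as a fixed ranking rule with a fold-change filter,
  not as a calibrated error rate.
* MIC significance is not calibrated per pair; the ΔMIC > 0.4 rule is a
  fixed effect-size threshold.
* Localization features see only annotated direct neighbours; hub proteins
  with heterogeneous partners produce diffuse probability vectors, and
  multi-compartment biology is reduced to single labels for training.
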