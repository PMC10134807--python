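# Methods

This note documents the models implemented in `pelagos`, the parameter
choices that matter, the numerical conventions, and what the synthetic
study does and does not establish about real data.

## Synthetic metacommunities

The generator emulates a marine depth transect: 5 stations at 130°E spread
from 2.25°N to 18°N, three stations sampled at 5/75/200/500/1000/2000 m and
two at eleven depths (5–2000 m), giving 40 samples; the photic/aphotic
boundary sits at 200 m (configurable). Three microbial groups — protists,
free-living bacteria, particle-associated bacteria — are generated over
the same samples, each with its own metacommunity, phylogeny and trait
optima. Environmental variables are smooth monotone functions of depth
(temperature 28→2 °C with an e-folding depth of 250 m; salinity and
dissolved oxygen analogous; bacterial/viral/nanoflagellate abundances
decaying exponentially) plus optional Gaussian noise, so depth, water mass
and the niche axis are intertwined the way they are in a real water
column.

**Neutral regime.** Sloan's model describes a local community of `N`
individuals receiving immigrants from a metacommunity with relative
abundances `p` at rate `m`. Its stationary composition is Beta-distributed
per taxon; we draw whole compositions from the conjugate
`Dirichlet(N·m·p)` — whose marginals are exactly those Betas — and then
`N` reads multinomially. `m = 1` degenerates to i.i.d. multinomial
sampling of the metacommunity. Metacommunity abundances default to a
logseries draw (shape 0.998), the canonical skewed abundance distribution;
user-supplied vectors are accepted.

**Niche regime.** Expected relative abundance of taxon `j` in sample `s`
is `p_j · exp(−(env_s − o_j)²/(2σ²))` with `σ = 1/niche_strength`; counts
are multinomial. The environmental axis is standardised log-depth. The
`mixed` regime applies the same filter to a neutral Dirichlet draw so
drift and selection act together.

**Phylogeny and traits.** Pure-birth (Yule) trees; tip optima are a
Brownian-motion trait (variance ∝ branch length, scaled by
`trait_signal`) plus unit i.i.d. noise, standardised across tips —
`trait_signal = 0` therefore gives optima independent of the tree. Tips
are *named in random order*: OTU identifiers carry abundance rank
downstream, and naming tips in traversal order would artificially cluster
abundant taxa on the tree and bias every phylogenetic null model.

**Defaults as study conditions.** 200 OTUs, 2,000 reads/sample, migration
`m = 0.15`, `niche_strength = 2` (σ = 0.5 on a unit-variance niche axis —
strong but not block-like filtering), `trait_signal = 1`. The transect
default assembles the photic zone under niche filtering and the aphotic
zone neutrally, the qualitative contrast reported for real depth
transects. These sizes keep a full pipeline run at minutes on one CPU
while leaving every test's effect detectable; they are fixed, not tuned
per test.

**What the generator does not emulate:** sequencing error, chimeras, PCR
and copy-number bias, read-depth heterogeneity beyond optional uniform
rarefaction, temporal dynamics, and true interaction-driven (predator-prey)
co-abundance — planted basis correlations stand in for the latter. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated models, not robustness to amplicon artefacts.

## Normalisation and prefiltering

Rarefaction is a seeded multivariate-hypergeometric subsample (without
replacement) to a common depth. The co-occurrence prefilter retains OTUs
present in ≥ 30% of samples **and** with mean relative abundance ≥ 0.01%
(the removal sentence is ambiguous between AND/OR; AND-retention is the
stricter, commoner convention, and `mode="or"` flips it). Relative
abundance is computed per sample after rarefaction; the mean across
samples feeds the 0.01% rule.

## Ordination and variation partitioning

Bray-Curtis runs on per-sample relative abundances; the presence/absence
variant equals Sørensen dissimilarity. PCoA, ANOSIM and PERMDISP are
delegated to scikit-bio (PERMDISP with spatial medians); depth decay
regresses similarity `1 − BC` on pairwise depth distance by OLS over all
sample pairs — pair non-independence is ignored, as is conventional, and a
Mantel-style permutation p is available (`n_perm > 0`).

dbMEM axes: great-circle (haversine, R = 6371 km) distances, truncation at
the largest minimum-spanning-tree edge (beyond-threshold distances set to
4× the threshold), double-centred eigendecomposition, eigenvectors with
positive eigenvalues returned. The vectors match `vegan::pcnm` exactly (up
to sign). Note the first eigenvector on a regular transect is a symmetric
large-scale wave, not a monotone trend.

Variation partitioning uses distance-based RDA: the response is the set of
positive-eigenvalue PCoA axes of the Bray-Curtis matrix (a raw-table RDA
alternative was considered and rejected as inconsistent with
distance-based inputs). For every subset of the four blocks (depth, dbMEM
space, environment PCA, biotic associations) the redundancy R² is
adjusted by Ezekiel's formula, `1 − (1 − R²)(n − 1)/(n − p − 1)` with `p`
the block rank; unique/shared fractions solve the inclusion-exclusion
linear system, negative fractions are reported as-is. Unique fractions are
tested by permuting the rows of the focal block (199 permutations by
default), Bonferroni-corrected across blocks. PCA blocks retain axes by
the Kaiser-Guttman rule (eigenvalue > mean), capped at two axes inside the
VPA. The biotic block for a focal group combines the biotic-abundance PCA
axes with the first two PCoA axes of each *other* group (the focal group's
own axes would be circular).

## Neutral-model fit

For each OTU, `p` is the mean relative abundance and the occurrence
frequency the fraction of samples where it appears. The predicted
frequency `1 − Beta(d; N m p, N m (1 − p))` is fitted in the single
parameter `N m` by bounded 1-D least squares on log `N m` with a 40-point
multistart grid; R² is computed on untransformed frequencies. Bootstrap
over OTUs (1,000 replicates by default) yields the 95% band around the
fitted curve, per-OTU above/below flags, and a CI on `m`.

**Detection limit.** Presence in count data means "≥ 1 read": a *soft*
binomial threshold whose 50%-detection point is at relative abundance
`1 − 2^(−1/N) ≈ ln 2/N`. Using the hard-cut value `1/N` with count-based
presence inflates the fitted `N m` by ~25–35% in recovery simulations;
with `d = ln 2/N` the generating `m` is recovered within a few percent.
`ln 2/N` is therefore the default; pass `detection_limit=1/N` for the
classic convention (the R² values move only marginally).

## C-score and sim9

The C-score averages `(R_i − S)(R_j − S)` over species pairs on the
binarised matrix. The null preserves row and column sums by sequential
checkerboard swaps: burn-in of 10× the matrix fill, thinning of one fill
between saved matrices (`n_sim` counts saved matrices). SES > +2 is read
as segregation, < −2 as aggregation. Species present everywhere or
nowhere contribute constant pairs and trigger a warning, not an error.
Self-calibration (observed matrices drawn from the chain itself) holds
|SES| ≤ 2 at ≈95%.

## Phylogenetic null model

Weighted βMNTD between two samples averages, in both directions, each
taxon's relative abundance times its cophenetic distance to the nearest
taxon of the other sample. The null shuffles tip labels (`taxa.labels`),
1,000 randomizations by default; βNTI is the z-score, undefined (missing)
when the null SD is 0 — note two *identical* communities share every
taxon, so all nulls are also 0 and βNTI is reported missing, not
negative. RC_bray assembles null pairs preserving each sample's richness
and total reads (taxa drawn without replacement ∝ occupancy; remaining
reads multinomial ∝ regional relative abundance), with ties counted half:
`RC = 2(P(null < obs) + ½ ties) − 1`. Because the occupancy/abundance
pool is estimated from the table itself, RC carries a small positive bias
on tables of fewer than ~20 samples; calibration uses ≥ 30-sample pools.
Process classification: βNTI > +2 heterogeneous selection, < −2
homogeneous selection; otherwise RC > +0.95 dispersal limitation,
< −0.95 homogenizing dispersal, else undominated. Pairs with missing βNTI
are excluded from the denominators and counted separately.

## Niche breadth and dispersal

`P_ij` normalises over the OTU (an OTU's proportions across communities
sum to 1), so `B_j ∈ [1, N]` with `N` the number of communities — the
reading under which the uniform OTU attains `B = N`. `B_com` is the
unweighted mean over OTUs present in the sample. The dispersal proxy is
the symmetric min-ratio `2·min/(sum)`, in [0, 1], computed on rarefied
counts. Both statistics depend on the number of communities, so zone
comparisons are made at matched size: the larger group is subsampled
(1,000×) to the smaller group's size, per-sample values are averaged over
the subsamples containing each sample, and the Wilcoxon rank-sum test
compares those size-matched values.

## SparCC and networks

SparCC: per Dirichlet resampling (pseudocount 1) the log-ratio variance
matrix `T_ij` is reduced, under the sparsity assumption, to the linear
system `(D−1)w_i + Σ_{j≠i} w_j = Σ_j T_ij` for basis variances `w`;
correlations `(w_i + w_j − T_ij)/(2√(w_i w_j))` are clipped to [−1, 1].
The most correlated pair above 0.1 is iteratively excluded from the
system (10 rounds), and results are averaged over 20 resamplings.
Defaults follow the algorithm's original description. Significance is the
two-sided pseudo-p `(#{|r_boot| ≥ |r_obs|} + 1)/(B + 1)` from
column-shuffled bootstrap datasets; since the smallest attainable p is
`1/(B+1)`, FDR control at α over `T` pairs can only ever reject when
`B + 1 ≥ T/(α·k)` for `k` discoveries — the analysis scripts use
`B = 2000` with 2 Dirichlet iterations per bootstrap (the extra noise
only widens the null, making p conservative).

Edges: |r| ≥ 0.6 and BH-adjusted p < 0.01 over the upper triangle;
isolated nodes dropped. Topology: standard networkx definitions; average
path length on the largest component (flagged when the graph is
disconnected); degree power law by OLS on log-log frequency bins;
Erdős–Rényi references at matched (n, m). Modules by greedy modularity
maximisation with lexicographic tie-breaking; `Z_i` is the within-module
degree z-score (module mean and population SD; 0 for zero-SD modules) —
the within-module dispersion denominator follows the role-classification
framework the thresholds come from; `P_i = 1 − Σ_c (k_ic/k_i)²`. Roles at
Z = 2.50 / P = 0.62; hubs and connectors are keystone candidates; overlap
between networks is Jaccard on keystone sets. Natural connectivity is
computed from the adjacency eigenvalues via logsumexp; attack curves use
the static initial betweenness/degree ranking by default ("predetermined
order"; recomputed ranking behind a flag) or average seeded random
orders, and stop when fewer than two nodes remain.

Environment edges: each network node is correlated (Pearson, on relative
abundances) with each standardised environmental variable; BH adjustment
runs across all node-variable tests; an edge is taxon-taxon-environment
when both endpoints pass |r| ≥ 0.6 and adjusted p < 0.01 for the same
variable with sign concordance (product of endpoint signs equals the edge
sign). Thresholds default to the network's own since no separate values
are conventional. Diversity-complexity regressions use per-sample induced
subgraphs; rows with R² < 0.01 are flagged as conventionally omitted.

## Problem sizes and determinism

The analysis scripts and the acceptance script run the study at 40
samples × 200 OTUs × 3 groups, 2,000 reads/sample, 200 phylogenetic-null
randomizations, 1,000 sim9 matrices, 2,000 SparCC bootstraps, and
top-40-per-group network tables — sizes chosen so the full pipeline
completes in minutes on a single CPU while every effect stays well
resolved. All Monte-Carlo operations take explicit seeds; identical
config + seed reproduces identical output bit-for-bit.

## Known limitations

* The aphotic (neutral) half of the default study genuinely has no basis
  correlations, so its co-occurrence network is empty at desk scale —
  an amplified version of the "less widespread aphotic co-occurrence"
  pattern rather than a sparse-but-present network.
* The dispersal proxy is higher in the neutral zone of the synthetic
  study (homogeneous communities share more reads), so its photic/aphotic
  direction need not match field data.
* RC_bray inherits a small positive bias from self-estimated pools on
  small tables (see above).
* sim9 swap chains mix slowly on near-degenerate matrices; the defaults
  assume moderate fill.
* No iCAMP-style per-clade process partitioning, no NMDS/CCA, and no
  alternative correlation engines — extension points, not features.
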