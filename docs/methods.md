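# Methods

This note documents the models and algorithms implemented in
`phytoassembly`, the parameter choices that matter, and what the
synthetic validation does and does not demonstrate.

## Inference framework

Community assembly is read off two complementary null models applied to
every pair of samples of a rarefied ASV table aligned to a rooted,
branch-length-bearing phylogeny.

**Phylogenetic turnover (βMPD, βNRI).** βMPD between samples a and b is
the unweighted mean of cophenetic distances over all ordered cross pairs
(i ∈ a, j ∈ b), shared taxa contributing zero distances — the standard
between-community MPD convention. The null shuffles the tip labels of the
*full* tree uniformly (taxa absent from every sample included), leaving
membership and abundances untouched; `n_reps` permutations (default 999)
give `βNRI = (βMPD_obs − mean_null) / sd_null` with the sample (n−1)
standard deviation, since the replicates are a sample from the
permutation distribution. One permutation stream is shared by all pairs
of a run, which makes βNRI exactly symmetric and lets each replicate be
computed as a single quadratic form `Xᵀ D X` over the tips×samples
incidence matrix (999 replicates on 150 taxa × 20 samples take seconds).
The per-sample NRI uses the same null with the conventional sign flip,
`NRI = −z`, so that positive values mean phylogenetic clustering.

**Taxonomic turnover (RC_bray).** The Raup–Crick null extended to
Bray–Curtis dissimilarity. Each null community preserves its template
sample's observed richness and read total: membership is drawn without
replacement with probability proportional to occupancy (the number of
samples containing the taxon); each drawn taxon receives one read and the
remaining reads are allocated multinomially with probabilities
proportional to dataset-wide relative abundance. Both constraints are
asserted inside the null loop. With RC_raw the fraction of null
dissimilarities below the observed one (ties counted half, which removes
bias from discrete Bray–Curtis values at low depth),
`RC_bray = 2(RC_raw − 0.5) ∈ [−1, 1]`. Null draws are consumed in
lexicographic sample order so results are invariant to input column
order.

**Classification.** Strict thresholds, boundary values falling to the
stochastic side: βNRI < −2 homogeneous selection; βNRI > 2 heterogeneous
selection; else RC_bray > 0.95 dispersal limitation; RC_bray < −0.95
homogenizing dispersal; else drift. Pairs with an undefined statistic
(degenerate null sd, empty sample) are excluded from denominators but
reported. Monthly summaries keep only pairs whose samples share a
calendar month, pooled across years and stations, so each month's
fractions are independent; groups with fewer classified pairs than
C(4, 2) = 6 carry a small-n warning.

**Phylogenetic signal (Mantel correlogram).** Per-taxon niche values are
abundance-weighted means of an environmental variable over samples.
Distance classes are equal-width bins over the cophenetic distance range,
class count by Sturges' rule on the number of pairs. The per-class Mantel
statistic is the Pearson correlation between the class indicator and the
niche-distance matrix over off-diagonal pairs; the permutation test
jointly permutes taxon order (two-tailed, add-one p-values), and p-values
receive a progressive Holm correction (class k corrected within classes
1..k), the standard correlogram convention. The reported `r` is the raw
statistic sign-flipped so that positive means "more ecologically similar
than chance"; the raw value is also emitted.

## Other statistics

Richness, Shannon H (nats), Simpson 1−D from column relative abundances;
Faith PD as the branch-length sum of the minimal subtree connecting the
occupied tips and the root (all-zero samples are flagged undefined, never
reported as 0). Rarefaction is classical subsampling without replacement
(one multivariate-hypergeometric draw per sample from a single seeded
stream); samples below the target depth are dropped and logged, as are
taxa left without reads. Unweighted (presence–absence) metrics are the
default throughout, appropriate for semi-quantitative metabarcoding
counts; abundance-weighted MPD/βMPD sit behind a `weighted` flag for
sensitivity analysis.

## Synthetic communities

The generator emulates the statistical structure of a rarefied coastal
metabarcoding survey and assembles it under one dominant process per
scenario, with per-pair truth labels for parameter recovery. Defaults:
150 taxa, 20 samples, 1000 reads per sample, Yule tree (birth 1, death
0), log-normal(0, 1) metacommunity abundances.

* **Trees** are birth–death simulations conditioned on the tip count;
  terminal branches are extended by the waiting time to the next event so
  all branch lengths are strictly positive, and the stem edge below the
  first split is removed. Tips are relabeled `t0001…`.
* **Niche optima** evolve on the tree under an early-burst Brownian
  model: the rate decays as `exp(−burst_rate · t/H)` with relative depth,
  default `burst_rate = 5`, on `niche_dims = 3` independent axes each
  min–max scaled to [0, 1]. Early burst concentrates divergence on deep
  branches, so clades occupy distinct, internally conserved niche
  regions — the niche-conservatism premise of the framework. Plain
  Brownian motion (`evolve_niche_trait`, or `burst_rate = 0`) is used for
  the signal power study, where conservatism only needs to be detectable,
  not strong. A single-axis plain-Brownian filter was rejected: trait
  convergence across clades makes a narrow trait band phylogenetically
  incoherent, and selection then produces no reliable clustering signal.
* **Selection scenarios** sample each community's membership (richness
  uniform in [0.2, 0.5] × n_taxa) without replacement with weight
  `exp(−‖niche_i − env_s‖² / (2 σ_w² d)) · m_i` — a Gaussian niche filter
  of per-axis width `filter_width` (default 0.05) times metacommunity
  abundance — then allocate reads multinomially with the same weights.
  Homogeneous selection anchors every sample's environment at the
  realized niche of one randomly chosen taxon; heterogeneous selection
  anchors two alternating environments at the most phylogenetically
  distant tip pair (across the basal split, hence also niche-divergent
  under early burst). With a narrow filter most reads concentrate on the
  few taxa near the anchor, so realized richness is low — the strong
  filtering / low diversity / high NRI regime.
* **Drift** draws each sample multinomially from the shared metacommunity
  after an independent log-normal chance fluctuation of its log relative
  abundances, scale `drift_sigma = 0.25`. The scale was fixed once from
  the behavior of the Raup–Crick band: with no fluctuation, samples are
  *more* similar than the Raup–Crick null expects (the pattern of
  homogenizing dispersal), while scales ≥ 0.5 already push most pairs
  past RC = 0.95; 0.25 represents modest chance fluctuation, clearly
  separated from the dispersal-limitation scenario's scale of 2.
* **Dispersal limitation** is the same mechanism with divergence scale
  `2(1 − migration)`, migration ≈ 0.
* **Homogenizing dispersal** (migration ≈ 1) realizes one source
  community and makes every sample a near-deterministic aliquot of it:
  largest-remainder allocation of `(1 − noise_fraction)` of the reads
  plus multinomial noise on the rest (`noise_fraction = 0.2`).
* **Environments**: dates spread over one synthetic year at one station;
  the active `env` variable on [0, 1] (constant, two-level, or seasonal
  sinusoid depending on scenario) plus decoy variables (a seasonal
  temperature, pure-noise salinity) so signal tests can be checked for
  non-detection too.

What passing recovery shows: the implemented βNRI/RC_bray machinery
detects each process when it is the designed dominant signal at realistic
survey sizes. What it does not show: performance on real data with mixed
processes per pair, multi-station spatial structure, temporal
autocorrelation, sequencing noise or compositional artifacts — none of
which the generator emulates. The generator also has no mechanistic
population dynamics (growth, grazing, nutrients).

## Numerical and design choices

* All randomness flows through seeded `numpy` generators (the tree
  simulator uses a seeded `random.Random`); a pipeline run derives every
  stage seed from the global seed, so identical configurations are
  byte-identical on disk.
* Tables are canonicalized to lexicographic taxon/sample order before any
  permutation null; file readers preserve input order.
* Degenerate cases are flagged, not silently zeroed: richness < 2, null
  sd = 0, all-equal niche values, empty samples.
* Validation sizes: null-model agreement is checked against *exhaustive*
  tip-label permutation distributions on a 4-tip tree (9,999 Monte-Carlo
  replicates, 3-standard-error tolerance); metric implementations against
  brute-force pair enumeration on 100 random ≤ 12-tip instances at 1e-10;
  scenario recovery at 199 randomizations; the signal study on 20
  replicates of 200-tip trees with 499 permutations. These sizes keep the
  full validation in minutes on one CPU while leaving each check
  well-powered.
* BIOM input is not supported (TSV only; convert externally). βNTI/MNTD
  variants are out of scope; the MPD-based NRI/βNRI family is
  implemented.
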