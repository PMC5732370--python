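# Methods

## The model

Spatial principal component analysis (sPCA) looks for axes of genetic
variation that are also spatially organised.  Given an n × p matrix **X** of
centred allele frequencies (rows: individuals or populations; columns: one
column per biallelic locus, frequency = dosage/2 for diploids) and an n × n
matrix **L** of spatial weights (row i: proximities of all units to unit i,
row-standardised by default), the spatial PCs are the eigenvectors of the
symmetric matrix

    H = 1/(2n) · Xᵀ (Lᵀ + L) X.

For a score z = Xv with row-standardised L, each eigenvalue factorises
exactly as

    λ = var(z) · I(z),     I(z) = zᵀ((L+Lᵀ)/2)z / zᵀz,

the product of the score's variance and its Moran's I, so positive
eigenvalues capture *global* structure (clines, patches; positive spatial
autocorrelation) and negative eigenvalues *local* structure (neighbours
more different than expected; negative autocorrelation).  This identity is
asserted per axis at 1e-8 in the test suite and is the reason row
standardisation is the default weight style.

## The eigenvalue permutation test

The test statistic for the j leading positive axes is the cumulative sum
f⁺_j = Σ_{i≤j} λ⁺_i (and f⁻_j = Σ_{i≤j} |λ⁻_i| for the negative side);
cumulative sums are used because axis j can only be meaningful if axes
1..j−1 are.  The null distribution is generated by Monte-Carlo permutation:
whole genotypes are re-assigned to coordinates (rows of X shuffled, L
fixed), the sPCA is recomputed, and f⁺, f⁻ plus the full vector of ranked
eigenvalues are recorded.  P-values use the plus-one convention
p = (1 + #{null ≥ obs}) / (B + 1), which counts the observed configuration
as one admissible permutation and keeps p ≥ 1/(B+1).

Step 1 reports p_global (f⁺) and p_local (f⁻).  Step 2 runs only on a side
whose step-1 p-value is below α: each observed eigenvalue is compared with
the permutation distribution of the *same rank* (the number of eigenvalues
does not change under row permutation), and a sequential Bonferroni cascade
tests rank i at threshold α/i, stopping at the first non-significant rank.
The comparison is strict (p = α/i is not significant).  Raw per-eigenvalue
p-values are reported even when the gate is closed, for inspection only.

By default f⁺/f⁻ sum over *all* eigenvalues of their sign (`stat_axes =
"all"`): this needs no pre-selection of axes and makes one f⁺/f⁻ pair per
permutation; a fixed prefix length is available through `--stat-axes K` for
sensitivity analysis.

### Numerical choices

* Eigenvalues with |λ| ≤ 1e-9 · max|λ| are discarded as rank-deficiency
  zeros (column centring alone removes one dimension).
* Eigenvector signs follow a fixed convention (largest-magnitude loading
  positive) so reruns and permutation streams are comparable.  Exact
  eigenvalue ties cannot arise with continuous data; the stable sort order
  of the solver breaks them deterministically if they ever do.
* The count of positive/negative eigenvalues can wobble by one between
  permutations (sign changes near zero); null matrices are rank-aligned to
  the observed counts, padding with zeros under a logged warning.
* H is formed explicitly (p × p, p ≤ a few hundred in all study designs);
  the permutation loop uses an eigenvalues-only symmetric solver.

## Connection networks

Networks come from k-nearest neighbours (union-symmetrised, distance ties
broken towards the smaller index), a distance band (d_min < d ≤ d_max), or
a user adjacency matrix.  The benchmark default is k = max(1, round(√n))
(k = 10 for n = 100), a common density heuristic; it is a scenario
parameter, not part of the method.  Isolated units are an error — except in
the adversarial local-pattern network, where they are dropped with a
warning.  Binary-style weights may carry a nonzero diagonal to admit the
non-spatial limit L = I, under which H = XᵀX/n and sPCA collapses to
ordinary PCA (used as an oracle in the tests).

## Synthetic data

`simgen` draws genotypes from structured-coalescent models (msprime): one
independent genealogy per unlinked locus, with a single mutation placed
uniformly at random on the branches.  This is the infinite-sites model
conditioned on the locus segregating, so every locus is a biallelic SNP and
the overall mutation rate drops out of the model.  Diploid dosages pair the
two gene copies of each individual.

* **IS** (island): d demes of diploid size N; each deme receives immigrants
  at total rate m per generation, split equally over the other d−1 demes.
* **SS** (stepping stone): chain of d demes (ring optional); total
  immigration m split over a deme's neighbours.
* **IBD** (isolation by distance): 10 × 10 lattice of demes with
  nearest-neighbour migration, one diploid sampled per deme (n = 100).

Defaults mirror the benchmark design: 4 demes × 25 diploids (IS/SS), 200
unlinked SNPs, rates {0.005, 0.01, 0.1}, deme size N = 100.  N stands in
for the original simulators' scaled-mutation parameterisation; because loci
are conditioned on segregation, N acts mainly through the strength of
drift, i.e. through N·m.

For this parameterisation the two-lineage structured coalescent gives, for
the island model, E[T_within] = 2Nd and E[T_between] = 2Nd + (d−1)/(2m),
hence an expected Hudson F_ST of

    F_ST = 1 / (1 + 4Nm · d/(d−1)),

which the simulator reproduces (tested within 3 SE over 20 replicates;
`mean_fst` implements the Bhatia–Hudson ratio-of-averages estimator).

Spatial patterns:

* **random** — coordinates uniform on a square, independent of the
  genotypes: no structure, used for type-I error.  Because coordinates are
  independent of genotypes, the permutation test is *exact* here and its
  p-values are uniform on the (B+1)-grid by construction.
* **global** — the square is split into contiguous blocks (quadrants for 4
  demes; strips in gradient mode) and each deme's individuals are placed in
  their own block: patches/gradients with positive autocorrelation.
* **local** — the network itself is adversarial: units are neighbours iff
  their Euclidean genetic distance lies in the upper quartile of all
  pairwise distances, so neighbours are maximally dissimilar; a 1-D layout
  on the first genetic PC is carried along for reporting.

## Study sizes and what they show

The bundled benchmark runs at desk scale: type-I cells use 200 replicates ×
199 permutations, power cells 100 replicates × 199 permutations, against
the original design of 1000 × 1000.  Monte-Carlo error on a proportion is
therefore ~±0.03 at the 0.05 level; the acceptance comparisons use binomial
intervals at these sizes.  The panmixia check uses migration rate 1.0
(expected F_ST ≈ 0.002), already far beyond the panmixia threshold.

What the simulator does *not* emulate: linkage, mutation-model detail
(every locus is forced biallelic and segregating), unequal deme sizes,
continuous-space dispersal kernels (the IBD lattice is a discretisation),
and the original simulators' exact drift/mutation balance.  The last point
matters quantitatively: with N = 100 the weak-migration regime m = 0.1
still yields F_ST ≈ 1/(1 + 4·100·0.1·4/3) ≈ 0.018, comfortably above the
detection floor of a 100 × 200 dataset (~0.005), so the test retains power
≈ 1 there, whereas the original study's parameterisation left m = 0.1
barely detectable (power ≈ 0.13).  Power comparisons with the original
tables are therefore directional (more loci ⇒ no less power; power
non-increasing in m; strong-migration cells near 1), not value-for-value;
type-I error comparisons are unaffected because the permutation test is
exact under the random pattern regardless of the genetic model.

## Reproducibility

All randomness flows from a single seed.  The power harness derives one
child seed per (cell, replicate) pair counter-style from the master seed
(via `SeedSequence(master, spawn_key=(crc32(cell), rep))`), so extending
`n_reps` or re-running a subset of cells reproduces earlier replicates
bit-for-bit; each replicate splits its child into a data seed and a
permutation seed.  Reports embed the fully resolved run configuration.

## Known limitations

* Populations-as-units analyses treat per-population allele frequencies as
  plain rows (haploid convention); no weighting by sample size per
  population.
* Missing genotypes are either an error or column-mean imputed; no
  model-based imputation.
* Only biallelic loci; multi-allelic sites in VCF input are skipped.
* The negative-side (local) power of the benchmark is sensitive to the
  adversarial-network construction; isolated-unit dropping slightly changes
  n between replicates.
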