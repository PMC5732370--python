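"""Synthetic genetic data and spatial patterns for the benchmarking study.

Genotypes are drawn from structured-coalescent models via msprime, one
independent genealogy per unlinked locus with a single mutation placed
uniformly on the branches (infinite sites, conditioned on segregating), so
every locus is a biallelic SNP:

* IS  — island model: d demes, total immigration rate m split equally over
        the other d-1 demes;
* SS  — stepping-stone: demes on a chain (optionally a ring), each deme's
        total immigration m split over its neighbours;
* IBD — isolation by distance: a 10 x 10 lattice of demes with
        nearest-neighbour migration, one diploid sampled per deme.

Spatial patterns mirror the benchmark design: ``random`` coordinates carry
no structure (type-I error), ``global`` coordinates segregate demes into
contiguous blocks (patches/gradients, positive autocorrelation), and
``local`` builds a network joining the most genetically distinct pairs
(negative autocorrelation).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import msprime
import numpy as np
import pandas as pd

from .genodata import CentredFreqMatrix, GenotypeTable, ValidationError, centre_frequencies
from .randtest import spca_randtest
from .spatial import CoordinateSet, SpatialWeights, knn_graph, weights_from_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "SimulatedDataset",
    "simulate_snps",
    "random_coordinates",
    "patched_coordinates",
    "local_pattern_graph",
    "power_study",
    "mean_fst",
    "default_knn_k",
]

IBD_LATTICE_SIDE = 10


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation design.

    Defaults mirror the benchmark: 4 demes x 25 diploids (IS/SS) or a
    10 x 10 lattice totalling 100 individuals (IBD), 200 unlinked biallelic
    SNPs, diploid deme size ``deme_size`` (the simulator's stand-in for the
    original scaled-mutation parameterisation), migration rates in
    {0.005, 0.01, 0.1}.
    """

    model: str = "SS"  # IS | SS | IBD
    migration_rate: float = 0.005
    n_demes: int = 4
    per_deme: int = 25
    n_loci: int = 200
    deme_size: int = 100
    pattern: str = "random"  # random | global | local
    grid_scale: float = 1.0
    ss_ring: bool = False
    gradient: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("IS", "SS", "IBD"):
            raise ValidationError(f"unknown migration model {self.model!r}")
        if self.pattern not in ("random", "global", "local"):
            raise ValidationError(f"unknown spatial pattern {self.pattern!r}")
        if self.migration_rate <= 0:
            raise ValidationError("migration rate must be positive")
        if self.n_demes < 2 or self.per_deme < 1 or self.n_loci < 1:
            raise ValidationError("invalid scenario dimensions")

    @property
    def n_individuals(self) -> int:
        if self.model == "IBD":
            return IBD_LATTICE_SIDE**2
        return self.n_demes * self.per_deme

    @property
    def deme_labels(self) -> np.ndarray:
        if self.model == "IBD":
            return np.arange(IBD_LATTICE_SIDE**2)
        return np.repeat(np.arange(self.n_demes), self.per_deme)


@dataclass
class SimulatedDataset:
    """Genotypes, coordinates, network and the ground-truth pattern label."""

    genotypes: GenotypeTable
    coords: CoordinateSet
    weights: SpatialWeights
    truth: str  # random | global | local


# ---------------------------------------------------------------------------
# coalescent genotype simulation


def _demography(s: SimScenario) -> tuple[msprime.Demography, dict[str, int]]:
    if s.model == "IS":
        d = s.n_demes
        dem = msprime.Demography.isolated_model([s.deme_size] * d)
        rate = s.migration_rate / (d - 1)
        for i in range(d):
            for j in range(d):
                if i != j:
                    dem.migration_matrix[i, j] = rate
        samples = {f"pop_{i}": s.per_deme for i in range(d)}
    elif s.model == "SS":
        d = s.n_demes
        dem = msprime.Demography.isolated_model([s.deme_size] * d)
        neighbours = [[] for _ in range(d)]
        for i in range(d - 1):
            neighbours[i].append(i + 1)
            neighbours[i + 1].append(i)
        if s.ss_ring and d > 2:
            neighbours[0].append(d - 1)
            neighbours[d - 1].append(0)
        for i, nb in enumerate(neighbours):
            for j in nb:
                dem.migration_matrix[i, j] = s.migration_rate / len(nb)
        samples = {f"pop_{i}": s.per_deme for i in range(d)}
    else:  # IBD lattice
        side = IBD_LATTICE_SIDE
        dem = msprime.Demography.isolated_model([s.deme_size] * side * side)
        for i in range(side):
            for j in range(side):
                u = i * side + j
                nb = []
                if i > 0:
                    nb.append(u - side)
                if i < side - 1:
                    nb.append(u + side)
                if j > 0:
                    nb.append(u - 1)
                if j < side - 1:
                    nb.append(u + 1)
                for v in nb:
                    dem.migration_matrix[u, v] = s.migration_rate / len(nb)
        samples = {f"pop_{u}": 1 for u in range(side * side)}
    return dem, samples


def _drop_single_mutation(ts, rng: np.random.Generator, dosage_col: np.ndarray) -> None:
    """Place one mutation uniformly on the branches of the (single) tree."""
    tree = ts.first()
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lengths = np.array([tree.branch_length(u) for u in nodes])
    u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
    carriers = np.fromiter(tree.samples(u), dtype=np.int64)
    individuals = ts.tables.nodes.individual[carriers]
    np.add.at(dosage_col, individuals, 1)


def simulate_snps(s: SimScenario, seed: int | None = None) -> GenotypeTable:
    """Simulate unlinked biallelic diploid SNPs under the scenario's model.

    Each locus is an independent structured-coalescent genealogy of the 2n
    sampled gene copies; one mutation is placed uniformly at random on its
    branches, which conditions every locus on being segregating.  Dosages
    pair gene copies within diploid individuals.
    """
    if seed is None:
        seed = s.seed
    ss = np.random.SeedSequence(seed)
    msp_seed = int(ss.generate_state(1)[0] % (2**31 - 1)) + 1
    rng = np.random.default_rng(ss.spawn(1)[0])
    dem, samples = _demography(s)
    n = s.n_individuals
    dosages = np.zeros((n, s.n_loci), dtype=float)
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        num_replicates=s.n_loci,
        random_seed=msp_seed,
    )
    for locus, ts in enumerate(replicates):
        _drop_single_mutation(ts, rng, dosages[:, locus])
    unit_ids = [f"ind_{i:03d}" for i in range(n)]
    locus_ids = [f"snp_{j:04d}" for j in range(s.n_loci)]
    return GenotypeTable(unit_ids=unit_ids, dosages=dosages, locus_ids=locus_ids)


def mean_fst(g: GenotypeTable, deme_labels: Sequence[int]) -> float:
    """Hudson-type FST, ratio of averages over loci and deme pairs."""
    labels = np.asarray(deme_labels)
    dosage = g.dosages
    pops = np.unique(labels)
    if pops.size < 2:
        raise ValidationError("FST requires at least two demes")
    num = den = 0.0
    for a in range(pops.size):
        for b in range(a + 1, pops.size):
            da = dosage[labels == pops[a]]
            db = dosage[labels == pops[b]]
            na, nb = g.ploidy * da.shape[0], g.ploidy * db.shape[0]
            p1, p2 = da.sum(0) / na, db.sum(0) / nb
            num += np.sum(
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (na - 1)
                - p2 * (1 - p2) / (nb - 1)
            )
            den += np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)


# ---------------------------------------------------------------------------
# spatial patterns


def random_coordinates(
    n: int, grid_scale: float = 1.0, seed: int | np.random.Generator | None = None
) -> CoordinateSet:
    """n points uniform on a square of side grid_scale (no spatial signal)."""
    if n < 3:
        raise ValidationError("need at least 3 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = rng.uniform(0.0, grid_scale, size=(n, 2))
    return CoordinateSet(unit_ids=[f"ind_{i:03d}" for i in range(n)], xy=xy)


def patched_coordinates(
    s: SimScenario, seed: int | np.random.Generator | None = None
) -> CoordinateSet:
    """Spatially segregated deme blocks: the 'global' benchmark pattern.

    The square is partitioned into contiguous blocks (quadrants for four
    demes) and every deme's individuals are placed uniformly inside their
    own block; in gradient mode the blocks are strips ordered along x.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = s.deme_labels
    n_blocks = int(labels.max()) + 1
    scale = s.grid_scale
    xy = np.empty((labels.size, 2))
    if s.gradient:
        width = scale / n_blocks
        for d in range(n_blocks):
            sel = labels == d
            xy[sel, 0] = rng.uniform(d * width, (d + 1) * width, size=int(sel.sum()))
            xy[sel, 1] = rng.uniform(0.0, scale, size=int(sel.sum()))
    else:
        ncol = int(np.ceil(np.sqrt(n_blocks)))
        nrow = int(np.ceil(n_blocks / ncol))
        bw, bh = scale / ncol, scale / nrow
        for d in range(n_blocks):
            r, c = divmod(d, ncol)
            sel = labels == d
            xy[sel, 0] = rng.uniform(c * bw, (c + 1) * bw, size=int(sel.sum()))
            xy[sel, 1] = rng.uniform(r * bh, (r + 1) * bh, size=int(sel.sum()))
    return CoordinateSet(unit_ids=[f"ind_{i:03d}" for i in range(labels.size)], xy=xy)


def local_pattern_graph(
    g: GenotypeTable,
) -> tuple[SpatialWeights, CoordinateSet, list[str]]:
    """Adversarial 'local' network: neighbours are the most distinct pairs.

    Units i, j are neighbours iff their Euclidean genetic distance on the
    centred frequencies falls in the upper quartile of all pairwise
    distances, which makes neighbouring units maximally dissimilar (negative
    autocorrelation by construction).  Isolated units are dropped with a
    warning.  Returns the row-standardised weights, the 1-D layout given by
    the first genetic PC (second coordinate zero), and the retained ids.
    """
    if g.n_units < 8:
        raise ValidationError("local pattern graph requires at least 8 units")
    cf = centre_frequencies(g)
    X = cf.X
    from scipy.spatial.distance import pdist, squareform

    condensed = pdist(X)
    if np.all(condensed == 0):
        raise ValidationError("degenerate genotypes: all units identical")
    cut = np.quantile(condensed, 0.75)
    D = squareform(condensed)
    A = (D >= cut).astype(float)
    np.fill_diagonal(A, 0.0)
    keep = A.sum(axis=1) > 0
    if not keep.all():
        logger.warning(
            "dropping %d isolated unit(s) from the local-pattern network",
            int((~keep).sum()),
        )
        A = A[np.ix_(keep, keep)]
    kept_ids = [u for u, k in zip(cf.unit_ids, keep) if k]
    weights = weights_from_adjacency(A, standardise=True)
    weights.graph_spec.update(method="genetic_upper_quartile", cut=float(cut))
    # 1-D layout on the first genetic PC, for reporting
    _, _, Vt = np.linalg.svd(X[keep] - X[keep].mean(axis=0), full_matrices=False)
    pc1 = (X[keep] - X[keep].mean(axis=0)) @ Vt[0]
    coords = CoordinateSet(
        unit_ids=kept_ids, xy=np.column_stack([pc1, np.zeros(pc1.size)])
    )
    return weights, coords, kept_ids


def default_knn_k(n: int) -> int:
    """Default connection-network density: k = max(1, round(sqrt(n)))."""
    return max(1, int(round(np.sqrt(n))))


def build_dataset(s: SimScenario, seed: int | None = None) -> SimulatedDataset:
    """Simulate one replicate: genotypes + pattern coordinates + network."""
    if seed is None:
        seed = s.seed
    ss = np.random.SeedSequence(seed)
    geno_seed, coord_seed = ss.spawn(2)
    g = simulate_snps(s, seed=int(geno_seed.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(coord_seed)
    if s.pattern == "local":
        weights, coords, kept = local_pattern_graph(g)
        if len(kept) < g.n_units:
            sel = [g.unit_ids.index(u) for u in kept]
            g = GenotypeTable(
                unit_ids=kept,
                dosages=g.dosages[sel],
                locus_ids=list(g.locus_ids),
                ploidy=g.ploidy,
            )
        return SimulatedDataset(g, coords, weights, truth="local")
    if s.pattern == "random":
        coords = random_coordinates(g.n_units, s.grid_scale, rng)
    else:
        coords = patched_coordinates(s, rng)
    weights = knn_graph(coords, default_knn_k(g.n_units))
    return SimulatedDataset(g, coords, weights, truth=s.pattern)


# ---------------------------------------------------------------------------
# power / type-I-error study


def _replicate_seed(master: int, cell_key: tuple, rep: int) -> np.random.SeedSequence:
    """Counter-based child seed, stable under n_reps extension and cell subsetting."""
    cell_id = zlib.crc32(repr(cell_key).encode())
    return np.random.SeedSequence(entropy=master, spawn_key=(cell_id, rep))


def power_study(
    models: Iterable[str] = ("SS",),
    rates: Iterable[float] = (0.005, 0.01, 0.1),
    patterns: Iterable[str] = ("random", "global", "local"),
    n_reps: int = 100,
    B: int = 999,
    alphas: Iterable[float] = (0.05, 0.01),
    n_loci_list: Iterable[int] = (200,),
    seed: int = 0,
    scenario_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rejection-rate study over a grid of simulation scenarios.

    For every (model, rate, pattern, loci) cell, simulates ``n_reps``
    replicates, runs the eigenvalue permutation test with ``B``
    permutations, and tabulates the proportion of replicates with p <=
    alpha, separately for the global (+) and local (-) statistics.  Returns
    a long-format results table and a histogram of how many leading axes
    the Bonferroni cascade finds significant per rank and side.
    """
    if n_reps < 20:
        raise ValidationError("n_reps must be at least 20")
    if B < 99:
        raise ValidationError("B must be at least 99")
    alphas = list(alphas)
    scenario_kwargs = scenario_kwargs or {}
    rows = []
    hist_rows = []
    cells = [
        (model, rate, pattern, loci)
        for model in models
        for rate in rates
        for pattern in patterns
        for loci in n_loci_list
    ]
    for model, rate, pattern, loci in cells:
        scenario = SimScenario(
            model=model,
            migration_rate=rate,
            pattern=pattern,
            n_loci=loci,
            **scenario_kwargs,
        )
        p_global = np.empty(n_reps)
        p_local = np.empty(n_reps)
        nsig_pos = np.zeros(n_reps, dtype=int)
        nsig_neg = np.zeros(n_reps, dtype=int)
        for rep in range(n_reps):
            child = _replicate_seed(seed, (model, rate, pattern, loci), rep)
            data_seed, perm_seed = child.spawn(2)
            ds = build_dataset(scenario, seed=int(data_seed.generate_state(1)[0] % (2**31)))
            X = centre_frequencies(ds.genotypes)
            result = spca_randtest(
                X,
                ds.weights,
                B=B,
                alpha=max(alphas),
                seed=np.random.default_rng(perm_seed),
            )  # cascade counts gated at the loosest alpha of the grid

            p_global[rep] = result.p_global
            p_local[rep] = result.p_local
            nsig_pos[rep] = bonferroni_hist_count(result, "pos")
            nsig_neg[rep] = bonferroni_hist_count(result, "neg")
        for alpha in alphas:
            for side, pvals in (("pos", p_global), ("neg", p_local)):
                rows.append(
                    {
                        "model": model,
                        "rate": rate,
                        "pattern": pattern,
                        "loci": loci,
                        "alpha": alpha,
                        "side": side,
                        "proportion_significant": float(np.mean(pvals <= alpha)),
                        "n_reps": n_reps,
                        "B": B,
                        "seed": seed,
                    }
                )
        for side, counts in (("pos", nsig_pos), ("neg", nsig_neg)):
            for rank in range(1, int(counts.max(initial=0)) + 1):
                hist_rows.append(
                    {
                        "model": model,
                        "rate": rate,
                        "pattern": pattern,
                        "loci": loci,
                        "side": side,
                        "rank": rank,
                        "frequency": float(np.mean(counts >= rank)),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


def bonferroni_hist_count(result, side: str) -> int:
    return result.n_sig_pos if side == "pos" else result.n_sig_neg
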