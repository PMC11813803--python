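"""Generation cycles of multinucleate (coenocytic) fungal colonies.

Colonies carry nuclei of several neutral genotypes in one cytoplasm.  Each
generation is a germination–growth–sporulation cycle: a spore of ``N_s``
nuclei germinates, the colony grows by repeated nuclear divisions in which
every new nucleus copies a uniformly chosen existing one (Polya-urn growth,
so genotype frequency is a martingale), pairs of colonies may fuse their
hyphae (anastomosis) and exchange nuclei — the biological realization of
cooperative resetting, averaging genotype fractions pairwise — and finally a
random subset of nuclei is emitted as the next generation's spore.

Without fusion each colony is an absorbing Markov chain and genotypes fix
within tens of generations; with fusion the distribution of genotype
fractions localizes around the population mean, preserving heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColonyState",
    "FungalParams",
    "GenerationReport",
    "FixationEstimate",
    "grow_colony",
    "sporulate",
    "anastomose",
    "run_generations",
    "mutant_fixation_probability",
]


@dataclass
class ColonyState:
    """Nucleus counts per genotype of one colony."""

    genotype_counts: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_counts = np.asarray(self.genotype_counts, dtype=np.int64)
        if np.any(self.genotype_counts < 0):
            raise ValueError("nucleus counts must be non-negative")
        if self.total == 0:
            raise ValueError("colony must contain at least one nucleus")

    @property
    def total(self) -> int:
        return int(self.genotype_counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.genotype_counts / self.total

    @property
    def fixed(self) -> bool:
        return bool((self.genotype_counts > 0).sum() == 1)


@dataclass
class FungalParams:
    """Population parameters.

    Defaults follow physiological estimates for coenocytic fungi: 2.5e4
    colonies, spores of 5–20 nuclei (default 20), a growth phase of 7 nuclear
    divisions (a 128-fold increase), anastomosis probability 12–50% (default
    25%), 25 generations, two neutral genotypes started at equal fractions.
    """

    n_colonies: int = 25_000
    spore_size: int = 20
    division_rounds: int = 7
    p_anastomosis: float = 0.25
    generations: int = 25
    n_genotypes: int = 2
    initial_fractions: tuple[float, ...] = (0.5, 0.5)
    fusion_timing: str = "after_growth"  # or "after_germination"
    averaging_mode: str = "pool_split"  # or "deterministic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.spore_size < 1:
            raise ValueError("spore_size must be >= 1")
        if not 0 <= self.p_anastomosis <= 1:
            raise ValueError("p_anastomosis must lie in [0, 1]")
        if len(self.initial_fractions) != self.n_genotypes:
            raise ValueError("initial_fractions must have one entry per genotype")
        if abs(sum(self.initial_fractions) - 1.0) > 1e-9:
            raise ValueError("initial_fractions must sum to 1")
        if self.fusion_timing not in ("after_growth", "after_germination"):
            raise ValueError(f"unknown fusion_timing {self.fusion_timing!r}")
        if self.averaging_mode not in ("pool_split", "deterministic"):
            raise ValueError(f"unknown averaging_mode {self.averaging_mode!r}")


@dataclass
class GenerationReport:
    """Population snapshot after one generation's growth (and fusion)."""

    generation: int
    minor_fraction: np.ndarray  # per colony: 1 - max genotype share
    fraction_fixed: float
    heterozygosity: float  # mean of 1 - sum_i f_i^2 (= 2f(1-f) for 2 genotypes)

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_fixed <= 1:
            raise ValueError("fraction_fixed must lie in [0, 1]")


@dataclass
class FixationEstimate:
    probability: float
    se: float
    n_fixed: int
    n_lost: int
    n_censored: int


# ---------------------------------------------------------------------------
# single-colony operations


def grow_colony(
    spore: ColonyState,
    division_rounds: int,
    seed: int | None = None,
    method: str = "exact",
) -> ColonyState:
    """Grow a germinated spore by ``division_rounds`` doublings of the
    nucleus count via single-birth (Polya-urn) events.

    Each birth copies one existing nucleus chosen uniformly at random.  The
    exchangeability of the urn makes the added composition exactly
    Dirichlet-multinomial with the spore counts as weights, which is what
    ``method="exact"`` draws in O(1); ``method="sequential"`` performs the
    literal birth-by-birth chain (useful as an oracle at small sizes).
    Genotype frequency is a martingale under either path.
    """
    rng = np.random.default_rng(seed)
    counts = spore.genotype_counts.copy()
    n_new = spore.total * (2**division_rounds) - spore.total
    if method == "sequential":
        for _ in range(n_new):
            g = rng.choice(counts.size, p=counts / counts.sum())
            counts[g] += 1
    elif method == "exact":
        p = rng.dirichlet(counts.astype(float))
        counts += rng.multinomial(n_new, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ColonyState(genotype_counts=counts)


def sporulate(colony: ColonyState, spore_size: int, seed: int | None = None) -> ColonyState:
    """Draw a spore of ``spore_size`` nuclei without replacement
    (multivariate hypergeometric); an unbiased sample of the colony."""
    if spore_size > colony.total:
        raise ValueError(
            f"spore_size {spore_size} exceeds colony size {colony.total}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.multivariate_hypergeometric(colony.genotype_counts, spore_size)
    return ColonyState(genotype_counts=picked)


def anastomose(
    a: ColonyState,
    b: ColonyState,
    seed: int | None = None,
    averaging_mode: str = "pool_split",
) -> tuple[ColonyState, ColonyState]:
    """Fuse two colonies and redistribute their pooled nuclei.

    ``pool_split`` draws colony a's share hypergeometrically from the pooled
    nuclei (preserving integer counts and the demographic noise of a
    physical exchange); ``deterministic`` assigns each colony the pooled
    fractions rounded to integers.  Per-genotype totals are conserved
    exactly in both modes.
    """
    if a.genotype_counts.size != b.genotype_counts.size:
        raise ValueError("colonies must share a genotype alphabet")
    pooled = a.genotype_counts + b.genotype_counts
    if averaging_mode == "pool_split":
        rng = np.random.default_rng(seed)
        new_a = rng.multivariate_hypergeometric(pooled, a.total)
    elif averaging_mode == "deterministic":
        exact = pooled * (a.total / pooled.sum())
        new_a = np.floor(exact).astype(np.int64)
        rem = a.total - new_a.sum()
        order = np.argsort(-(exact - new_a))
        new_a[order[:rem]] += 1
    else:
        raise ValueError(f"unknown averaging_mode {averaging_mode!r}")
    return (
        ColonyState(genotype_counts=new_a),
        ColonyState(genotype_counts=pooled - new_a),
    )


# ---------------------------------------------------------------------------
# vectorized population kernels (two genotypes fast path, general fallback)


def _grow_counts(counts: np.ndarray, rounds: int, rng: np.random.Generator) -> np.ndarray:
    """Urn-grow all colonies: counts (n, g) -> counts * 2**rounds total."""
    totals = counts.sum(axis=1)
    n_new = totals * (2**rounds) - totals
    # Dirichlet weights via gammas: shape 0 yields weight 0, so absorbed
    # (single-genotype) colonies stay absorbed without special-casing
    gam = rng.standard_gamma(counts.astype(float))
    p = gam / gam.sum(axis=1, keepdims=True)
    if counts.shape[1] == 2:
        add0 = rng.binomial(n_new, p[:, 0])
        return counts + np.stack([add0, n_new - add0], axis=1)
    out = counts.copy()
    for i in range(counts.shape[0]):
        out[i] += rng.multinomial(n_new[i], p[i])
    return out


def _sporulate_counts(counts: np.ndarray, spore_size: int,
                      rng: np.random.Generator) -> np.ndarray:
    totals = counts.sum(axis=1)
    if np.any(totals < spore_size):
        raise ValueError("spore_size exceeds a colony size")
    if counts.shape[1] == 2:
        s0 = rng.hypergeometric(counts[:, 0], counts[:, 1], spore_size)
        return np.stack([s0, spore_size - s0], axis=1)
    out = np.empty((counts.shape[0], counts.shape[1]), dtype=np.int64)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], spore_size)
    return out


def _fuse_counts(counts: np.ndarray, pairs: np.ndarray,
                 rng: np.random.Generator, averaging_mode: str) -> np.ndarray:
    """Apply pool-and-split fusion to the listed colony index pairs."""
    out = counts.copy()
    if pairs.size == 0:
        return out
    a, b = pairs[:, 0], pairs[:, 1]
    pooled = counts[a] + counts[b]
    na = counts[a].sum(axis=1)
    if averaging_mode == "deterministic":
        exact = pooled * (na / pooled.sum(axis=1))[:, None]
        new_a = np.floor(exact).astype(np.int64)
        rem = na - new_a.sum(axis=1)
        for r in range(pairs.shape[0]):
            order = np.argsort(-(exact[r] - new_a[r]))
            new_a[r, order[: rem[r]]] += 1
    elif counts.shape[1] == 2:
        s0 = rng.hypergeometric(pooled[:, 0], pooled[:, 1], na)
        new_a = np.stack([s0, na - s0], axis=1)
    else:
        new_a = np.empty_like(pooled)
        for r in range(pairs.shape[0]):
            new_a[r] = rng.multivariate_hypergeometric(pooled[r], na[r])
    out[a] = new_a
    out[b] = pooled - new_a
    return out


def _initial_spores(params: FungalParams) -> np.ndarray:
    """Deterministic rounded split of the spore among genotypes."""
    exact = np.asarray(params.initial_fractions) * params.spore_size
    base = np.floor(exact).astype(np.int64)
    rem = params.spore_size - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return np.tile(base, (params.n_colonies, 1))


def run_generations(params: FungalParams) -> list[GenerationReport]:
    """Simulate the full population for ``params.generations`` cycles.

    Per generation and colony: germinate one spore, grow by urn doublings,
    enter the anastomosis pool with probability ``p_anastomosis`` (the pool
    is shuffled into pairs, an odd leftover skips), then sporulate.  Reports
    are taken on the grown (post-fusion) colonies.
    """
    rng = np.random.default_rng(params.seed)
    spores = _initial_spores(params)
    reports: list[GenerationReport] = []
    for gen in range(1, params.generations + 1):
        counts = spores
        if params.fusion_timing == "after_germination":
            counts = _anastomosis_round(counts, params, rng)
        counts = _grow_counts(counts, params.division_rounds, rng)
        if params.fusion_timing == "after_growth":
            counts = _anastomosis_round(counts, params, rng)
        reports.append(_report(gen, counts))
        spores = _sporulate_counts(counts, params.spore_size, rng)
    return reports


def _anastomosis_round(counts: np.ndarray, params: FungalParams,
                       rng: np.random.Generator) -> np.ndarray:
    if params.p_anastomosis == 0:
        return counts
    pool = np.nonzero(rng.random(counts.shape[0]) < params.p_anastomosis)[0]
    rng.shuffle(pool)
    n_pairs = pool.size // 2  # odd leftover skips
    pairs = pool[: 2 * n_pairs].reshape(n_pairs, 2)
    return _fuse_counts(counts, pairs, rng, params.averaging_mode)


def _report(gen: int, counts: np.ndarray) -> GenerationReport:
    totals = counts.sum(axis=1)
    frac = counts / totals[:, None]
    minor = 1.0 - frac.max(axis=1)
    het = 1.0 - (frac**2).sum(axis=1)
    return GenerationReport(
        generation=gen,
        minor_fraction=minor,
        fraction_fixed=float((minor == 0).mean()),
        heterozygosity=float(het.mean()),
    )


def mutant_fixation_probability(
    params: FungalParams,
    n_replicates: int,
    seed: int | None = None,
    max_generations: int | None = None,
) -> FixationEstimate:
    """Fate of a single neutral mutant nucleus introduced in one founder
    spore at generation 0.

    Without anastomosis colonies are independent, so each replicate tracks
    one colony until its spore line fixes or loses the mutant (colony-level
    fixation; by neutrality the probability is ``1/N_s``).  With anastomosis
    each replicate simulates the whole population; success is any colony
    reaching all-mutant, failure is population-wide loss.  Replicates still
    unresolved at the horizon are reported as censored and excluded from the
    estimate.
    """
    horizon = max_generations or max(20 * params.spore_size, params.generations)
    rng = np.random.default_rng(seed)
    if params.p_anastomosis == 0:
        return _fixation_independent(params, n_replicates, horizon, rng)
    return _fixation_population(params, n_replicates, horizon, rng)


def _fixation_independent(params: FungalParams, n_replicates: int,
                          horizon: int, rng: np.random.Generator) -> FixationEstimate:
    ns = params.spore_size
    spores = np.tile([1, ns - 1], (n_replicates, 1)).astype(np.int64)
    resolved = np.zeros(n_replicates, dtype=bool)
    fixed = np.zeros(n_replicates, dtype=bool)
    for _ in range(horizon):
        live = ~resolved
        if not live.any():
            break
        counts = _grow_counts(spores[live], params.division_rounds, rng)
        sp = _sporulate_counts(counts, ns, rng)
        spores[live] = sp
        mono = (spores[live] == 0).any(axis=1)
        idx = np.nonzero(live)[0][mono]
        resolved[idx] = True
        fixed[idx] = spores[idx, 0] == ns
    return _fixation_summary(fixed, resolved)


def _fixation_population(params: FungalParams, n_replicates: int,
                         horizon: int, rng: np.random.Generator) -> FixationEstimate:
    resolved = np.zeros(n_replicates, dtype=bool)
    fixed = np.zeros(n_replicates, dtype=bool)
    for r in range(n_replicates):
        spores = np.tile([0, params.spore_size], (params.n_colonies, 1)).astype(np.int64)
        spores[0] = (1, params.spore_size - 1)
        for _ in range(horizon):
            counts = spores
            if params.fusion_timing == "after_germination":
                counts = _anastomosis_round(counts, params, rng)
            counts = _grow_counts(counts, params.division_rounds, rng)
            if params.fusion_timing == "after_growth":
                counts = _anastomosis_round(counts, params, rng)
            if (counts[:, 1] == 0).any():  # a colony fixed the mutant
                resolved[r] = True
                fixed[r] = True
                break
            spores = _sporulate_counts(counts, params.spore_size, rng)
            if spores[:, 0].sum() == 0:  # mutant extinct population-wide
                resolved[r] = True
                break
    return _fixation_summary(fixed, resolved)


def _fixation_summary(fixed: np.ndarray, resolved: np.ndarray) -> FixationEstimate:
    n = fixed.size
    n_censored = int((~resolved).sum())
    n_fixed = int(fixed.sum())
    n_lost = n - n_censored - n_fixed
    n_res = n - n_censored
    if n_res == 0:
        raise RuntimeError("all replicates censored; extend the horizon")
    p = n_fixed / n_res
    se = math.sqrt(p * (1 - p) / n_res)
    return FixationEstimate(probability=p, se=se, n_fixed=n_fixed,
                            n_lost=n_lost, n_censored=n_censored)
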