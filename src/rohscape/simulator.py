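"""Individual-based forward Wright-Fisher simulation of one chromosome.

The engine evolves a diploid population on a single chromosome with
per-region recombination rates and a three-class distribution of
fitness effects (neutral / beneficial / deleterious, gamma-distributed
selection coefficients). Haplotypes are sorted arrays of mutation
tokens (position in the high bits), so recombination is a merge of
array slices and genotype output is a counting pass over tokens.

Three demographic scenarios mirror a wild red deer system: a large
stable population (Ne 7500), the focal island history (bottleneck to
Ne 100 for ~30 generations) and a severe bottleneck (Ne 10 for 5
generations, then Ne 100). Four models cross these with recombination
and selection: (1) neutral, constant recombination at 1.038 cM/Mb;
(2) neutral, 10-region recombination map; (3) the 10-region map plus a
gamma DFE (beneficial mean s +0.001, h 0.5; deleterious mean s -0.01,
h 0.1; neutral:beneficial:deleterious = 3:1:10); (4) as 3 with all
selection coefficients multiplied by five.

Rescaling (factor Q) divides the burn-in population size and duration
by Q while multiplying mutation rate, recombination rate and selection
coefficients by Q, preserving 4*Ne*mu, 4*Ne*r and 2*Ne*s. Bottleneck
epochs (already small) always run unrescaled. For desk-scale work the
burn-in can be replaced by an exact neutral equilibrium sample from
the coalescent (msprime); the forward engine then runs the
non-equilibrium epochs. Selection during the burn-in requires the
forward engine (optionally as a tail of generations appended after a
coalescent initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .diversity import PhasedHaplotypes
from .markers_io import GenotypeMatrix, MarkerMap

__all__ = [
    "RecombRegions", "DfeModel", "SimScenario", "SimPopulation", "SimResult",
    "build_scenario", "draw_mutation", "step_generation", "run_simulation",
    "equilibrium_population", "pairwise_diversity", "SimulationError",
    "DEER_MEAN_RECOMB_CM_PER_MB", "VARIED_RECOMB_CM_PER_MB",
]

#: Genome-wide mean recombination rate of red deer acrocentric autosomes.
DEER_MEAN_RECOMB_CM_PER_MB = 1.038

#: Broad-scale 10-region recombination profile (elevated peri-centromeric
#: rates at the proximal end of an acrocentric chromosome).
VARIED_RECOMB_CM_PER_MB = (1.75, 1.23, 0.89, 0.81, 0.74, 0.80, 0.87, 1.05,
                           1.20, 0.67)

_TOKEN_SHIFT = 21
_COUNTER_BASE = 1 << 20       # forward-time counters; coalescent site ids sit below
_COUNTER_SPAN = 1 << 20


class SimulationError(RuntimeError):
    """Raised when a simulation cannot proceed (e.g. zero total fitness)."""


# ---------------------------------------------------------------------------
# Recombination map


@dataclass(frozen=True)
class RecombRegions:
    """Piecewise-constant recombination map over [0, chromosome_length]."""

    region_ends_bp: tuple[float, ...]
    rates_cm_per_mb: tuple[float, ...]

    def __post_init__(self) -> None:
        ends = np.asarray(self.region_ends_bp, float)
        rates = np.asarray(self.rates_cm_per_mb, float)
        if len(ends) != len(rates) or len(ends) == 0:
            raise ValueError("region ends and rates must have equal length")
        if (np.diff(np.r_[0.0, ends]) <= 0).any():
            raise ValueError("region ends must be strictly increasing")
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")

    @classmethod
    def constant(cls, chromosome_length: float,
                 rate_cm_per_mb: float = DEER_MEAN_RECOMB_CM_PER_MB) -> "RecombRegions":
        return cls((float(chromosome_length),), (float(rate_cm_per_mb),))

    @classmethod
    def ten_region(cls, chromosome_length: float,
                   rates=VARIED_RECOMB_CM_PER_MB) -> "RecombRegions":
        edges = tuple(chromosome_length * (i + 1) / len(rates)
                      for i in range(len(rates)))
        return cls(edges, tuple(float(r) for r in rates))

    @property
    def chromosome_length(self) -> float:
        return self.region_ends_bp[-1]

    def scaled(self, q: float) -> "RecombRegions":
        return RecombRegions(self.region_ends_bp,
                             tuple(r * q for r in self.rates_cm_per_mb))

    def _rates_m_per_bp(self) -> np.ndarray:
        return np.asarray(self.rates_cm_per_mb, float) * 1e-8

    def total_morgans(self) -> float:
        lengths = np.diff(np.r_[0.0, np.asarray(self.region_ends_bp, float)])
        return float((lengths * self._rates_m_per_bp()).sum())

    def cumulative_morgans(self) -> np.ndarray:
        lengths = np.diff(np.r_[0.0, np.asarray(self.region_ends_bp, float)])
        return np.cumsum(lengths * self._rates_m_per_bp())

    def cm_at(self, bp: np.ndarray) -> np.ndarray:
        """Genetic position (cM) of physical positions under this map."""
        bp = np.asarray(bp, float)
        ends = np.asarray(self.region_ends_bp, float)
        starts = np.r_[0.0, ends[:-1]]
        cum_cm = np.r_[0.0, self.cumulative_morgans() * 100.0]
        region = np.searchsorted(ends, bp, side="left").clip(max=len(ends) - 1)
        rate_cm_per_bp = np.asarray(self.rates_cm_per_mb, float) * 1e-6
        return cum_cm[region] + (bp - starts[region]) * rate_cm_per_bp[region]

    def sample_crossovers(self, rng: np.random.Generator) -> np.ndarray:
        """Crossover bp positions of one meiosis (Poisson, no interference)."""
        total = self.total_morgans()
        k = rng.poisson(total)
        if k == 0:
            return np.empty(0)
        u = np.sort(rng.random(k) * total)
        cum = np.r_[0.0, self.cumulative_morgans()]
        region = np.searchsorted(cum[1:], u, side="right").clip(max=len(self.region_ends_bp) - 1)
        starts = np.r_[0.0, np.asarray(self.region_ends_bp, float)[:-1]]
        rates = self._rates_m_per_bp()
        with np.errstate(divide="ignore", invalid="ignore"):
            pos = starts[region] + (u - cum[region]) / rates[region]
        return pos[np.isfinite(pos)]

    def rate_map(self) -> msprime.RateMap:
        return msprime.RateMap(position=np.r_[0.0, np.asarray(self.region_ends_bp, float)],
                               rate=self._rates_m_per_bp())


# ---------------------------------------------------------------------------
# Distribution of fitness effects


@dataclass(frozen=True)
class DfeModel:
    """Three-class DFE with gamma-distributed selection coefficients."""

    class_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)  # neutral, beneficial, deleterious
    beneficial_mean_s: float = 0.001
    beneficial_shape: float = 0.2
    beneficial_h: float = 0.5
    deleterious_mean_s: float = -0.01
    deleterious_shape: float = 0.2
    deleterious_h: float = 0.1
    selection_multiplier: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("class weights must be non-negative, one positive")
        if self.beneficial_shape <= 0 or self.deleterious_shape <= 0:
            raise ValueError("gamma shapes must be positive")
        for h in (self.beneficial_h, self.deleterious_h):
            if not 0.0 <= h <= 1.0:
                raise ValueError("dominance must be in [0, 1]")

    @classmethod
    def neutral(cls) -> "DfeModel":
        return cls()

    @classmethod
    def deer_default(cls, selection_multiplier: float = 1.0) -> "DfeModel":
        """The 3:1:10 neutral:beneficial:deleterious mixture."""
        return cls(class_weights=(3.0, 1.0, 10.0),
                   selection_multiplier=selection_multiplier)

    @property
    def is_neutral(self) -> bool:
        return self.class_weights[1] == 0 and self.class_weights[2] == 0

    def draw(self, n: int, rng: np.random.Generator,
             extra_multiplier: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Vector draw of n (selection coefficient, dominance) pairs."""
        w = np.asarray(self.class_weights, float)
        cls_idx = rng.choice(3, size=n, p=w / w.sum())
        s = np.zeros(n)
        h = np.full(n, 0.5)
        mult = self.selection_multiplier * extra_multiplier
        ben = cls_idx == 1
        if ben.any():
            scale = self.beneficial_mean_s * mult / self.beneficial_shape
            s[ben] = rng.gamma(self.beneficial_shape, scale, size=int(ben.sum()))
            h[ben] = self.beneficial_h
        dele = cls_idx == 2
        if dele.any():
            scale = abs(self.deleterious_mean_s) * mult / self.deleterious_shape
            s[dele] = -rng.gamma(self.deleterious_shape, scale, size=int(dele.sum()))
            h[dele] = self.deleterious_h
        return s, h


def draw_mutation(dfe: DfeModel, rng: np.random.Generator) -> tuple[float, float]:
    """One (selection coefficient, dominance) draw from the DFE."""
    s, h = dfe.draw(1, rng)
    return float(s[0]), float(h[0])


# ---------------------------------------------------------------------------
# Scenario


@dataclass(frozen=True)
class SimScenario:
    """Full parameterisation of one simulation run.

    ``epochs`` are (start_generation, diploid Ne) on the nominal
    (unrescaled) generation axis; the first epoch is the burn-in.
    Under rescaling Q, the burn-in runs at Ne/Q for 1/Q as many
    generations with mu, r and s multiplied by Q; later epochs (the
    bottleneck endgame) run unrescaled.
    """

    name: str
    epochs: tuple[tuple[int, int], ...]
    n_generations_total: int
    chromosome_length: int = 100_000_000
    mutation_rate: float = 1e-8
    recomb: RecombRegions | None = None
    dfe: DfeModel = field(default_factory=DfeModel.neutral)
    sample_size: int = 100
    rescale_Q: int = 1
    seed: int = 1
    fixed_prune_interval: int = 100
    #: forward generations run at burn-in parameters after a coalescent
    #: initialisation (gives selection a scaled window to act in desk runs)
    burn_in_tail_generations: int = 0

    def __post_init__(self) -> None:
        if self.recomb is None:
            object.__setattr__(self, "recomb",
                               RecombRegions.constant(self.chromosome_length))
        if abs(self.recomb.chromosome_length - self.chromosome_length) > 0.5:
            raise ValueError("recombination map does not span the chromosome")
        if self.rescale_Q < 1:
            raise ValueError("rescale_Q must be >= 1")
        if not self.epochs or self.epochs[0][0] != 0:
            raise ValueError("epochs must start at generation 0")
        starts = [e[0] for e in self.epochs]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise ValueError("epoch starts must be strictly increasing")
        if any(ne < 2 for _, ne in self.epochs):
            raise ValueError("all Ne must be >= 2")
        if starts[-1] > self.n_generations_total:
            raise ValueError("epoch starts beyond the final generation")
        if self.mutation_rate * self.rescale_Q * self.chromosome_length < 0:
            raise ValueError("invalid mutation rate")

    @property
    def burn_in_ne(self) -> int:
        return max(2, round(self.epochs[0][1] / self.rescale_Q))

    @property
    def burn_in_generations(self) -> int:
        """Rescaled burn-in length (the nominal first-epoch span / Q)."""
        end = (self.epochs[1][0] if len(self.epochs) > 1
               else self.n_generations_total)
        return max(1, round(end / self.rescale_Q))

    @property
    def burn_in_mutation_rate(self) -> float:
        return self.mutation_rate * self.rescale_Q

    @property
    def burn_in_recomb(self) -> RecombRegions:
        return self.recomb.scaled(self.rescale_Q)

    def endgame_sizes(self) -> list[int]:
        """Per-generation population sizes after the burn-in (unrescaled)."""
        if len(self.epochs) == 1:
            return []
        start = self.epochs[1][0]
        sizes = []
        for g in range(start, self.n_generations_total + 1):
            ne = next(ne for s, ne in reversed(self.epochs) if s <= g)
            sizes.append(ne)
        return sizes


def build_scenario(name: str, model: int, rescale_Q: int = 1, seed: int = 1,
                   chromosome_length: int = 100_000_000,
                   **overrides) -> SimScenario:
    """Standard scenario x model grid.

    Scenarios: ``no_bottleneck`` (Ne 7500 throughout), ``rum`` (7500
    then 100 from generation 75,000) and ``severe_bottleneck`` (7500,
    then 10 at 75,000, then 100 from 75,005); all end at generation
    75,030. Models: 1 constant recombination + neutral; 2 ten-region
    map + neutral; 3 ten-region map + DFE; 4 as 3 with selection
    coefficients x5.
    """
    demographies = {
        "no_bottleneck": (((0, 7500),), 7500),
        "rum": (((0, 7500), (75_000, 100)), 100),
        "severe_bottleneck": (((0, 7500), (75_000, 10), (75_005, 100)), 100),
    }
    if name not in demographies:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(demographies)}")
    epochs, sample_size = demographies[name]
    if name == "no_bottleneck":
        sample_size = 7500

    if model == 1:
        recomb = RecombRegions.constant(chromosome_length)
        dfe = DfeModel.neutral()
    elif model == 2:
        recomb = RecombRegions.ten_region(chromosome_length)
        dfe = DfeModel.neutral()
    elif model == 3:
        recomb = RecombRegions.ten_region(chromosome_length)
        dfe = DfeModel.deer_default(1.0)
    elif model == 4:
        recomb = RecombRegions.ten_region(chromosome_length)
        dfe = DfeModel.deer_default(5.0)
    else:
        raise ValueError(f"unknown model {model!r}; choose 1-4")

    params = dict(name=f"{name}_model{model}", epochs=epochs,
                  n_generations_total=75_030,
                  chromosome_length=chromosome_length, recomb=recomb, dfe=dfe,
                  sample_size=sample_size, rescale_Q=rescale_Q, seed=seed)
    params.update(overrides)
    return SimScenario(**params)


# ---------------------------------------------------------------------------
# Population state


class _Registry:
    """Selected-mutation registry: token -> (selection coefficient, dominance)."""

    def __init__(self) -> None:
        self.tokens = np.empty(0, dtype=np.int64)
        self.s = np.empty(0)
        self.h = np.empty(0)

    def add(self, tokens: np.ndarray, s: np.ndarray, h: np.ndarray) -> None:
        if len(tokens) == 0:
            return
        tokens = np.concatenate([self.tokens, tokens])
        s = np.concatenate([self.s, s])
        h = np.concatenate([self.h, h])
        order = np.argsort(tokens, kind="stable")
        self.tokens, self.s, self.h = tokens[order], s[order], h[order]

    def lookup(self, tokens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.tokens, tokens)
        return self.s[idx], self.h[idx]

    def drop(self, tokens: np.ndarray) -> None:
        keep = ~np.isin(self.tokens, tokens, assume_unique=False)
        self.tokens, self.s, self.h = (self.tokens[keep], self.s[keep],
                                       self.h[keep])


@dataclass
class SimPopulation:
    """Diploid population: individual i owns haplotype rows 2i and 2i+1.

    ``haplotypes`` are sorted int64 token arrays (token = bp << 21 |
    counter); ``selected`` holds the subset of tokens under selection,
    kept in parallel so fitness never scans neutral mutations. Fixed
    mutations are pruned periodically but counted.
    """

    haplotypes: list[np.ndarray]
    selected: list[np.ndarray]
    registry: _Registry
    generation: int = 0
    n_fixed_pruned: int = 0
    mutation_counter: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.haplotypes) // 2

    @classmethod
    def founders(cls, n_individuals: int) -> "SimPopulation":
        empty = np.empty(0, dtype=np.int64)
        return cls(haplotypes=[empty] * (2 * n_individuals),
                   selected=[empty] * (2 * n_individuals),
                   registry=_Registry())

    def fitness(self) -> np.ndarray:
        """Multiplicative fitness; factors (1, 1+hs, 1+s), floored at 0."""
        n = self.n_individuals
        w = np.ones(n)
        if len(self.registry.tokens) == 0:
            return w
        for i in range(n):
            a, b = self.selected[2 * i], self.selected[2 * i + 1]
            if len(a) == 0 and len(b) == 0:
                continue
            merged = np.sort(np.concatenate([a, b]), kind="stable")
            dup = np.zeros(len(merged), dtype=bool)
            dup[1:] = merged[1:] == merged[:-1]
            hom = merged[dup]
            het = merged[~dup & ~np.r_[dup[1:], False]]
            factors = []
            if len(hom):
                s_hom, _ = self.registry.lookup(hom)
                factors.append(1.0 + s_hom)
            if len(het):
                s_het, h_het = self.registry.lookup(het)
                factors.append(1.0 + h_het * s_het)
            if factors:
                fac = np.concatenate(factors)
                w[i] = 0.0 if (fac <= 0).any() else float(np.prod(fac))
        return w

    def prune_fixed(self) -> int:
        """Remove mutations carried by every haplotype; return the count."""
        n_hap = len(self.haplotypes)
        if n_hap == 0:
            return 0
        tokens, counts = np.unique(np.concatenate(self.haplotypes),
                                   return_counts=True)
        fixed = tokens[counts == n_hap]
        if len(fixed) == 0:
            return 0
        for i, hap in enumerate(self.haplotypes):
            idx = np.searchsorted(hap, fixed)
            self.haplotypes[i] = np.delete(hap, idx)
        for i, sel in enumerate(self.selected):
            mask = np.isin(sel, fixed, assume_unique=True)
            if mask.any():
                self.selected[i] = sel[~mask]
        self.registry.drop(fixed)
        self.n_fixed_pruned += len(fixed)
        return len(fixed)


def _make_gamete(pop: SimPopulation, parent: int, crossovers: np.ndarray,
                 start_hap: int) -> tuple[np.ndarray, np.ndarray]:
    a_full = pop.haplotypes[2 * parent + start_hap]
    b_full = pop.haplotypes[2 * parent + 1 - start_hap]
    a_sel = pop.selected[2 * parent + start_hap]
    b_sel = pop.selected[2 * parent + 1 - start_hap]
    if len(crossovers) == 0:
        return a_full, a_sel
    cuts = (crossovers.astype(np.int64) << _TOKEN_SHIFT)
    out_full, out_sel = [], []
    sources = ((a_full, a_sel), (b_full, b_sel))
    bounds = np.r_[np.int64(np.iinfo(np.int64).min), cuts,
                   np.int64(np.iinfo(np.int64).max)]
    for seg in range(len(bounds) - 1):
        full, sel = sources[seg % 2]
        lo, hi = np.searchsorted(full, (bounds[seg], bounds[seg + 1]))
        if hi > lo:
            out_full.append(full[lo:hi])
        lo, hi = np.searchsorted(sel, (bounds[seg], bounds[seg + 1]))
        if hi > lo:
            out_sel.append(sel[lo:hi])
    full = np.concatenate(out_full) if out_full else np.empty(0, np.int64)
    sel = np.concatenate(out_sel) if out_sel else np.empty(0, np.int64)
    return full, sel


def step_generation(pop: SimPopulation, target_ne: int, mutation_rate: float,
                    recomb: RecombRegions, dfe: DfeModel,
                    rng: np.random.Generator, chromosome_length: int,
                    s_multiplier: float = 1.0) -> SimPopulation:
    """Breed the next Wright-Fisher generation of ``target_ne`` diploids.

    Parents are drawn with probability proportional to multiplicative
    fitness; each transmitted gamete recombines with Poisson crossovers
    placed by local rate and receives Poisson(mu * L) new mutations at
    uniform positions.
    """
    if pop.n_individuals == 0:
        raise SimulationError("empty population")
    w = pop.fitness()
    total_w = w.sum()
    if total_w <= 0:
        raise SimulationError("population fitness collapsed to zero")
    p = w / total_w
    parents = rng.choice(pop.n_individuals, size=(target_ne, 2), p=p)
    mu_total = mutation_rate * chromosome_length
    n_new = rng.poisson(mu_total, size=2 * target_ne)
    start_haps = rng.integers(0, 2, size=2 * target_ne)

    new_haps: list[np.ndarray] = []
    new_sel: list[np.ndarray] = []
    counter = pop.mutation_counter
    reg_tokens, reg_s, reg_h = [], [], []
    for g in range(2 * target_ne):
        parent = parents[g // 2, g % 2]
        crossovers = recomb.sample_crossovers(rng)
        full, sel = _make_gamete(pop, parent, crossovers, int(start_haps[g]))
        k = int(n_new[g])
        if k:
            positions = rng.integers(1, chromosome_length + 1, size=k)
            tokens = ((positions.astype(np.int64) << _TOKEN_SHIFT)
                      | (_COUNTER_BASE + (counter + np.arange(k)) % _COUNTER_SPAN))
            counter += k
            tokens.sort()
            full = np.insert(full, np.searchsorted(full, tokens), tokens)
            if not dfe.is_neutral:
                s, h = dfe.draw(k, rng, extra_multiplier=s_multiplier)
                chosen = s != 0.0
                if chosen.any():
                    sel_tokens = tokens[chosen]
                    sel = np.insert(sel, np.searchsorted(sel, sel_tokens),
                                    sel_tokens)
                    reg_tokens.append(sel_tokens)
                    reg_s.append(s[chosen])
                    reg_h.append(h[chosen])
        new_haps.append(full)
        new_sel.append(sel)

    registry = pop.registry
    if reg_tokens:
        registry.add(np.concatenate(reg_tokens), np.concatenate(reg_s),
                     np.concatenate(reg_h))
    return SimPopulation(haplotypes=new_haps, selected=new_sel,
                         registry=registry, generation=pop.generation + 1,
                         n_fixed_pruned=pop.n_fixed_pruned,
                         mutation_counter=counter)


# ---------------------------------------------------------------------------
# Coalescent equilibrium initialisation


def equilibrium_population(ne: int, chromosome_length: int,
                           mutation_rate: float, recomb: RecombRegions,
                           seed: int, n_individuals: int | None = None,
                           ) -> SimPopulation:
    """Neutral mutation-drift equilibrium sample drawn via the coalescent.

    Exact replacement for a >= 10 Ne forward burn-in under neutrality:
    haplotype diversity, site-frequency spectrum and IBD tract structure
    all follow the stationary Wright-Fisher distribution for the given
    compound parameters.
    """
    n_individuals = ne if n_individuals is None else n_individuals
    ts = msprime.sim_ancestry(
        samples=n_individuals, population_size=ne,
        sequence_length=chromosome_length,
        recombination_rate=recomb.rate_map(),
        random_seed=max(1, seed % (2**31 - 1)))
    ts = msprime.sim_mutations(
        ts, rate=mutation_rate, model=msprime.BinaryMutationModel(),
        random_seed=max(1, (seed + 7919) % (2**31 - 1)))
    genotypes = ts.genotype_matrix()          # sites x haplotypes, {0,1}
    positions = ts.tables.sites.position.astype(np.int64)
    tokens_per_site = ((positions << _TOKEN_SHIFT)
                       | np.arange(len(positions), dtype=np.int64))
    haplotypes = [tokens_per_site[np.flatnonzero(genotypes[:, j])]
                  for j in range(genotypes.shape[1])]
    empty = np.empty(0, dtype=np.int64)
    return SimPopulation(haplotypes=haplotypes,
                         selected=[empty] * len(haplotypes),
                         registry=_Registry())


# ---------------------------------------------------------------------------
# Whole-run driver


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    haplotypes: PhasedHaplotypes
    population: SimPopulation
    scenario: SimScenario
    n_dropped_duplicate_bp: int = 0


def _emit_sample(pop: SimPopulation, scenario: SimScenario,
                 rng: np.random.Generator) -> SimResult:
    """Sample individuals and emit segregating sites as genotypes + map."""
    n = pop.n_individuals
    k = min(scenario.sample_size, n)
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    hap_rows = [pop.haplotypes[2 * i + j] for i in chosen for j in (0, 1)]
    if hap_rows and any(len(h) for h in hap_rows):
        all_tokens = np.concatenate(hap_rows)
    else:
        all_tokens = np.empty(0, dtype=np.int64)
    tokens, counts = np.unique(all_tokens, return_counts=True)
    seg = tokens[(counts > 0) & (counts < 2 * k)]
    bp = (seg >> _TOKEN_SHIFT)
    # collapse rare duplicate-bp sites so map positions stay strictly increasing
    keep = np.r_[True, np.diff(bp) > 0]
    seg, bp = seg[keep], bp[keep]
    n_dropped = int((~keep).sum())

    m = len(seg)
    hap_matrix = np.zeros((2 * k, m), dtype=np.int8)
    for row, hap in enumerate(hap_rows):
        pos = np.searchsorted(seg, hap)
        ok = (pos < m) & (seg[pos.clip(max=m - 1)] == hap) if m else np.zeros(len(hap), bool)
        hap_matrix[row, pos[ok]] = 1
    calls = (hap_matrix[0::2] + hap_matrix[1::2]).astype(np.int8)

    ids = [f"ind_{int(i)}" for i in chosen]
    marker_map = MarkerMap(pd.DataFrame({
        "chromosome": np.ones(m, dtype=int),
        "marker_id": [f"site_{j}" for j in range(m)],
        "bp_pos": bp,
        "cm_pos": scenario.recomb.cm_at(bp),
    }), n_autosomes=1)
    return SimResult(
        genotypes=GenotypeMatrix(calls, ids),
        marker_map=marker_map,
        haplotypes=PhasedHaplotypes(hap_matrix, ids),
        population=pop, scenario=scenario,
        n_dropped_duplicate_bp=n_dropped)


def run_simulation(scenario: SimScenario, burn_in: str = "coalescent",
                   initial_population: SimPopulation | None = None,
                   ) -> SimResult:
    """Run burn-in plus post-burn-in epochs and sample the final generation.

    ``burn_in``: "coalescent" draws the (neutral) equilibrium directly
    from the coalescent; "forward" runs the rescaled burn-in with the
    forward engine (required when the DFE should act during the
    burn-in). With a coalescent burn-in and a non-neutral DFE,
    ``scenario.burn_in_tail_generations`` forward generations at
    burn-in parameters give selection a window to act.

    ``initial_population`` skips the burn-in entirely and starts the
    post-burn-in epochs from the given equilibrium population (e.g. to
    run several demographic endgames from one equilibrium draw).
    """
    if burn_in not in ("coalescent", "forward"):
        raise ValueError("burn_in must be 'coalescent' or 'forward'")
    rng = np.random.default_rng(scenario.seed)
    q = scenario.rescale_Q
    l_chrom = scenario.chromosome_length

    if initial_population is not None:
        pop = initial_population
        for step in range(scenario.burn_in_tail_generations):
            pop = step_generation(pop, pop.n_individuals,
                                  scenario.burn_in_mutation_rate,
                                  scenario.burn_in_recomb, scenario.dfe, rng,
                                  l_chrom, s_multiplier=q)
            if (step + 1) % scenario.fixed_prune_interval == 0:
                pop.prune_fixed()
    elif burn_in == "forward":
        pop = SimPopulation.founders(scenario.burn_in_ne)
        for step in range(scenario.burn_in_generations):
            pop = step_generation(pop, scenario.burn_in_ne,
                                  scenario.burn_in_mutation_rate,
                                  scenario.burn_in_recomb, scenario.dfe, rng,
                                  l_chrom, s_multiplier=q)
            if (step + 1) % scenario.fixed_prune_interval == 0:
                pop.prune_fixed()
    else:
        pop = equilibrium_population(
            scenario.burn_in_ne, l_chrom, scenario.burn_in_mutation_rate,
            scenario.burn_in_recomb,
            seed=int(rng.integers(1, 2**31 - 1)))
        for step in range(scenario.burn_in_tail_generations):
            pop = step_generation(pop, scenario.burn_in_ne,
                                  scenario.burn_in_mutation_rate,
                                  scenario.burn_in_recomb, scenario.dfe, rng,
                                  l_chrom, s_multiplier=q)
            if (step + 1) % scenario.fixed_prune_interval == 0:
                pop.prune_fixed()

    for ne in scenario.endgame_sizes():
        pop = step_generation(pop, ne, scenario.mutation_rate, scenario.recomb,
                              scenario.dfe, rng, l_chrom, s_multiplier=1.0)
    pop.prune_fixed()
    return _emit_sample(pop, scenario, rng)


def pairwise_diversity(haplotypes: PhasedHaplotypes | np.ndarray,
                       sequence_length: float) -> float:
    """Mean pairwise diversity per site (unbiased) from 0/1 haplotypes."""
    alleles = haplotypes.alleles if isinstance(haplotypes, PhasedHaplotypes) else haplotypes
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    freq = alleles.mean(axis=0)
    per_site = 2.0 * freq * (1.0 - freq) * n / (n - 1)
    return float(per_site.sum() / sequence_length)
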