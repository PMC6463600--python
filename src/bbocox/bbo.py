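"""Binary biogeography-based optimization (BBO) over covariate subsets.

Each habitat is a 0/1 vector with one suitability index variable (SIV) per
covariate; its habitat suitability index (HSI) is the in-sample Harrell
C-statistic of a Cox model fitted on the selected covariates.  Migration
copies SIVs from emigration-prone (fit) habitats into immigration-prone
(unfit) ones; mutation redraws SIVs uniformly at a rate shrinking with the
stationary species-count probability; elitism preserves the best habitats
unchanged.  An exhaustive-search oracle over all 2^d subsets is provided for
small d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import (
    ConcordanceUndefinedError,
    CoxData,
    DegenerateDesignError,
    concordance,
    fit_cox,
)

__all__ = [
    "BBOParams",
    "MigrationModel",
    "Habitat",
    "BBORun",
    "ExhaustiveResult",
    "HSIEvaluator",
    "migration_rates",
    "species_count_probabilities",
    "mutation_rate",
    "rank_to_species_count",
    "migrate",
    "mutate",
    "evaluate_hsi",
    "run_bbo",
    "exhaustive_search",
]


@dataclass(frozen=True)
class BBOParams:
    """Search parameters; defaults follow the published configuration
    (population 50, 100 generations, E = I = 1, 2 elites, m_max = 0.04)."""

    population_size: int = 50
    generations: int = 100
    E: float = 1.0
    I: float = 1.0
    m_max: float = 0.04
    elites: int = 2
    p_mod: float = 1.0
    s_max: int | None = None  # None -> population_size
    seed: int = 0

    def __post_init__(self):
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population_size and generations must be positive")
        if not 0 <= self.elites < self.population_size:
            raise ValueError("elites must satisfy 0 <= elites < population_size")
        if not 0.0 <= self.m_max <= 1.0:
            raise ValueError("m_max must be in [0, 1]")
        if self.E <= 0 or self.I <= 0:
            raise ValueError("E and I must be positive")
        if not 0.0 <= self.p_mod <= 1.0:
            raise ValueError("p_mod must be in [0, 1]")

    @property
    def S_max(self) -> int:
        return self.population_size if self.s_max is None else self.s_max


def migration_rates(k: int, params: BBOParams) -> tuple[float, float]:
    """Linear migration model: immigration lambda_k = I(1 - k/S_max),
    emigration mu_k = E k/S_max for species count k."""
    S = params.S_max
    if not 0 <= k <= S:
        raise ValueError(f"species count {k} outside [0, {S}]")
    return params.I * (1.0 - k / S), params.E * k / S


def species_count_probabilities(params: BBOParams) -> np.ndarray:
    """Stationary distribution of the species-count birth-death chain.

    P_s is proportional to prod_{i=0}^{s-1} lambda_i / prod_{i=1}^{s} mu_i
    (empty products 1), normalized to sum to one.  For E = I this is the
    symmetric binomial shape over 0..S_max.
    """
    S = params.S_max
    k = np.arange(S + 1)
    lam = params.I * (1.0 - k / S)
    mu = params.E * k / S
    ratios = lam[:-1] / mu[1:]  # lambda_{s-1} / mu_s, s = 1..S
    nu = np.concatenate([[1.0], np.cumprod(ratios)])
    return nu / nu.sum()


@dataclass(frozen=True)
class MigrationModel:
    lambda_k: np.ndarray
    mu_k: np.ndarray
    P_s: np.ndarray
    P_max: float

    @classmethod
    def from_params(cls, params: BBOParams) -> "MigrationModel":
        k = np.arange(params.S_max + 1)
        lam = params.I * (1.0 - k / params.S_max)
        mu = params.E * k / params.S_max
        P = species_count_probabilities(params)
        return cls(lambda_k=lam, mu_k=mu, P_s=P, P_max=float(P.max()))


def mutation_rate(p_s_value: float, model: MigrationModel,
                  params: BBOParams) -> float:
    """m = m_max (1 - P_s / P_max): rare species counts mutate the most."""
    return params.m_max * (1.0 - p_s_value / model.P_max)


@dataclass
class Habitat:
    """One candidate subset: SIV bit vector plus its cached HSI and the
    rank-derived species count."""

    siv: np.ndarray
    hsi: float | None = None
    species_count: int | None = None

    def copy(self) -> "Habitat":
        return Habitat(self.siv.copy(), self.hsi, self.species_count)


class HSIEvaluator:
    """Memoized HSI: C-statistic of the Cox fit on the covariates a SIV
    vector selects, computed in-sample on one fixed cohort.

    The all-zero vector scores 0.5 (chance discrimination); degenerate or
    non-converged fits also score 0.5 and are recorded in ``flags``.  A fit
    stopped at the monotone-likelihood divergence bound keeps its (capped)
    linear predictor: the risk ordering it induces is the limit ordering, so
    the C-statistic remains well defined and informative.  Results are
    memoized by bit pattern, so repeated evaluations are exact cache hits
    and ``evaluations`` counts distinct Cox fits only.
    """

    def __init__(self, cohort: pd.DataFrame, ties: str = "breslow",
                 mode: str = "harrell"):
        self.data = CoxData.from_cohort(cohort)
        self.names = self.data.names
        self.d = len(self.names)
        self.ties = ties
        self.mode = mode
        self._memo: dict[bytes, float] = {}
        self.evaluations = 0
        self.flags: list[tuple[str, str]] = []

    def __call__(self, siv: np.ndarray) -> float:
        siv = np.asarray(siv)
        key = np.packbits(siv.astype(np.uint8)).tobytes()
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        self.evaluations += 1
        hsi = self._compute(siv)
        self._memo[key] = hsi
        return hsi

    def _subset(self, siv: np.ndarray) -> tuple[str, ...]:
        return tuple(n for n, b in zip(self.names, siv) if b)

    def _compute(self, siv: np.ndarray) -> float:
        subset = self._subset(siv)
        if not subset:
            return 0.5
        try:
            fit = fit_cox(self.data, subset, ties=self.ties)
        except DegenerateDesignError as e:
            self.flags.append(("degenerate", str(e)))
            return 0.5
        if fit.diverged:
            self.flags.append(("diverged", str(subset)))
        elif not fit.converged:
            self.flags.append(("not_converged", str(subset)))
            return 0.5
        try:
            res = concordance(self.data.time, self.data.event,
                              fit.linear_predictor[self.data.order],
                              mode=self.mode)
        except ConcordanceUndefinedError:
            self.flags.append(("undefined_concordance", str(subset)))
            return 0.5
        return res.c


def evaluate_hsi(siv: np.ndarray, cohort: pd.DataFrame,
                 ties: str = "breslow") -> float:
    """One-off HSI of a single SIV vector (builds a fresh evaluator)."""
    return HSIEvaluator(cohort, ties=ties)(siv)


def rank_to_species_count(population: list[Habitat],
                          params: BBOParams) -> list[int]:
    """Assign species counts by HSI rank: the best habitat hosts S_max
    species, the worst S_max - population_size + 1; HSI ties keep the
    stable order of the population list.  Mutates ``species_count`` in
    place and returns the rank order (indices, best first)."""
    if any(h.hsi is None for h in population):
        raise ValueError("all habitats must be evaluated before ranking")
    order = sorted(range(len(population)),
                   key=lambda i: (-population[i].hsi, i))
    for rank, i in enumerate(order):
        population[i].species_count = params.S_max - rank
    return order


def _roulette_sources(mu: np.ndarray, exclude: int, count: int,
                      rng: np.random.Generator,
                      log: list[str] | None = None) -> np.ndarray:
    w = mu.copy()
    w[exclude] = 0.0
    total = w.sum()
    if total <= 0.0:
        if log is not None:
            log.append("all emigration rates zero; uniform source selection")
        w = np.ones_like(w)
        w[exclude] = 0.0
        total = w.sum()
    cdf = np.cumsum(w / total)
    return np.searchsorted(cdf, rng.random(count), side="right")


def migrate(population: list[Habitat], model: MigrationModel,
            params: BBOParams, rng: np.random.Generator,
            elite_indices: set[int] | None = None,
            log: list[str] | None = None) -> list[int]:
    """In-place migration step; returns the indices of modified habitats.

    Each non-elite habitat is considered with probability ``p_mod``; each
    of its SIV positions immigrates independently with probability
    lambda_i (from its species count), the source habitat drawn by
    roulette wheel over the emigration rates mu_j of the other habitats.
    Sources are read from a pre-migration snapshot, so the operator is
    order-independent.  Elites are untouched.
    """
    elite_indices = elite_indices or set()
    snapshot = [h.siv.copy() for h in population]
    mu = np.array([model.mu_k[h.species_count] for h in population])
    touched = []
    for i, hab in enumerate(population):
        if i in elite_indices:
            continue
        if rng.random() >= params.p_mod:
            continue
        lam_i = model.lambda_k[hab.species_count]
        positions = np.nonzero(rng.random(hab.siv.size) < lam_i)[0]
        if positions.size == 0:
            continue
        sources = _roulette_sources(mu, i, positions.size, rng, log)
        new = hab.siv.copy()
        for pos, j in zip(positions, sources):
            new[pos] = snapshot[j][pos]
        if not np.array_equal(new, hab.siv):
            hab.siv = new
            hab.hsi = None
            touched.append(i)
    return touched


def mutate(population: list[Habitat], model: MigrationModel,
           params: BBOParams, rng: np.random.Generator,
           elite_indices: set[int] | None = None) -> list[int]:
    """In-place mutation step; returns indices of modified habitats.

    Each SIV position of a non-elite habitat is, with probability m (from
    its species-count probability), replaced by a fresh uniform 0/1 draw —
    the redraw may keep the current value.
    """
    elite_indices = elite_indices or set()
    touched = []
    for i, hab in enumerate(population):
        if i in elite_indices:
            continue
        m = mutation_rate(model.P_s[hab.species_count], model, params)
        if m <= 0.0:
            continue
        mask = rng.random(hab.siv.size) < m
        if not mask.any():
            continue
        new = hab.siv.copy()
        new[mask] = rng.integers(0, 2, int(mask.sum()), dtype=np.int8)
        if not np.array_equal(new, hab.siv):
            hab.siv = new
            hab.hsi = None
            touched.append(i)
    return touched


@dataclass
class BBORun:
    best: Habitat
    best_subset: tuple[str, ...]
    history: pd.DataFrame  # per-generation best/mean HSI
    evaluations: int
    params: BBOParams
    flags: list[tuple[str, str]] = field(default_factory=list)


def run_bbo(cohort: pd.DataFrame, params: BBOParams | None = None,
            ties: str = "breslow",
            evaluator: HSIEvaluator | None = None) -> BBORun:
    """Full BBO search for the covariate subset maximising the C-statistic.

    Per generation: rank habitats and assign species counts, set aside
    copies of the elite habitats, apply migration then mutation to the
    non-elites, re-evaluate, and reinsert the elites over the worst
    habitats.  Fully reproducible from ``params.seed``; distinct Cox fits
    are counted via the memoizing evaluator.
    """
    params = params or BBOParams()
    ev = evaluator if evaluator is not None else HSIEvaluator(cohort, ties=ties)
    d = ev.d
    if d < 1:
        raise ValueError("cohort has no covariate columns")
    rng = np.random.default_rng(params.seed)
    model = MigrationModel.from_params(params)
    log: list[str] = []

    population = [Habitat(rng.integers(0, 2, d, dtype=np.int8))
                  for _ in range(params.population_size)]
    for h in population:
        h.hsi = ev(h.siv)

    records = []
    for gen in range(params.generations):
        order = rank_to_species_count(population, params)
        elite_idx = set(order[: params.elites])
        elite_copies = [population[i].copy() for i in order[: params.elites]]

        migrate(population, model, params, rng, elite_idx, log)
        for h in population:
            if h.hsi is None:
                h.hsi = ev(h.siv)
        # species counts reflect the pre-operator ranking, as in the
        # published loop (rates are recomputed at the next generation)
        mutate(population, model, params, rng, elite_idx)
        for h in population:
            if h.hsi is None:
                h.hsi = ev(h.siv)

        # elites replace the worst post-operator habitats
        post_order = sorted(range(len(population)),
                            key=lambda i: (-population[i].hsi, i))
        for worst_i, elite in zip(reversed(post_order), elite_copies):
            population[worst_i] = elite.copy()

        hsis = np.array([h.hsi for h in population])
        records.append({"generation": gen, "best_hsi": float(hsis.max()),
                        "mean_hsi": float(hsis.mean())})

    best = max(population, key=lambda h: h.hsi).copy()
    history = pd.DataFrame(records)
    return BBORun(
        best=best,
        best_subset=tuple(n for n, b in zip(ev.names, best.siv) if b),
        history=history,
        evaluations=ev.evaluations,
        params=params,
        flags=ev.flags + [("migration", m) for m in log],
    )


@dataclass
class ExhaustiveResult:
    best_siv: np.ndarray
    best_subset: tuple[str, ...]
    best_hsi: float
    hsi_map: np.ndarray  # indexed by bit-pattern integer, bit j = covariate j


def exhaustive_search(cohort: pd.DataFrame, max_d: int = 20,
                      ties: str = "breslow",
                      evaluator: HSIEvaluator | None = None) -> ExhaustiveResult:
    """Evaluate the HSI of every covariate subset (oracle for the search).

    Ties in HSI resolve to the lowest bit-pattern integer.  Refuses to
    enumerate more than ``max_d`` covariates.
    """
    ev = evaluator if evaluator is not None else HSIEvaluator(cohort, ties=ties)
    d = ev.d
    if d > max_d:
        raise ValueError(
            f"{d} covariates exceed the exhaustive-search guard max_d={max_d}")
    n_patterns = 2 ** d
    hsi_map = np.empty(n_patterns)
    bits = np.arange(d)
    for pattern in range(n_patterns):
        siv = ((pattern >> bits) & 1).astype(np.int8)
        hsi_map[pattern] = ev(siv)
    best_pattern = int(np.argmax(hsi_map))  # argmax takes the first (lowest)
    best_siv = ((best_pattern >> bits) & 1).astype(np.int8)
    return ExhaustiveResult(
        best_siv=best_siv,
        best_subset=tuple(n for n, b in zip(ev.names, best_siv) if b),
        best_hsi=float(hsi_map[best_pattern]),
        hsi_map=hsi_map,
    )
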