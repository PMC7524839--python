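"""Sexual genetic algorithm over binary SINDy masks.

An individual is a binary mask the shape of the coefficient matrix Xi; ones
mark the library terms a fit may use.  The population is seeded from
per-trajectory dense fits by a per-column bisection threshold (keep only the
largest-magnitude entries), expanded to the target size by mating and
mutation.  Each generation, 255 children are bred from the 45 ranked elites
by tournament selection and structured crossover (keep bits present in both
parents, coin-flip bits present in one), mutated at a scheduled rate that is
0.05 in generation 1, periodically halved, and zero over the final 10% of
generations.  Elites are re-evaluated every generation because the
classification objective is noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .sindy import (
    LibrarySpec,
    estimate_derivatives,
    evaluate_library,
    fit_coefficients,
    normalize_library,
)


@dataclass(frozen=True)
class Mask:
    """Binary (n_terms, d) template; the constant row is always live, which
    also guarantees >=1 nonzero per column."""

    bits: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=np.uint8)
        b.setflags(write=False)
        object.__setattr__(self, "bits", b)

    @staticmethod
    def repair(bits: np.ndarray) -> "Mask":
        b = np.asarray(bits, dtype=np.uint8).copy()
        b[0, :] = 1  # constant row forced live
        return Mask(b)

    def density(self) -> float:
        return float(self.bits.mean())

    def key(self) -> bytes:
        return self.bits.tobytes()

    def __hash__(self):
        return hash(self.key())

    def __eq__(self, other):
        return isinstance(other, Mask) and self.key() == other.key()


@dataclass
class Individual:
    mask: Mask
    fitness: float
    rank: int | None = None  # worst = 1 .. best = n_elites


@dataclass
class MutationSchedule:
    r_init: float = 0.15  # population seeding
    r_gen1: float = 0.05  # first generation
    zero_tail_frac: float = 0.10

    def n_halvings(self, n_xi: int) -> int:
        n = int(np.ceil(np.log2(self.r_gen1 * n_xi) + 1))
        return max(n, 2)


def mutation_rate(
    gen: int, total_gens: int, n_xi: int, schedule: MutationSchedule | None = None
) -> float:
    """Scheduled mutation rate for generation ``gen`` (1-based).

    0.05 in generation 1; halved at evenly spaced checkpoints across the
    first 90% of generations (``n_halvings`` of them); exactly zero for the
    last 10%.
    """
    schedule = schedule or MutationSchedule()
    if not 1 <= gen <= total_gens:
        raise ValueError("generation index out of range")
    active = total_gens - int(np.floor(schedule.zero_tail_frac * total_gens))
    if gen > active:
        return 0.0
    n_halv = schedule.n_halvings(n_xi)
    # active span split into n_halvings + 1 equal segments
    seg = int(np.floor((gen - 1) * (n_halv + 1) / active))
    return schedule.r_gen1 / (2**seg)


@dataclass
class TrajectoryData:
    """Cached per-trajectory regression quantities shared by all masks.

    ``gram`` and ``xty`` are the normal-equation blocks of the Z-scored
    library against the derivatives, so a masked fit reduces to a small
    linear solve instead of a fresh least-squares pass over the data.
    """

    theta_z: np.ndarray
    dV: np.ndarray
    norm: object
    label: object = None
    points: np.ndarray | None = None  # trimmed, aligned with dV
    gram: np.ndarray | None = None  # theta_z^T theta_z
    xty: np.ndarray | None = None  # theta_z^T dV
    dv_ss: np.ndarray | None = None  # per-dim sum dV^2
    dv_mean: np.ndarray | None = None


def prepare_trajectories(
    trajectories: list[np.ndarray], library: LibrarySpec, labels=None
) -> list[TrajectoryData]:
    out = []
    for i, pts in enumerate(trajectories):
        V, dV = estimate_derivatives(np.asarray(pts, dtype=float))
        theta = evaluate_library(library, V)
        theta_z, norm = normalize_library(theta, library)
        out.append(
            TrajectoryData(
                theta_z=theta_z,
                dV=dV,
                norm=norm,
                label=None if labels is None else labels[i],
                points=V,
                gram=theta_z.T @ theta_z,
                xty=theta_z.T @ dV,
                dv_ss=(dV**2).sum(axis=0),
                dv_mean=dV.mean(axis=0),
            )
        )
    return out


def masked_solve(td: TrajectoryData, bits: np.ndarray) -> np.ndarray:
    """Masked least squares via the cached normal equations -> (n_terms, d)."""
    n_terms, d = bits.shape
    xi = np.zeros((n_terms, d))
    sel_bool = bits.astype(bool)
    for k in range(d):
        sel = sel_bool[:, k]
        G = td.gram[np.ix_(sel, sel)]
        b = td.xty[sel, k]
        try:
            xi[sel, k] = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            xi[sel, k] = np.linalg.lstsq(G, b, rcond=None)[0]
    return xi


def fit_all(data: list[TrajectoryData], mask: Mask, library: LibrarySpec):
    """One CoeffMatrix per trajectory under a shared mask (normal-equation
    path; agrees with :func:`dyndisc.sindy.fit_coefficients` on
    well-conditioned problems)."""
    from .sindy import CoeffMatrix

    out = []
    n = len(data[0].dV)
    for td in data:
        xi = masked_solve(td, mask.bits)
        ss_res = td.dv_ss - 2 * np.einsum("td,td->d", xi, td.xty) + np.einsum(
            "td,tu,ud->d", xi, td.gram, xi
        )
        ss_tot = td.dv_ss - len(td.dV) * td.dv_mean**2
        r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0)
        out.append(
            CoeffMatrix(xi=xi, mask=mask.bits, norm=td.norm, library=library,
                        fit_r2=r2)
        )
    return out


def feature_matrix(data: list[TrajectoryData], mask: Mask) -> np.ndarray:
    """(n_trajectories, n_live_terms) coefficient features under a mask."""
    sel = mask.bits.astype(bool)
    return np.stack([masked_solve(td, mask.bits)[sel] for td in data])


def seed_masks(data: list[TrajectoryData], library: LibrarySpec) -> list[Mask]:
    """One maximally sparse seed mask per trajectory.

    Fit a dense Xi, then per column keep only the entries surviving the
    largest magnitude threshold that leaves at least one nonzero — i.e. the
    maximal-|coefficient| entries of each column.
    """
    dense = Mask.repair(np.ones((library.n_terms, library.d), dtype=np.uint8))
    seeds = []
    for td in data:
        cm = fit_coefficients(td.theta_z, td.dV, dense.bits, td.norm, library)
        bits = np.zeros_like(dense.bits)
        mags = np.abs(cm.xi)
        for k in range(library.d):
            col = mags[:, k]
            bits[col >= col.max() - 1e-12 * max(col.max(), 1.0), k] = 1
        seeds.append(Mask.repair(bits))
    # dedupe, preserve order
    uniq, seen = [], set()
    for m in seeds:
        if m.key() not in seen:
            seen.add(m.key())
            uniq.append(m)
    return uniq


def _mutate(bits: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return bits
    flips = rng.random(bits.shape) < rate
    return np.where(flips, 1 - bits, bits).astype(np.uint8)


def crossover(a: Mask, b: Mask, rng: np.random.Generator) -> np.ndarray:
    """Child bit = 1 if in both parents, Bernoulli(1/2) if in exactly one,
    0 if in neither."""
    both = a.bits & b.bits
    one = a.bits ^ b.bits
    coin = (rng.random(a.bits.shape) < 0.5).astype(np.uint8)
    return (both | (one & coin)).astype(np.uint8)


def seed_population(
    data: list[TrajectoryData],
    library: LibrarySpec,
    rng: np.random.Generator,
    target_size: int = 300,
    mutation: float = 0.15,
) -> list[Mask]:
    """Expand the per-trajectory seed masks to ``target_size`` unique masks
    by mating and mutation at the seeding rate."""
    seeds = seed_masks(data, library)
    pop: list[Mask] = list(seeds)
    seen = {m.key() for m in pop}
    guard = 0
    while len(pop) < target_size and guard < 100 * target_size:
        guard += 1
        i = int(rng.integers(len(pop)))
        j = int(rng.integers(len(pop)))
        if i == j and len(pop) > 1:
            continue
        child = _mutate(crossover(pop[i], pop[j], rng), mutation, rng)
        m = Mask.repair(child)
        if m.key() not in seen:
            seen.add(m.key())
            pop.append(m)
    return pop[:target_size]


def breed(
    elites: list[Individual],
    rate: float,
    rng: np.random.Generator,
    n_children: int = 255,
) -> list[Mask]:
    """Tournament mating: parent 1 cycles through the elites, parent 2 is
    sampled with probability proportional to rank (self excluded)."""
    n = len(elites)
    ranks = np.array([ind.rank for ind in elites], dtype=float)
    children = []
    for i in range(n_children):
        p1 = elites[i % n]
        w = ranks.copy()
        w[i % n] = 0.0
        w = w / w.sum()
        p2 = elites[int(rng.choice(n, p=w))]
        child = _mutate(crossover(p1.mask, p2.mask, rng), rate, rng)
        children.append(Mask.repair(child))
    return children


def _rank_sort(inds: list[Individual]) -> list[Individual]:
    """Best first; ties by sparser mask, then by mask hash (determinism)."""
    return sorted(
        inds,
        key=lambda x: (x.fitness, x.mask.bits.sum(), x.mask.key()),
    )


@dataclass
class EvolutionHistory:
    best: list[float] = field(default_factory=list)
    median: list[float] = field(default_factory=list)
    n_seeds: int = 0
    stopped_early: bool = False
    generations_run: int = 0


def run_evolution(
    data: list[TrajectoryData],
    library: LibrarySpec,
    objective: Callable[[Mask], float],
    rng: np.random.Generator,
    population: int = 300,
    n_elites: int = 45,
    total_gens: int | None = None,
    schedule: MutationSchedule | None = None,
) -> tuple[list[Individual], EvolutionHistory]:
    """Run the GA and return the ranked elites (best rank = n_elites).

    ``objective`` maps a mask to a fitness in [0, 1] (lower is better); a
    failing objective call assigns the worst fitness 1.0.  Early termination
    when the elite fitness spread falls below 1/1000 of the initial
    population's fitness range.
    """
    schedule = schedule or MutationSchedule()
    if total_gens is None:
        total_gens = 100 * int(np.ceil(library.d / 3))
    n_xi = library.n_terms * library.d

    def safe_obj(mask: Mask) -> float:
        try:
            f = float(objective(mask))
        except Exception:
            return 1.0
        return f if np.isfinite(f) else 1.0

    pop = seed_population(
        data, library, rng, target_size=population, mutation=schedule.r_init
    )
    history = EvolutionHistory(n_seeds=len(pop))
    scored = [Individual(m, safe_obj(m)) for m in pop]
    fits = np.array([s.fitness for s in scored])
    init_range = float(fits.max() - fits.min())
    n_children = population - n_elites
    if n_children < 1:
        raise ValueError("population must exceed the number of elites")

    elites = _rank_sort(scored)[:n_elites]
    for gen in range(1, total_gens + 1):
        rate = mutation_rate(gen, total_gens, n_xi, schedule)
        for rank, ind in enumerate(elites):
            ind.rank = n_elites - rank  # best first in list -> highest rank
        children = breed(elites, rate, rng, n_children=n_children)
        # re-evaluate elites (noisy objectives) and evaluate children
        candidates = [Individual(i.mask, safe_obj(i.mask)) for i in elites]
        candidates += [Individual(m, safe_obj(m)) for m in children]
        # unique by mask, keeping the better score
        best_by_mask: dict[bytes, Individual] = {}
        for ind in candidates:
            k = ind.mask.key()
            if k not in best_by_mask or ind.fitness < best_by_mask[k].fitness:
                best_by_mask[k] = ind
        elites = _rank_sort(list(best_by_mask.values()))[:n_elites]
        efits = np.array([e.fitness for e in elites])
        history.best.append(float(efits.min()))
        history.median.append(float(np.median(efits)))
        history.generations_run = gen
        if efits.max() - efits.min() <= init_range / 1000.0:
            history.stopped_early = True
            break
    for rank, ind in enumerate(elites):
        ind.rank = n_elites - rank
    return elites, history
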