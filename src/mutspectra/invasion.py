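"""Stochastic serial-passage simulation of antimutator invasions.

The model follows the LTEE-style daily transfer regime: a population grows
from the bottleneck size to the dilution threshold by discrete, non-overlapping
generations, then a random 1/100 sample seeds the next cycle.  Individuals are
grouped into classes by genetic background (mutator resident vs invading
antimutator) and by the number ``n`` of accumulated deleterious mutations.
Reproduction is deterministic, with per-generation multiplicative growth rate

    r = 2 - n * s_d           (antimutator background)
    r = 2 - kappa * n * s_d   (mutator background)

where ``s_d`` is the mean cost per deleterious mutation and ``kappa`` is the
spectrum-bias factor: mutator-made mutations are milder (kappa < 1) or harsher
(kappa > 1) than antimutator-made ones.  Mutation and lethal hits are Poisson;
drift enters through the bottleneck sampling step.

The effective selection coefficient of the invading antimutator allele is
measured empirically from its frequency trajectory as the per-generation slope
of ln(p/q), p and q being the antimutator and mutator frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimulationParams",
    "PopulationState",
    "InvasionResult",
    "SEffEstimate",
    "growth_rate",
    "reproduce",
    "mutate",
    "apply_lethal",
    "bottleneck",
    "recovery_generations",
    "equilibrate",
    "deterministic_balance",
    "naive_resident",
    "run_invasion",
    "run_replicates",
    "estimate_s_eff",
    "lethal_rate_estimate",
    "round_to_sig",
]

KappaTarget = Literal["deleterious", "lethal", "both"]

#: relative Poisson tail mass below which further multi-hit classes are dropped
_PMF_TAIL = 1e-12


class ExtinctError(RuntimeError):
    """Raised when every class has zero growth rate (population cannot grow)."""


@dataclass(frozen=True)
class SimulationParams:
    """All population-genetic and demographic parameters of one condition.

    Parameters
    ----------
    m
        Mutator strength: fold elevation of the mutation rate over wild type
        (the antimutator runs at m = 1).
    s_d
        Mean fitness-cost magnitude per deleterious mutation (0 < s_d < 1);
        stored as a positive number and subtracted from the baseline growth
        rate of 2.
    kappa
        Multiplicative spectrum-bias factor applied in the mutator background.
    kappa_target
        Which rate kappa modifies for mutators: the deleterious effect size
        ("deleterious", default), the lethal rate ("lethal"), or "both".
    u_d
        Basal deleterious mutation rate per individual per generation.
    u_l
        Basal lethal mutation rate per individual per generation.
    n_bottleneck, n_max
        Post-dilution population size and the size that triggers dilution
        (defaults 1e7 and 1e9: the LTEE 1/100 daily transfer).
    burn_in_cycles
        Stochastic growth-dilution cycles run after analytic initialization
        before the antimutator is introduced.
    max_generations
        Hard stop; an unresolved invasion is reported as censored.
    """

    m: float = 100.0
    s_d: float = 0.064
    kappa: float = 1.0
    kappa_target: KappaTarget = "deleterious"
    u_d: float = 2e-4
    u_l: float = 0.0
    n_bottleneck: int = 10_000_000
    n_max: float = 1_000_000_000.0
    burn_in_cycles: int = 5
    max_generations: int = 500_000
    seed: int | None = None
    class_cap: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"mutator strength m must be >= 1, got {self.m}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not 0 < self.s_d < 1:
            raise ValueError(f"s_d must be in (0, 1), got {self.s_d}")
        if self.u_d < 0:
            raise ValueError("u_d must be >= 0")
        if self.u_l < 0 or self.u_l > self.u_d:
            raise ValueError(f"need 0 <= u_l <= u_d, got u_l={self.u_l}, u_d={self.u_d}")
        if not self.n_bottleneck < self.n_max:
            raise ValueError("n_bottleneck must be < n_max")
        if self.kappa_target not in ("deleterious", "lethal", "both"):
            raise ValueError(f"unknown kappa_target {self.kappa_target!r}")

    # -- derived per-background rates -------------------------------------

    def cost_per_mutation(self, background: str) -> float:
        """Growth-rate deduction per deleterious mutation in ``background``."""
        if background == "mutator" and self.kappa_target in ("deleterious", "both"):
            return self.kappa * self.s_d
        return self.s_d

    def mutation_rate(self, background: str) -> float:
        return self.m * self.u_d if background == "mutator" else self.u_d

    def lethal_rate(self, background: str) -> float:
        if background == "mutator":
            scale = self.kappa if self.kappa_target in ("lethal", "both") else 1.0
            return self.m * scale * self.u_l
        return self.u_l

    @property
    def dilution_factor(self) -> float:
        return self.n_bottleneck / self.n_max

    def resolved_class_cap(self) -> int:
        """Truncation class: mutation counts beyond it pool in the top class.

        Sized from the mutator's deterministic balance mean
        lambda = 2 m u_d / (kappa_eff s_d) plus a wide (10 sigma + 20) margin.
        """
        if self.class_cap is not None:
            return self.class_cap
        if self.u_d == 0:
            return 8
        lam = 2.0 * self.mutation_rate("mutator") / self.cost_per_mutation("mutator")
        return int(lam + 10.0 * math.sqrt(lam) + 20.0)


@dataclass
class PopulationState:
    """Class abundances for both backgrounds, indexed by mutation count.

    ``mutator[n]`` counts resident individuals carrying ``n`` deleterious
    mutations.  ``antimutator[n]`` counts invader individuals by the number of
    *new* mutations acquired since the founding event; the founder's inherited
    load is carried as the constant growth-rate offset ``anti_inherited_cost``
    (inherited mutations were made under the mutator spectrum and keep their
    kappa-scaled cost).  Abundances are real-valued during deterministic
    growth and integerized at sampling steps.
    """

    mutator: np.ndarray
    antimutator: np.ndarray
    generation: int = 0
    anti_inherited_cost: float = 0.0

    @classmethod
    def empty(cls, class_cap: int) -> "PopulationState":
        z = np.zeros(class_cap + 1)
        return cls(mutator=z.copy(), antimutator=z.copy())

    @property
    def total(self) -> float:
        return float(self.mutator.sum() + self.antimutator.sum())

    @property
    def anti_frequency(self) -> float:
        tot = self.total
        return float(self.antimutator.sum() / tot) if tot > 0 else math.nan

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.mutator.copy(), self.antimutator.copy(),
            self.generation, self.anti_inherited_cost,
        )


@dataclass
class InvasionResult:
    """One replicate: trajectory of the invading allele and its outcome."""

    generations: np.ndarray
    p: np.ndarray                     # antimutator frequency
    q: np.ndarray                     # mutator frequency
    total_size: np.ndarray
    outcome: Literal["fixed", "lost", "censored"]
    founder_load: int
    seed: int | None = None
    s_eff_replicate: float | None = None

    @property
    def final_frequency(self) -> float:
        return float(self.p[-1])


@dataclass
class SEffEstimate:
    """Aggregated effective selection coefficient over replicates."""

    mean: float
    se: float
    n_used: int
    n_replicates: int
    fixation_fraction: float
    per_replicate: np.ndarray
    protocol: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.n_used > 0 and math.isfinite(self.mean)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def growth_rate(n, params: SimulationParams, background: str = "mutator"):
    """Per-generation offspring multiplier r = 2 - cost * n, clamped at 0.

    ``n`` may be a scalar or an array of mutation counts.
    """
    cost = params.cost_per_mutation(background)
    return np.clip(2.0 - cost * np.asarray(n, dtype=float), 0.0, None)[()]


def reproduce(pop: PopulationState, params: SimulationParams) -> PopulationState:
    """Deterministic growth: every class multiplied by its growth rate."""
    n = np.arange(pop.mutator.size)
    w_mut = growth_rate(n, params, "mutator")
    w_anti = np.clip(growth_rate(n, params, "antimutator") - pop.anti_inherited_cost, 0.0, None)
    if pop.total > 0 and (pop.mutator @ w_mut) + (pop.antimutator @ w_anti) == 0:
        raise ExtinctError("all occupied classes have zero growth rate")
    return PopulationState(
        pop.mutator * w_mut, pop.antimutator * w_anti,
        pop.generation + 1, pop.anti_inherited_cost,
    )


def _poisson_kernel(lam: float) -> np.ndarray:
    """Poisson pmf truncated where the remaining tail mass drops below 1e-12."""
    if lam <= 0:
        return np.ones(1)
    kmax = int(stats.poisson.isf(_PMF_TAIL, lam)) + 1
    return stats.poisson.pmf(np.arange(kmax + 1), lam)


def _shift_counts(counts: np.ndarray, movers: np.ndarray) -> np.ndarray:
    """Move ``movers[n, k]`` individuals from class n to class n+k (k >= 1),
    pooling overflow into the top class."""
    out = np.clip(counts - movers.sum(axis=1), 0.0, None)
    cap = counts.size - 1
    for k in range(1, movers.shape[1] + 1):
        col = movers[:, k - 1]
        if k > cap:
            out[cap] += col.sum()
            continue
        out[k:] += col[: counts.size - k]
        # overflow beyond the truncation class pools at the cap
        out[cap] += col[counts.size - k:].sum()
    return out


def _mutate_one(counts: np.ndarray, lam: float, rng: np.random.Generator,
                deterministic: bool) -> np.ndarray:
    if lam <= 0 or not counts.any():
        return counts
    pmf = _poisson_kernel(lam)
    if pmf.size < 2:
        return counts
    expected = counts[:, None] * pmf[None, 1:]
    movers = expected if deterministic else rng.poisson(expected).astype(float)
    # independent Poisson draws can overshoot the class size; rescale (rare)
    tot = movers.sum(axis=1)
    over = tot > counts
    if np.any(over):
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(over, counts / np.where(tot > 0, tot, 1.0), 1.0)
        movers = movers * scale[:, None]
    return _shift_counts(counts, movers)


def mutate(pop: PopulationState, params: SimulationParams,
           rng: np.random.Generator, deterministic: bool = False) -> PopulationState:
    """Stochastic acquisition of deleterious mutations.

    Per individual per generation the number of new hits is Poisson with mean
    m*u_d (mutator) or u_d (antimutator); a class-n individual acquiring k
    hits moves to class n+k.  Expected total abundance is conserved.  With
    ``deterministic=True`` the draws are replaced by their expectations
    (used by the recursion oracle).
    """
    return PopulationState(
        _mutate_one(pop.mutator, params.mutation_rate("mutator"), rng, deterministic),
        _mutate_one(pop.antimutator, params.mutation_rate("antimutator"), rng, deterministic),
        pop.generation, pop.anti_inherited_cost,
    )


def _kill_one(counts: np.ndarray, rate: float, rng: np.random.Generator,
              deterministic: bool) -> np.ndarray:
    if rate <= 0 or not counts.any():
        return counts
    expected = counts * rate
    deaths = expected if deterministic else rng.poisson(expected).astype(float)
    return np.clip(counts - deaths, 0.0, None)


def apply_lethal(pop: PopulationState, params: SimulationParams,
                 rng: np.random.Generator, deterministic: bool = False) -> PopulationState:
    """Remove individuals hit by lethal mutations.

    Mutator classes lose at per-capita rate m*kappa*u_l when kappa targets
    lethality (m*u_l otherwise); antimutator classes at u_l.
    """
    return PopulationState(
        _kill_one(pop.mutator, params.lethal_rate("mutator"), rng, deterministic),
        _kill_one(pop.antimutator, params.lethal_rate("antimutator"), rng, deterministic),
        pop.generation, pop.anti_inherited_cost,
    )


def bottleneck(pop: PopulationState, params: SimulationParams,
               rng: np.random.Generator) -> PopulationState:
    """Random 1/100-style dilution to exactly n_bottleneck individuals.

    Multinomial sampling across classes with probability proportional to
    abundance (a sound approximation to sampling without replacement at a
    100-fold dilution); returns an integer-valued population.
    """
    total = pop.total
    if total <= params.n_bottleneck:
        raise ValueError(
            f"population size {total:.3g} must exceed n_bottleneck {params.n_bottleneck}"
        )
    concat = np.concatenate([pop.mutator, pop.antimutator])
    draws = rng.multinomial(int(params.n_bottleneck), concat / concat.sum())
    k = pop.mutator.size
    return PopulationState(
        draws[:k].astype(float), draws[k:].astype(float),
        pop.generation, pop.anti_inherited_cost,
    )


def recovery_generations(params: SimulationParams) -> int:
    """Minimal g with n_bottleneck * 2**g >= n_max (mutation-free bound)."""
    return max(0, math.ceil(math.log2(params.n_max / params.n_bottleneck)))


# ---------------------------------------------------------------------------
# equilibration of the resident mutator
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _stationary_distribution(U: float, cost: float, cap: int) -> tuple[float, ...]:
    """Deterministic mutation-selection stationary class distribution.

    Iterates frequency -> normalize(growth * frequency convolved with the
    Poisson(U) mutation kernel) to a fixed point, starting from the
    small-load analytic guess Poisson(2U/cost).
    """
    n = np.arange(cap + 1)
    w = np.clip(2.0 - cost * n, 0.0, None)
    pmf = _poisson_kernel(U)
    f = stats.poisson.pmf(n, min(2.0 * U / cost, cap * 0.8))
    f /= f.sum()
    prev_mean = np.inf
    for it in range(200_000):
        a = f * w
        new = a * pmf[0]
        for k in range(1, pmf.size):
            if pmf[k] < 1e-15:
                break
            shifted = np.zeros_like(a)
            shifted[k:] = a[:-k]
            shifted[-1] += a[-k:].sum()  # overflow pools in the truncation class
            new = new + pmf[k] * shifted
        s = new.sum()
        if s <= 0:
            raise ExtinctError("stationary recursion collapsed")
        f = new / s
        if it % 200 == 0:
            mean = float(f @ n)
            if abs(mean - prev_mean) < 1e-6:
                break
            prev_mean = mean
    return tuple(f)


def deterministic_balance(params: SimulationParams) -> np.ndarray:
    """Stationary mutator class-frequency distribution of the deterministic model."""
    cap = params.resolved_class_cap()
    if params.u_d == 0:
        f = np.zeros(cap + 1)
        f[0] = 1.0
        return f
    return np.asarray(_stationary_distribution(
        params.mutation_rate("mutator"), params.cost_per_mutation("mutator"), cap,
    ))


def _grow_cycle(pop: PopulationState, params: SimulationParams,
                rng: np.random.Generator) -> PopulationState:
    """One growth-to-threshold phase followed by the dilution bottleneck."""
    while pop.total < params.n_max:
        pop = reproduce(pop, params)
        pop = mutate(pop, params, rng)
        if params.u_l > 0:
            pop = apply_lethal(pop, params, rng)
        if pop.total <= 0:
            raise ExtinctError("population went extinct during growth")
    return bottleneck(pop, params, rng)


def equilibrate(params: SimulationParams, rng: np.random.Generator) -> PopulationState:
    """All-mutator resident population at mutation-selection balance.

    Initializes n_bottleneck individuals by multinomial sampling from the
    deterministic stationary class distribution, then runs burn_in_cycles
    stochastic growth-dilution cycles so the realized state reflects the
    model's own drift and truncation.
    """
    f = deterministic_balance(params)
    counts = rng.multinomial(int(params.n_bottleneck), f).astype(float)
    pop = PopulationState(
        mutator=counts, antimutator=np.zeros_like(counts), generation=0,
    )
    for _ in range(params.burn_in_cycles):
        pop = _grow_cycle(pop, params, rng)
    return pop


# ---------------------------------------------------------------------------
# invasion runs and s_eff estimation
# ---------------------------------------------------------------------------

def naive_resident(params: SimulationParams) -> PopulationState:
    """Mutation-free all-mutator population of size n_bottleneck.

    This is the default invasion starting point: the experiment begins with
    the resident yet to accumulate its deleterious load, as in a serial
    transfer started from a clone.  The mutator then converges to
    mutation-selection balance during the run itself.  Pass
    ``resident=equilibrate(params, rng)`` to start from a resident already
    at balance instead; note that in a strictly asexual model an antimutator
    arising on a random background of a balanced resident has no expected
    advantage (it can never shed its inherited load), so invasions in that
    variant are driven by low-load founder sampling alone.
    """
    pop = PopulationState.empty(params.resolved_class_cap())
    pop.mutator[0] = float(params.n_bottleneck)
    return pop


def run_invasion(params: SimulationParams, rng: np.random.Generator | int | None = None,
                 resident: PopulationState | None = None) -> InvasionResult:
    """Simulate one antimutator invasion to fixation, loss, or censoring.

    A single resident mutator is sampled (with its deleterious load n), its
    lineage is relabeled antimutator -- new mutations arise at rate u_d with
    cost s_d, while the inherited load keeps its mutator-spectrum pricing as
    a fixed growth offset -- and the growth/mutation/lethal/bottleneck cycle
    iterates until the allele fixes or is lost.  The resident defaults to
    :func:`naive_resident`; see there for the equilibrated alternative.
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = params.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)

    if resident is None:
        resident = naive_resident(params)
    pop = resident.copy()

    # founder: one randomly sampled resident, inheriting its load n
    probs = pop.mutator / pop.mutator.sum()
    n0 = int(rng.choice(probs.size, p=probs))
    pop.mutator[n0] -= 1
    pop.antimutator[0] = 1.0
    pop.anti_inherited_cost = params.cost_per_mutation("mutator") * n0
    pop.generation = 0

    gens, ps, qs, totals = [], [], [], []

    def record() -> None:
        tot = pop.total
        gens.append(pop.generation)
        ps.append(pop.antimutator.sum() / tot)
        qs.append(pop.mutator.sum() / tot)
        totals.append(tot)

    record()
    outcome: str = "censored"
    while pop.generation < params.max_generations:
        pop = reproduce(pop, params)
        pop = mutate(pop, params, rng)
        if params.u_l > 0:
            pop = apply_lethal(pop, params, rng)
        if pop.total >= params.n_max:
            pop = bottleneck(pop, params, rng)
        record()
        anti, mut = pop.antimutator.sum(), pop.mutator.sum()
        if anti == 0:
            outcome = "lost"
            break
        if mut == 0:
            outcome = "fixed"
            break

    result = InvasionResult(
        generations=np.asarray(gens), p=np.asarray(ps), q=np.asarray(qs),
        total_size=np.asarray(totals), outcome=outcome, founder_load=n0, seed=seed,
    )
    result.s_eff_replicate = replicate_s_eff(result)
    return result


def replicate_s_eff(result: InvasionResult,
                    min_count: int = 10, max_freq: float = 0.9) -> float | None:
    """Per-replicate s_eff: slope of ln(p/q) over the segregating window.

    The window keeps generations where the antimutator count is >= min_count
    and its frequency <= max_freq, so that the log-ratio is well defined and
    endpoint noise (single-copy drift, near-fixation saturation) is excluded.
    Evaluating the log-ratio formula at the window endpoints is the two-point
    special case of this regression.
    """
    counts = result.p * result.total_size
    mask = (counts >= min_count) & (result.p <= max_freq) & (result.q > 0)
    if mask.sum() < 2:
        return None
    g = result.generations[mask]
    y = np.log(result.p[mask] / result.q[mask])
    return float(np.polyfit(g, y, 1)[0])


def estimate_s_eff(results: Sequence[InvasionResult],
                   qualify_freq: float = 0.1,
                   min_count: int = 10, max_freq: float = 0.9) -> SEffEstimate:
    """Aggregate per-replicate log-ratio slopes into one s_eff estimate.

    Replicates qualify when the allele reaches frequency >= qualify_freq and
    a segregating window of >= 2 recorded generations exists; lost-early
    replicates are excluded from the mean but counted in the totals.
    """
    vals = []
    n_fixed = 0
    for r in results:
        n_fixed += r.outcome == "fixed"
        if float(r.p.max()) < qualify_freq:
            continue
        s = r.s_eff_replicate
        if s is None or (min_count, max_freq) != (10, 0.9):
            s = replicate_s_eff(r, min_count, max_freq)
        if s is not None:
            vals.append(s)
    arr = np.asarray(vals, dtype=float)
    n = arr.size
    mean = float(arr.mean()) if n else math.nan
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return SEffEstimate(
        mean=mean, se=se, n_used=n, n_replicates=len(results),
        fixation_fraction=n_fixed / len(results) if results else math.nan,
        per_replicate=arr,
        protocol={
            "window": f"antimutator count >= {min_count} and frequency <= {max_freq}",
            "qualify": f"replicates reaching frequency >= {qualify_freq}",
            "statistic": "least-squares slope of ln(p/q) vs generation, averaged over qualifying replicates",
        },
    )


def run_replicates(params: SimulationParams, n_replicates: int,
                   base_seed: int = 0,
                   spawn_key: tuple[int, ...] = ()) -> list[InvasionResult]:
    """Run independent invasion replicates with per-replicate child RNGs."""
    out = []
    for i in range(n_replicates):
        ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(*spawn_key, i))
        out.append(run_invasion(params, np.random.default_rng(ss)))
    return out


# ---------------------------------------------------------------------------
# small closed-form helpers
# ---------------------------------------------------------------------------

def lethal_rate_estimate(u_d: float = 2e-4, essential_fraction: float = 0.07,
                         inactivating_fraction: float = 0.13) -> float:
    """Lower-bound lethal rate: deleterious rate scaled by the unconditionally
    essential genome fraction and the inactivating fraction of protein
    mutations (E. coli-derived defaults)."""
    return u_d * essential_fraction * inactivating_fraction


def round_to_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
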