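"""Multi-replicate, multi-generation breeding-strategy experiments.

Discrete, non-overlapping generations: each season the current cohort is
the complete parent pool, a mating plan is optimized under the chosen
strategy, every planned pair produces exactly one offspring, and the
offspring replace their parents.  Cohort sizes are Poisson around the
reference-population size (clamped up to the smallest feasible size when
a participation floor requires it) and offspring sexes are Bernoulli
draws, redrawn while a cohort lacks either sex (and, inside the
simulator, while males outnumber females, preserving the polygynous
sex-ratio assumption).

Per generation the newborn cohort's NeF and NeC are computed from its
cumulative pedigree quantities (inbreeding, equivalent generations and
kinship), which the simulator carries forward incrementally via the
standard one-generation recursions — identical to recomputing them from
the full pedigree, because parents are always fully recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import delta_c, delta_f
from .pedigree import FEMALE, MALE, Individual, KinshipMatrix, Pedigree
from .strategies import (
    InfeasibleError,
    MatingPlan,
    StrategySpec,
    constraint_floor,
    offspring_kinship,
    optimize_plan,
    parse_strategy,
    random_plan,
)

logger = logging.getLogger(__name__)


def next_cohort_size(rng: np.random.Generator, N0: int, constraint_floor: int = 2) -> tuple[int, bool]:
    """Poisson cohort size with mean ``N0``, clamped up to the smallest
    feasible size.  Returns ``(size, clamped)``."""
    if N0 < 2:
        raise ValueError("reference population size must be >= 2")
    draw = int(rng.poisson(N0))
    if draw < constraint_floor:
        return constraint_floor, True
    return draw, False


def assign_sexes(
    rng: np.random.Generator,
    n: int,
    male_fraction: float = 0.5,
    enforce_ratio: bool = False,
    max_redraws: int = 10_000,
) -> tuple[np.ndarray, int]:
    """Independent Bernoulli sexes, redrawn wholesale until both sexes are
    present (and, with ``enforce_ratio``, until males <= females).

    Returns ``(sex array, number of redraws)``.
    """
    if n < 2:
        raise ValueError("a viable cohort needs n >= 2")
    for redraws in range(max_redraws):
        males = rng.random(n) < male_fraction
        nm = int(males.sum())
        if 0 < nm < n and (not enforce_ratio or nm <= n - nm):
            return np.where(males, MALE, FEMALE), redraws
    # pathological male_fraction: fall back to the most balanced split
    nm = max(1, min(n - 1, n // 2))
    sexes = np.array([MALE] * nm + [FEMALE] * (n - nm))
    rng.shuffle(sexes)
    return sexes, max_redraws


@dataclass
class CohortState:
    """Everything the simulator needs about the current generation."""

    ids: list[str]
    sexes: np.ndarray           # "M"/"F" per cohort member
    kinship: KinshipMatrix      # cumulative-pedigree kinship of the cohort
    eg: pd.Series               # equivalent complete generations
    F: pd.Series                # cumulative inbreeding coefficients
    generation: int = 0

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree, cohort_ids: Sequence[str]) -> "CohortState":
        ids = list(cohort_ids)
        eg = pedigree.equivalent_generations()
        F = pedigree.inbreeding()
        return cls(
            ids=ids,
            sexes=np.array([pedigree[i].sex for i in ids]),
            kinship=pedigree.kinship(ids),
            eg=eg[ids],
            F=F[ids],
            generation=0,
        )

    @property
    def males(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.sexes) if s == MALE]

    @property
    def females(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.sexes) if s == FEMALE]

    def ne_f(self) -> float:
        rates = np.array([delta_f(self.F[i], self.eg[i]) for i in self.ids])
        rates = rates[~np.isnan(rates)]
        if rates.size == 0:
            return float("nan")
        m = rates.mean()
        return float("inf") if m <= 0 else float(1.0 / (2.0 * m))

    def ne_c(self) -> float:
        n = len(self.ids)
        if n < 2:
            return float("nan")
        g = self.eg.to_numpy()
        rates = np.array(
            [delta_c(self.kinship.values[a, b], g[a], g[b]) for a, b in combinations(range(n), 2)]
        )
        rates = rates[~np.isnan(rates)]
        if rates.size == 0:
            return float("nan")
        m = rates.mean()
        return float("inf") if m <= 0 else float(1.0 / (2.0 * m))


@dataclass
class PedigreeRecorder:
    """Accumulates simulated offspring records for export / audit."""

    records: list[Individual] = field(default_factory=list)

    def add(self, ind: Individual) -> None:
        self.records.append(ind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.records],
                "sire": [i.sire_id or "" for i in self.records],
                "dam": [i.dam_id or "" for i in self.records],
                "sex": [i.sex for i in self.records],
                "birth": [i.birth_time for i in self.records],
            }
        )


def simulate_generation(
    state: CohortState,
    spec: StrategySpec,
    rng: np.random.Generator,
    *,
    N0: int | None = None,
    male_fraction: float | None = None,
    recorder: PedigreeRecorder | None = None,
    random_mating: bool = False,
    n_proposals: int = 3000,
    n_restarts: int = 2,
) -> tuple[CohortState, dict]:
    """Advance one generation; returns the new state and event counters."""
    males, females = state.males, state.females
    if not males or not females:
        raise InfeasibleError("current cohort lacks one sex")
    if N0 is None:
        N0 = len(state.ids)
    if male_fraction is None:
        male_fraction = len(males) / len(state.ids)
    floor = constraint_floor(spec, len(males), len(females))
    N_t, clamped = next_cohort_size(rng, N0, floor)
    if random_mating:
        plan = random_plan(spec, males, females, N_t, rng)
    else:
        plan = optimize_plan(
            spec, state.kinship, males, females, N_t,
            seed=int(rng.integers(2**31)),
            eg=state.eg, n_proposals=n_proposals, n_restarts=n_restarts,
        )
    kin_off = offspring_kinship(plan, state.kinship)
    F_off = np.array([state.kinship.get(s, d) for s, d in plan.pairs])
    eg_off = np.array(
        [1.0 + 0.5 * (state.eg[s] + state.eg[d]) for s, d in plan.pairs]
    )
    sexes, redraws = assign_sexes(rng, N_t, male_fraction, enforce_ratio=True)
    gen = state.generation + 1
    ids = [f"g{gen}_{k}" for k in range(N_t)]
    if recorder is not None:
        for k, (s, d) in enumerate(plan.pairs):
            recorder.add(Individual(ids[k], s, d, sexes[k], float(gen)))
    new_state = CohortState(
        ids=ids,
        sexes=sexes,
        kinship=KinshipMatrix(tuple(ids), kin_off.values),
        eg=pd.Series(eg_off, index=ids),
        F=pd.Series(F_off, index=ids),
        generation=gen,
    )
    return new_state, {"clamped": int(clamped), "sex_redraws": redraws}


@dataclass
class NeTrajectory:
    """Per-replicate Ne curve for one strategy."""

    strategy: str
    replicate: int
    ne_f: list[float]
    ne_c: list[float]
    aborted_at: int | None = None

    def rows(self) -> list[dict]:
        return [
            {
                "strategy": self.strategy,
                "replicate": self.replicate,
                "generation": t + 1,
                "NeF": self.ne_f[t],
                "NeC": self.ne_c[t],
                "aborted": self.aborted_at is not None and t + 1 >= self.aborted_at,
            }
            for t in range(len(self.ne_f))
        ]


def run_replicate(
    base: CohortState,
    spec: StrategySpec,
    n_generations: int,
    rng: np.random.Generator,
    replicate: int = 0,
    recorder: PedigreeRecorder | None = None,
    random_mating: bool = False,
    **opt_kwargs,
) -> NeTrajectory:
    N0 = len(base.ids)
    male_fraction = len(base.males) / N0
    state = base
    ne_f = [float("nan")] * n_generations
    ne_c = [float("nan")] * n_generations
    aborted_at = None
    for t in range(n_generations):
        try:
            state, _ = simulate_generation(
                state, spec, rng, N0=N0, male_fraction=male_fraction,
                recorder=recorder, random_mating=random_mating, **opt_kwargs,
            )
        except InfeasibleError as exc:
            aborted_at = t + 1
            logger.warning(
                "strategy %s replicate %d aborted at generation %d: %s",
                spec.name, replicate, t + 1, exc,
            )
            break
        ne_f[t] = state.ne_f()
        ne_c[t] = state.ne_c()
    return NeTrajectory(spec.name, replicate, ne_f, ne_c, aborted_at)


def replicate_rng(master_seed: int, strategy_index: int, replicate: int) -> np.random.Generator:
    """Deterministic per-(strategy, replicate) generator."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(strategy_index, replicate))
    return np.random.default_rng(ss)


def run_experiment(
    base: CohortState,
    strategies: Iterable[StrategySpec | str],
    n_generations: int = 20,
    n_replicates: int = 100,
    master_seed: int = 0,
    random_mating: bool = False,
    **opt_kwargs,
) -> pd.DataFrame:
    """Run every strategy for ``n_replicates`` seeded replicates.

    Returns a tidy frame with one row per (strategy, replicate,
    generation) carrying NeF, NeC and an aborted flag.  The experiment is
    a pure function of its inputs and ``master_seed``.
    """
    specs = [parse_strategy(s) if isinstance(s, str) else s for s in strategies]
    rows: list[dict] = []
    for si, spec in enumerate(specs):
        for rep in range(n_replicates):
            rng = replicate_rng(master_seed, si, rep)
            traj = run_replicate(
                base, spec, n_generations, rng, replicate=rep,
                random_mating=random_mating, **opt_kwargs,
            )
            rows.extend(traj.rows())
        logger.info("strategy %s: %d replicates done", spec.name, n_replicates)
    return pd.DataFrame(rows)


def summarize_experiment(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy, per-generation Ne summary (mean/median/quantiles)."""
    ok = tidy[~tidy["aborted"]].replace([np.inf, -np.inf], np.nan)
    g = ok.groupby(["strategy", "generation"])["NeF"]
    out = g.agg(
        mean_NeF="mean",
        median_NeF="median",
        q10_NeF=lambda s: s.quantile(0.10),
        q90_NeF=lambda s: s.quantile(0.90),
        n="count",
    ).reset_index()
    out["mean_NeC"] = (
        ok.groupby(["strategy", "generation"])["NeC"].mean().reset_index(drop=True)
    )
    aborted = (
        tidy.groupby("strategy")["aborted"].any().rename("any_aborted").reset_index()
    )
    return out.merge(aborted, on="strategy")


def rank_strategies(summary: pd.DataFrame, generation: int, by: str = "mean_NeF") -> pd.Series:
    """Strategies ranked (1 = largest Ne) at one generation."""
    at = summary[summary["generation"] == generation].set_index("strategy")[by]
    return at.rank(ascending=False, method="min").astype(int).sort_values()
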