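"""The 23 mate-selection strategies and the plan optimizer.

Each strategy minimizes an objective ``Fx`` over feasible mating plans for
one breeding season.  A plan assigns every prospective offspring a (sire,
dam) pair; under the default harem (polygyny) constraint each dam is mated
to a single sire per season.  Objective families:

====== =======================================================
F      sum over matings of parent coancestry ``C_jk``
dF     sum of depth-corrected increases ``dC_jk``
mFm    sum of ``m_j C_jk m_k`` with mean-kinship weights ``m``
dmFdm  the increase analogue, ``dm_j dC_jk dm_k``
C      sum over distinct prospective-offspring pairs of ``C_lm``
dC     the increase analogue on offspring pairs
mix    ``p1 * mean parent term + (1 - p1) * mean offspring term``
====== =======================================================

Participation variants: ``zero`` — every female contributes at least one
offspring; ``one`` — every female and every male do; ``free`` — no floor.
The printed strategy names (``F0, F1, Ff, dF0, ... mixf95-5``) combine the
two axes; weighted-mix strategies carry ``p1`` in {0.01, 0.05, 0.50, 0.95}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _anneal
from .diversity import delta_c, mean_kinship_weights
from .pedigree import KinshipMatrix

FAMILIES = ("F", "dF", "mFm", "dmFdm", "C", "dC", "mix")
PARTICIPATIONS = ("zero", "one", "free")
MIX_WEIGHTS = (0.01, 0.05, 0.50, 0.95)

_PART_SUFFIX = {"zero": "0", "one": "1", "free": "f"}
_FAMILY_PARTS = {
    "F": ("zero", "one", "free"),
    "dF": ("zero", "one"),
    "mFm": ("zero", "one"),
    "dmFdm": ("zero", "one"),
    "C": ("zero", "one", "free"),
    "dC": ("zero", "one", "free"),
}
_MIX_LABEL = {0.01: "1-99", 0.05: "5-95", 0.50: "50-50", 0.95: "95-5"}

#: printed names in display order (the field's figure labels)
PRINTED_NAMES = {"dF": "ΔF", "dmFdm": "ΔmΔFΔm", "dC": "ΔC"}


class InfeasibleError(ValueError):
    """No mating plan can satisfy the participation constraints."""


@dataclass(frozen=True)
class StrategySpec:
    """One strategy = objective family x participation variant (+ mix weight)."""

    family: str
    participation: str
    p1: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.participation not in PARTICIPATIONS:
            raise ValueError(f"unknown participation {self.participation!r}")
        if self.family == "mix":
            if self.p1 is None:
                raise ValueError("mix strategies require a p1 weight")
            if not (0.0 <= self.p1 <= 1.0):
                raise ValueError("p1 must lie in [0, 1]")
            if self.participation == "one":
                raise ValueError("mix strategies do not use participation 'one'")
        elif self.p1 is not None:
            raise ValueError("p1 only applies to the mix family")
        if self.family != "mix" and self.participation not in _FAMILY_PARTS[self.family]:
            raise ValueError(
                f"family {self.family!r} has no {self.participation!r} variant"
            )

    @property
    def name(self) -> str:
        if self.family == "mix":
            prefix = "mixf" if self.participation == "free" else "mix"
            return f"{prefix}{_MIX_LABEL[self.p1]}"
        return f"{self.family}{_PART_SUFFIX[self.participation]}"

    @property
    def needs_eg(self) -> bool:
        return self.family in ("dF", "dC", "dmFdm")

    @property
    def dam_floor(self) -> int:
        return 0 if self.participation == "free" else 1

    @property
    def sires_must_all_serve(self) -> bool:
        return self.participation == "one"


def _build_registry() -> dict[str, StrategySpec]:
    reg: dict[str, StrategySpec] = {}
    for fam, parts in _FAMILY_PARTS.items():
        for part in parts:
            s = StrategySpec(fam, part)
            reg[s.name] = s
    for part in ("zero", "free"):
        for p1 in MIX_WEIGHTS:
            s = StrategySpec("mix", part, p1)
            reg[s.name] = s
    return reg


_REGISTRY = _build_registry()
STRATEGY_NAMES: tuple[str, ...] = tuple(_REGISTRY)
assert len(STRATEGY_NAMES) == 23


def parse_strategy(name: str) -> StrategySpec:
    """Resolve a printed strategy label (e.g. ``"mixf5-95"``, ``"dF0"``)."""
    key = name.strip().replace("Δ", "d").replace("–", "-").replace(" ", "")
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown strategy {name!r}; valid names: {', '.join(STRATEGY_NAMES)}"
        )
    return _REGISTRY[key]


def all_strategies() -> list[StrategySpec]:
    return list(_REGISTRY.values())


@dataclass(frozen=True)
class MatingPlan:
    """A multiset of (sire, dam) pairs; each occurrence yields one offspring."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def sires(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def dams(self) -> tuple[str, ...]:
        return tuple(p[1] for p in self.pairs)

    def dam_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, d in self.pairs:
            out[d] = out.get(d, 0) + 1
        return out

    def sire_of_dam(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, d in self.pairs:
            out.setdefault(d, set()).add(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows: dict[tuple[str, str], int] = {}
        for p in self.pairs:
            rows[p] = rows.get(p, 0) + 1
        return pd.DataFrame(
            [(s, d, n) for (s, d), n in sorted(rows.items())],
            columns=["sire", "dam", "n_offspring"],
        )


def offspring_kinship(plan: MatingPlan, kinship: KinshipMatrix) -> KinshipMatrix:
    """Kinship matrix of the prospective offspring of a plan.

    For offspring ``l`` of (j1, k1) and ``m`` of (j2, k2):
    ``C_lm = (C_j1j2 + C_j1k2 + C_k1j2 + C_k1k2) / 4`` and the diagonal is
    ``C_ll = (1 + C_j1k1) / 2``.
    """
    n = len(plan)
    idx = {i: kinship.index(i) for i in set(plan.sires) | set(plan.dams)}
    K = kinship.values
    s = np.array([idx[p[0]] for p in plan.pairs])
    d = np.array([idx[p[1]] for p in plan.pairs])
    C = 0.25 * (K[np.ix_(s, s)] + K[np.ix_(s, d)] + K[np.ix_(d, s)] + K[np.ix_(d, d)])
    np.fill_diagonal(C, 0.5 * (1.0 + K[s, d]))
    ids = tuple(f"off{k}:{plan.pairs[k][0]}x{plan.pairs[k][1]}" for k in range(n))
    return KinshipMatrix(ids, C)


def _offspring_eg(plan: MatingPlan, eg: Mapping[str, float]) -> np.ndarray:
    return np.array([1.0 + 0.5 * (float(eg[s]) + float(eg[d])) for s, d in plan.pairs])


def objective_value(
    plan: MatingPlan,
    spec: StrategySpec,
    kinship: KinshipMatrix,
    eg: Mapping[str, float] | pd.Series | None = None,
    weights: pd.Series | None = None,
    include_self_pairs: bool = False,
) -> float:
    """Evaluate the strategy objective ``Fx`` for a plan.

    Parent-side sums run over the plan's pair occurrences; offspring-side
    sums run over unordered distinct prospective-offspring pairs (the
    diagonal self-coancestry terms are included only when
    ``include_self_pairs`` is set).  ``weights`` (mean kinships over the
    mating group) are computed from ``kinship`` when not supplied.
    """
    if spec.needs_eg and eg is None:
        raise ValueError(f"family {spec.family!r} requires equivalent generations")
    K = kinship

    def parent_sum() -> float:
        if spec.family in ("F", "mix"):
            return sum(K.get(s, d) for s, d in plan.pairs)
        if spec.family == "dF":
            return sum(delta_c(K.get(s, d), float(eg[s]), float(eg[d]))
                       for s, d in plan.pairs)
        if spec.family in ("mFm", "dmFdm"):
            mode = "plain" if spec.family == "mFm" else "increase"
            w = weights
            if w is None:
                w = mean_kinship_weights(K, list(K.ids), mode=mode, eg=eg)
            if spec.family == "mFm":
                return sum(w[s] * K.get(s, d) * w[d] for s, d in plan.pairs)
            return sum(
                w[s] * delta_c(K.get(s, d), float(eg[s]), float(eg[d])) * w[d]
                for s, d in plan.pairs
            )
        raise AssertionError

    def offspring_sum() -> float:
        off = offspring_kinship(plan, K)
        n = len(plan)
        if spec.family == "dC":
            g = _offspring_eg(plan, eg)
        total = 0.0
        for a in range(n):
            lo = a if include_self_pairs else a + 1
            for b in range(lo, n):
                c = off.values[a, b]
                if spec.family == "dC":
                    c = delta_c(c, g[a], g[b])
                total += c
        return total

    if spec.family in ("F", "dF", "mFm", "dmFdm"):
        return float(parent_sum())
    if spec.family in ("C", "dC"):
        return float(offspring_sum())
    # mix: per-term means so that both components share a [0, 1] scale
    n = len(plan)
    npairs = 0.5 * n * (n - 1) + (n if include_self_pairs else 0)
    mean_off = offspring_sum() / npairs if npairs > 0 else 0.0
    return float(spec.p1 * (parent_sum() / n) + (1.0 - spec.p1) * mean_off)


def check_feasible(
    plan: MatingPlan,
    spec: StrategySpec,
    males: Sequence[str],
    females: Sequence[str],
    N_t: int,
    harem: bool = True,
) -> str | None:
    """Return ``None`` if the plan satisfies all constraints, else a reason."""
    males, females = list(males), list(females)
    if len(plan) != N_t:
        return f"plan has {len(plan)} pairs, expected {N_t}"
    mset, fset = set(males), set(females)
    for s, d in plan.pairs:
        if s not in mset:
            return f"sire {s!r} is not a candidate male"
        if d not in fset:
            return f"dam {d!r} is not a candidate female"
    if harem:
        for dam, sires in plan.sire_of_dam().items():
            if len(sires) > 1:
                return f"dam {dam!r} mated to {len(sires)} distinct sires"
    used_dams = set(plan.dams)
    used_sires = set(plan.sires)
    if len(used_sires) > len(used_dams):
        return "more distinct sires than dams in the plan"
    if spec.dam_floor and used_dams != fset:
        missing = sorted(fset - used_dams)
        return f"females without offspring under participation floor: {missing}"
    if spec.sires_must_all_serve and used_sires != mset:
        missing = sorted(mset - used_sires)
        return f"males without offspring under participation 'one': {missing}"
    return None


def feasible(plan, spec, males, females, N_t, harem: bool = True) -> bool:
    return check_feasible(plan, spec, males, females, N_t, harem) is None


def assert_constraints_satisfiable(
    spec: StrategySpec, males: Sequence[str], females: Sequence[str], N_t: int
) -> None:
    nm, nf = len(males), len(females)
    if nm == 0 or nf == 0:
        raise InfeasibleError("need at least one male and one female")
    if nm > nf:
        raise InfeasibleError(
            f"{nm} males > {nf} females: sires cannot outnumber dams"
        )
    if spec.dam_floor and N_t < nf:
        raise InfeasibleError(
            f"cohort size {N_t} < {nf} females but every female must contribute"
        )
    if spec.sires_must_all_serve and N_t < max(nm, nf):
        raise InfeasibleError(
            f"cohort size {N_t} too small for all {nm} males and {nf} females to contribute"
        )


def constraint_floor(spec: StrategySpec, n_males: int, n_females: int) -> int:
    """Smallest cohort size for which feasible plans exist (>= 2 so both
    sexes can appear among the offspring)."""
    if spec.dam_floor:
        return max(2, n_females)
    return 2


# -- optimization -------------------------------------------------------------


def _compositions(total: int, parts: int, floor: int):
    """All vectors of length ``parts`` of ints >= floor summing to total."""
    def rec(remaining, slots):
        if slots == 1:
            if remaining >= floor:
                yield (remaining,)
            return
        for v in range(floor, remaining - floor * (slots - 1) + 1):
            for rest in rec(remaining - v, slots - 1):
                yield (v,) + rest
    yield from rec(total, parts)


def _plan_from_state(counts, sires, males, females) -> MatingPlan:
    pairs = []
    for d, c in enumerate(counts):
        for _ in range(int(c)):
            pairs.append((males[int(sires[d])], females[d]))
    return MatingPlan(tuple(pairs))


def enumeration_size(spec: StrategySpec, n_males: int, n_females: int, N_t: int) -> float:
    """Upper-bound estimate of the number of feasible harem plans."""
    floor = spec.dam_floor
    free_slots = N_t - floor * n_females
    if free_slots < 0:
        return 0.0
    n_counts = math.comb(free_slots + n_females - 1, n_females - 1)
    return float(n_counts) * float(n_males) ** min(n_females, N_t)


def _exhaustive(spec, kinship, males, females, N_t, eg, weights, harem, include_self_pairs):
    nm, nf = len(males), len(females)
    best_obj = math.inf
    best_plan: MatingPlan | None = None
    if not harem:
        pair_space = list(itertools.product(males, females))
        for combo in itertools.combinations_with_replacement(pair_space, N_t):
            plan = MatingPlan(combo)
            if not feasible(plan, spec, males, females, N_t, harem=False):
                continue
            obj = objective_value(plan, spec, kinship, eg, weights, include_self_pairs)
            if obj < best_obj - 1e-12 or (
                obj <= best_obj + 1e-12 and (best_plan is None or plan.pairs < best_plan.pairs)
            ):
                best_obj, best_plan = obj, plan
        if best_plan is None:
            raise InfeasibleError("no feasible plan exists")
        return best_plan
    if include_self_pairs:
        raise NotImplementedError(
            "self-pair offspring terms are only supported without the harem constraint"
        )
    # evaluate through the same compiled objective the annealer uses
    K, W, g, family, _ = _kernel_inputs(spec, kinship, males, females, eg, weights)
    p1 = float(spec.p1 or 0.0)
    counts_buf = np.zeros(nf, dtype=np.int64)
    sires_buf = np.zeros(nf, dtype=np.int64)
    for counts in _compositions(N_t, nf, spec.dam_floor):
        used = [d for d in range(nf) if counts[d] > 0]
        counts_buf[:] = counts
        for sire_combo in itertools.product(range(nm), repeat=len(used)):
            if spec.sires_must_all_serve and len(set(sire_combo)) != nm:
                continue
            for pos, d in enumerate(used):
                sires_buf[d] = sire_combo[pos]
            obj = _anneal._objective(counts_buf, sires_buf, K, W, g, family, p1, nm, nf, N_t)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_plan = _plan_from_state(counts_buf, sires_buf, males, females)
            elif obj <= best_obj + 1e-12:
                plan = _plan_from_state(counts_buf, sires_buf, males, females)
                if best_plan is None or plan.pairs < best_plan.pairs:
                    best_plan = plan
    if best_plan is None:
        raise InfeasibleError("no feasible plan exists")
    return best_plan


def _kernel_inputs(spec, kinship, males, females, eg, weights):
    """Order parents male-first and precompute the per-mating cost matrix."""
    ids = list(males) + list(females)
    K = kinship.subset(ids).values.copy()
    nm, nf = len(males), len(females)
    g = np.zeros(len(ids))
    if eg is not None:
        g = np.array([float(eg[i]) for i in ids])
    W = K[:nm, nm:].copy()  # C_jk between male j and female k
    if spec.family == "dF":
        for j in range(nm):
            for k in range(nf):
                W[j, k] = delta_c(W[j, k], g[j], g[nm + k])
    elif spec.family in ("mFm", "dmFdm"):
        mode = "plain" if spec.family == "mFm" else "increase"
        if weights is None:
            weights = mean_kinship_weights(kinship.subset(ids), ids, mode=mode, eg=dict(zip(ids, g)))
        wv = np.array([float(weights[i]) for i in ids])
        for j in range(nm):
            for k in range(nf):
                base = W[j, k]
                if spec.family == "dmFdm":
                    base = delta_c(base, g[j], g[nm + k])
                W[j, k] = wv[j] * base * wv[nm + k]
    if spec.family in ("F", "dF", "mFm", "dmFdm"):
        family = _anneal.PARENT_ONLY
    elif spec.family == "C":
        family = _anneal.OFFSPRING_PLAIN
    elif spec.family == "dC":
        family = _anneal.OFFSPRING_DELTA
    else:
        family = _anneal.MIX
    part = {"zero": _anneal.PART_ZERO, "one": _anneal.PART_ONE,
            "free": _anneal.PART_FREE}[spec.participation]
    return K, W, g, family, part


def optimize_plan(
    spec: StrategySpec,
    kinship: KinshipMatrix,
    males: Sequence[str],
    females: Sequence[str],
    N_t: int,
    seed: int = 0,
    method: str = "auto",
    harem: bool = True,
    enumeration_limit: int = 5_000,
    n_proposals: int = 8000,
    n_restarts: int = 6,
    eg: Mapping[str, float] | pd.Series | None = None,
    weights: pd.Series | None = None,
    include_self_pairs: bool = False,
) -> MatingPlan:
    """Find a feasible mating plan minimizing the strategy objective.

    ``method="exact"`` enumerates every feasible plan (ties broken by the
    lexicographically smallest pair encoding); ``"anneal"`` runs the
    seeded simulated-annealing kernel; ``"auto"`` enumerates when the
    estimated search space is below ``enumeration_limit`` plans.
    """
    males, females = list(males), list(females)
    assert_constraints_satisfiable(spec, males, females, N_t)
    if spec.needs_eg and eg is None:
        raise ValueError(f"family {spec.family!r} requires equivalent generations")
    if method == "auto":
        method = (
            "exact"
            if enumeration_size(spec, len(males), len(females), N_t) <= enumeration_limit
            else "anneal"
        )
    if method == "exact":
        return _exhaustive(spec, kinship, males, females, N_t, eg, weights, harem,
                           include_self_pairs)
    if method != "anneal":
        raise ValueError(f"unknown method {method!r}")
    if not harem:
        raise NotImplementedError(
            "the annealing kernel requires the harem constraint; use method='exact'"
        )
    if include_self_pairs:
        raise NotImplementedError(
            "self-pair offspring terms are only supported by method='exact'"
        )
    K, W, g, family, part = _kernel_inputs(spec, kinship, males, females, eg, weights)
    counts, sires, _ = _anneal.anneal(
        K, W, g, family, float(spec.p1 or 0.0), part,
        len(males), len(females), int(N_t),
        int(n_proposals), int(n_restarts), int(seed) % (2**31),
    )
    return _plan_from_state(counts, sires, males, females)


def random_plan(
    spec: StrategySpec,
    males: Sequence[str],
    females: Sequence[str],
    N_t: int,
    rng: np.random.Generator,
    harem: bool = True,
) -> MatingPlan:
    """A uniformly haphazard feasible plan (baseline / drift control)."""
    males, females = list(males), list(females)
    assert_constraints_satisfiable(spec, males, females, N_t)
    nm, nf = len(males), len(females)
    counts = np.full(nf, spec.dam_floor, dtype=np.int64)
    for _ in range(N_t - counts.sum()):
        counts[rng.integers(nf)] += 1
    sires = rng.integers(nm, size=nf)
    if spec.sires_must_all_serve:
        order = rng.permutation(nf)[:nm]
        sires[order] = rng.permutation(nm)
    if not harem:
        pairs = []
        for d in range(nf):
            for _ in range(int(counts[d])):
                pairs.append((males[int(rng.integers(nm))], females[d]))
        plan = MatingPlan(tuple(pairs))
        if feasible(plan, spec, males, females, N_t, harem=False):
            return plan
    return _plan_from_state(counts, sires, males, females)
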