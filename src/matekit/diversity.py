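"""Effective-population-size estimators from realized pedigrees.

Two pedigree-based estimators of the effective population size Ne:

* ``NeF`` from individual increases in inbreeding: each individual's
  cumulative inbreeding F and pedigree depth t (equivalent complete
  generations) yield a per-generation rate ``dF = 1 - (1 - F)^(1/(t-1))``,
  and ``NeF = 1 / (2 * mean(dF))`` over the cohort.
* ``NeC`` from pairwise increases in coancestry: each unordered pair
  (j, k) yields ``dC = 1 - (1 - C_jk)^(2/(g_j + g_k))`` and
  ``NeC = 1 / (2 * mean(dC))`` over all distinct pairs.

A cohort whose mean increase is zero has no measurable drift signal and
its Ne is reported as ``inf``; individuals with t <= 1 carry no increase
information and are excluded from the NeF mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix, Pedigree


def delta_f(F: float, t: float) -> float:
    """Individual increase in inbreeding ``1 - (1 - F)^(1/(t-1))``.

    ``t`` is the individual's equivalent complete generations.  Returns
    ``nan`` (undefined) when ``t <= 1``: such an individual has no
    pedigree span over which inbreeding can accumulate.
    """
    if t <= 1.0:
        return float("nan")
    return float(1.0 - (1.0 - F) ** (1.0 / (t - 1.0)))


def delta_c(Cjk: float, gj: float, gk: float) -> float:
    """Pairwise increase in coancestry ``1 - (1 - C)^(2/(gj + gk))``.

    ``gj`` and ``gk`` are the equivalent complete generations of the two
    individuals; the exponent is one over their mean.  Undefined (nan)
    when ``gj + gk == 0``.
    """
    if gj + gk <= 0.0:
        return float("nan")
    return float(1.0 - (1.0 - Cjk) ** (2.0 / (gj + gk)))


def _ne_from_rates(rates: np.ndarray) -> float:
    rates = rates[~np.isnan(rates)]
    if rates.size == 0:
        return float("nan")
    m = rates.mean()
    if m <= 0.0:
        return float("inf")
    return float(1.0 / (2.0 * m))


def ne_from_inbreeding(pedigree: Pedigree, cohort_ids: Sequence[str]) -> float:
    """``NeF = 1 / (2 mean dF)`` over the cohort (nan-excluding mean)."""
    if len(cohort_ids) == 0:
        raise ValueError("cohort must not be empty")
    F = pedigree.inbreeding()
    t = pedigree.equivalent_generations()
    rates = np.array([delta_f(F[i], t[i]) for i in cohort_ids])
    return _ne_from_rates(rates)


def ne_from_coancestry(pedigree: Pedigree, cohort_ids: Sequence[str]) -> float:
    """``NeC = 1 / (2 mean dC)`` over unordered distinct cohort pairs."""
    if len(cohort_ids) < 2:
        raise ValueError("NeC needs at least two cohort members")
    kin = pedigree.kinship(list(cohort_ids))
    g = pedigree.equivalent_generations()
    gv = np.array([g[i] for i in cohort_ids])
    rates = np.array(
        [delta_c(kin.values[a, b], gv[a], gv[b])
         for a, b in combinations(range(len(cohort_ids)), 2)]
    )
    return _ne_from_rates(rates)


@dataclass(frozen=True)
class CohortDiversity:
    """Per-cohort diversity panel: increase rates, NeF, NeC and their ratio."""

    cohort_ids: tuple[str, ...]
    delta_F: pd.Series
    mean_delta_C: float
    ne_f: float
    ne_c: float

    @property
    def ratio(self) -> float:
        """NeC / NeF; nan unless both estimators are finite and defined."""
        if np.isfinite(self.ne_f) and np.isfinite(self.ne_c):
            return self.ne_c / self.ne_f
        return float("nan")

    def to_row(self) -> dict:
        def cell(v):
            return "" if not np.isfinite(v) else v

        return {
            "n": len(self.cohort_ids),
            "NeF": cell(self.ne_f),
            "NeC": cell(self.ne_c),
            "NeC_NeF": cell(self.ratio),
            "NeF_flag": "" if np.isfinite(self.ne_f) else ("inf" if np.isinf(self.ne_f) else "undefined"),
            "NeC_flag": "" if np.isfinite(self.ne_c) else ("inf" if np.isinf(self.ne_c) else "undefined"),
        }


def cohort_diversity(pedigree: Pedigree, cohort_ids: Sequence[str]) -> CohortDiversity:
    """Compute the full diversity panel for one cohort."""
    F = pedigree.inbreeding()
    t = pedigree.equivalent_generations()
    dF = pd.Series(
        [delta_f(F[i], t[i]) for i in cohort_ids], index=list(cohort_ids), name="delta_F"
    )
    kin = pedigree.kinship(list(cohort_ids))
    gv = np.array([t[i] for i in cohort_ids])
    pair_rates = np.array(
        [delta_c(kin.values[a, b], gv[a], gv[b])
         for a, b in combinations(range(len(cohort_ids)), 2)]
    ) if len(cohort_ids) > 1 else np.array([])
    return CohortDiversity(
        cohort_ids=tuple(cohort_ids),
        delta_F=dF,
        mean_delta_C=(
            float(np.nanmean(pair_rates))
            if pair_rates.size and not np.all(np.isnan(pair_rates))
            else float("nan")
        ),
        ne_f=_ne_from_rates(dF.to_numpy()),
        ne_c=_ne_from_rates(pair_rates) if pair_rates.size else float("nan"),
    )


def expected_heterozygosity(kinship: KinshipMatrix) -> float:
    """Nei's gene diversity ``He = 1 - mean coancestry`` over all ordered
    pairs (including self-coancestry) of the group."""
    return float(1.0 - kinship.values.mean())


def mean_kinship_weights(
    kinship: KinshipMatrix,
    group: Sequence[str],
    mode: str = "plain",
    eg: dict | pd.Series | None = None,
) -> pd.Series:
    """Per-individual mean coancestry with the rest of the mating group.

    ``mode="plain"`` averages coancestries ``C_ji``; ``mode="increase"``
    averages pairwise increases ``dC_ji`` (requires equivalent-generation
    values ``eg``).  Used to penalize already well-represented animals in
    the weighted mate-selection objectives.
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("mean kinship weights need a group of at least 2")
    sub = kinship.subset(group)
    n = len(group)
    if mode == "plain":
        vals = sub.values.copy()
    elif mode == "increase":
        if eg is None:
            raise ValueError("mode='increase' requires equivalent generations")
        gv = np.array([float(eg[i]) for i in group])
        vals = np.empty((n, n))
        for a in range(n):
            for b in range(n):
                vals[a, b] = delta_c(sub.values[a, b], gv[a], gv[b]) if a != b else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(vals, 0.0)
    weights = vals.sum(axis=1) / (n - 1)
    return pd.Series(weights, index=group, name=f"m_{mode}")
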