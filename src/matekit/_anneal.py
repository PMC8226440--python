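"""Simulated-annealing kernel for mate-plan optimization (numba).

State encoding (harem representation): ``counts[d]`` = offspring assigned
to dam ``d``, ``sires[d]`` = index of the single sire mated to dam ``d``.
Parent indices: males ``0..nm-1``, females ``nm..nm+nf-1`` in the kinship
matrix ``K``.

Objective families are passed as integer codes:
``0`` parent-term only (sum over matings of a precomputed pair cost ``W``),
``1`` offspring coancestry (sum over distinct prospective-offspring pairs),
``2`` offspring increase in coancestry (depth-corrected),
``3`` mixture: ``p1 * mean(parent term) + (1 - p1) * mean(offspring term)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PARENT_ONLY = 0
OFFSPRING_PLAIN = 1
OFFSPRING_DELTA = 2
MIX = 3

PART_ZERO = 0  # every dam >= 1 offspring
PART_ONE = 1   # every dam and every sire >= 1 offspring
PART_FREE = 2  # no participation floor


@njit(cache=True)
def _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t):
    parent = 0.0
    for d in range(nf):
        if counts[d] > 0:
            parent += counts[d] * W[sires[d], d]
    if family == PARENT_ONLY:
        return parent
    off = 0.0
    for d1 in range(nf):
        c1 = counts[d1]
        if c1 == 0:
            continue
        s1 = sires[d1]
        f1 = nm + d1
        # full-sib pairs within the same mating
        if c1 > 1:
            css = 0.25 * (K[s1, s1] + 2.0 * K[s1, f1] + K[f1, f1])
            if family == OFFSPRING_DELTA:
                g1 = 1.0 + 0.5 * (g[s1] + g[f1])
                css = 1.0 - (1.0 - css) ** (1.0 / g1)
            off += 0.5 * c1 * (c1 - 1) * css
        for d2 in range(d1 + 1, nf):
            c2 = counts[d2]
            if c2 == 0:
                continue
            s2 = sires[d2]
            f2 = nm + d2
            c = 0.25 * (K[s1, s2] + K[s1, f2] + K[f1, s2] + K[f1, f2])
            if family == OFFSPRING_DELTA:
                g1 = 1.0 + 0.5 * (g[s1] + g[f1])
                g2 = 1.0 + 0.5 * (g[s2] + g[f2])
                c = 1.0 - (1.0 - c) ** (2.0 / (g1 + g2))
            off += c1 * c2 * c
    if family == MIX:
        npairs = 0.5 * N_t * (N_t - 1)
        mean_off = off / npairs if npairs > 0 else 0.0
        return p1 * (parent / N_t) + (1.0 - p1) * mean_off
    return off


@njit(cache=True)
def _sire_coverage_ok(counts, sires, part, nm, nf):
    """Under participation 'one' every male must sire >= 1 offspring."""
    if part != PART_ONE:
        return True
    used = np.zeros(nm, dtype=np.int64)
    for d in range(nf):
        if counts[d] > 0:
            used[sires[d]] = 1
    return used.sum() == nm


@njit(cache=True)
def _init_state(counts, sires, W, part, nm, nf, N_t, greedy):
    floor = 0 if part == PART_FREE else 1
    for d in range(nf):
        counts[d] = floor
    left = N_t - floor * nf
    if greedy:
        d = 0
        while left > 0:  # round-robin spread of the remaining slots
            counts[d % nf] += 1
            left -= 1
            d += 1
    else:
        while left > 0:  # random spread for restart diversity
            counts[np.random.randint(0, nf)] += 1
            left -= 1
    for d in range(nf):
        if greedy:
            best = 0
            for s in range(1, nm):
                if W[s, d] < W[best, d]:
                    best = s
            sires[d] = best
        else:
            sires[d] = np.random.randint(0, nm)
    if part == PART_ONE:
        # force coverage: dams 0..nm-1 exist because nm <= nf and floor=1
        for s in range(nm):
            sires[s] = s


@njit(cache=True)
def _hill_climb(counts, sires, K, W, g, family, p1, part, nm, nf, N_t, max_passes):
    floor = 0 if part == PART_FREE else 1
    obj = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
    for _ in range(max_passes):
        improved = False
        # sire reassignment
        for d in range(nf):
            if counts[d] == 0:
                continue
            old = sires[d]
            for s in range(nm):
                if s == old:
                    continue
                sires[d] = s
                if _sire_coverage_ok(counts, sires, part, nm, nf):
                    cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                    if cand < obj - 1e-12:
                        obj = cand
                        old = s
                        improved = True
                        continue
                sires[d] = old
        # move one offspring slot between dams, jointly retrying the
        # affected dams' sires (escapes shallow local minima); the donor
        # sire is only retried on small instances to bound the pass cost
        deep = nm * nf <= 42
        for d1 in range(nf):
            if counts[d1] <= floor:
                continue
            for d2 in range(nf):
                if d2 == d1:
                    continue
                counts[d1] -= 1
                counts[d2] += 1
                old1, old2 = sires[d1], sires[d2]
                n1 = nm if (deep and counts[d1] > 0) else 1
                n2 = nm if (deep or counts[d2] == 1) else 1
                done = False
                for s1 in range(n1):
                    if n1 > 1:
                        sires[d1] = s1
                    for s2 in range(n2):
                        if n2 > 1:
                            sires[d2] = s2
                        if not _sire_coverage_ok(counts, sires, part, nm, nf):
                            continue
                        cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                        if cand < obj - 1e-12:
                            obj = cand
                            improved = True
                            done = True
                            break
                    if done:
                        break
                if not done:
                    sires[d1], sires[d2] = old1, old2
                    counts[d1] += 1
                    counts[d2] -= 1
                if counts[d1] <= floor:
                    break
        # two-dam sire moves: full joint reassignment on small instances,
        # plain swaps at scale
        for d1 in range(nf):
            if counts[d1] == 0:
                continue
            for d2 in range(d1 + 1, nf):
                if counts[d2] == 0:
                    continue
                old1, old2 = sires[d1], sires[d2]
                done = False
                if deep:
                    for s1 in range(nm):
                        for s2 in range(nm):
                            if s1 == old1 and s2 == old2:
                                continue
                            sires[d1], sires[d2] = s1, s2
                            if not _sire_coverage_ok(counts, sires, part, nm, nf):
                                continue
                            cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                            if cand < obj - 1e-12:
                                obj = cand
                                improved = True
                                done = True
                                break
                        if done:
                            break
                elif old1 != old2:
                    sires[d1], sires[d2] = old2, old1
                    cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                    if cand < obj - 1e-12:
                        obj = cand
                        improved = True
                        done = True
                if not done:
                    sires[d1], sires[d2] = old1, old2
        if not improved:
            break
    return obj


@njit(cache=True)
def anneal(K, W, g, family, p1, part, nm, nf, N_t, n_proposals, n_restarts, seed):
    """Minimize the mating objective; returns (counts, sires, objective).

    Each restart runs geometric-cooling Metropolis sampling followed by a
    first-improvement hill climb over the full move neighbourhood; the
    best state across restarts is returned.
    """
    np.random.seed(seed)
    floor = 0 if part == PART_FREE else 1
    best_counts = np.zeros(nf, dtype=np.int64)
    best_sires = np.zeros(nf, dtype=np.int64)
    best_obj = np.inf
    counts = np.zeros(nf, dtype=np.int64)
    sires = np.zeros(nf, dtype=np.int64)
    seen_counts = np.zeros(nf, dtype=np.int64)
    seen_sires = np.zeros(nf, dtype=np.int64)
    for restart in range(n_restarts):
        _init_state(counts, sires, W, part, nm, nf, N_t, restart == 0)
        obj = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
        seen_obj = obj
        seen_counts[:] = counts
        seen_sires[:] = sires
        t0 = max(0.1 * abs(obj), 1e-3)
        t_end = 1e-6
        alpha = (t_end / t0) ** (1.0 / max(n_proposals - 1, 1))
        temp = t0
        for _ in range(n_proposals):
            kind = np.random.randint(0, 3)
            if kind == 0 and nm > 1:
                d = np.random.randint(0, nf)
                if counts[d] == 0:
                    temp *= alpha
                    continue
                old = sires[d]
                s = np.random.randint(0, nm)
                if s == old:
                    temp *= alpha
                    continue
                sires[d] = s
                if not _sire_coverage_ok(counts, sires, part, nm, nf):
                    sires[d] = old
                    temp *= alpha
                    continue
                cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                if cand <= obj or np.random.random() < np.exp(-(cand - obj) / temp):
                    obj = cand
                else:
                    sires[d] = old
            elif kind == 1 and nf > 1:
                d1 = np.random.randint(0, nf)
                d2 = np.random.randint(0, nf)
                if d1 == d2 or counts[d1] <= floor:
                    temp *= alpha
                    continue
                old_sire1 = sires[d1]
                old_sire2 = sires[d2]
                counts[d1] -= 1
                counts[d2] += 1
                # resample the affected dams' sires half the time so the
                # compound (slot + sire) transition is reachable directly
                if counts[d2] == 1 or np.random.random() < 0.5:
                    sires[d2] = np.random.randint(0, nm)
                if counts[d1] > 0 and np.random.random() < 0.5:
                    sires[d1] = np.random.randint(0, nm)
                if not _sire_coverage_ok(counts, sires, part, nm, nf):
                    counts[d1] += 1
                    counts[d2] -= 1
                    sires[d1] = old_sire1
                    sires[d2] = old_sire2
                    temp *= alpha
                    continue
                cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                if cand <= obj or np.random.random() < np.exp(-(cand - obj) / temp):
                    obj = cand
                else:
                    counts[d1] += 1
                    counts[d2] -= 1
                    sires[d1] = old_sire1
                    sires[d2] = old_sire2
            else:
                if nf > 1:
                    d1 = np.random.randint(0, nf)
                    d2 = np.random.randint(0, nf)
                    if d1 != d2 and counts[d1] > 0 and counts[d2] > 0 and sires[d1] != sires[d2]:
                        sires[d1], sires[d2] = sires[d2], sires[d1]
                        cand = _objective(counts, sires, K, W, g, family, p1, nm, nf, N_t)
                        if cand <= obj or np.random.random() < np.exp(-(cand - obj) / temp):
                            obj = cand
                        else:
                            sires[d1], sires[d2] = sires[d2], sires[d1]
            if obj < seen_obj - 1e-15:
                seen_obj = obj
                seen_counts[:] = counts
                seen_sires[:] = sires
            temp *= alpha
        # refine the best state seen during sampling, not the final one
        counts[:] = seen_counts
        sires[:] = seen_sires
        obj = _hill_climb(counts, sires, K, W, g, family, p1, part, nm, nf, N_t, 100)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_counts[:] = counts
            best_sires[:] = sires
    return best_counts, best_sires, best_obj
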