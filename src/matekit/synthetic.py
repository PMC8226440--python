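"""Seeded synthetic base pedigrees emulating the reference scenarios.

The two presets mirror the structure of the real reference cohorts used
throughout the package: a 6-male / 16-female cohort with mean inbreeding
around 0.26 and pedigree depth (equivalent complete generations) around
8.8, and an 8-male / 11-female cohort with mean F around 0.37 and depth
around 9.0.  The generator reaches those targets by random mating within
a small closed population: pedigree depth is set by the number of
generations simulated, and the inbreeding level by the number of
breeders per generation, calibrated on seeded pilot runs.  It is a
statistical stand-in for a real studbook, not a demographic model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedigree import FEMALE, MALE, Individual, Pedigree


@dataclass(frozen=True)
class ScenarioProfile:
    name: str
    n_males: int
    n_females: int
    target_mean_f: float
    target_eg: float
    seed: int = 0


PROFILES = {
    "almeria-like": ScenarioProfile("almeria-like", 6, 16, 0.26, 8.8),
    "lajita-like": ScenarioProfile("lajita-like", 8, 11, 0.37, 9.0),
}

#: |realized - target| tolerance on the final cohort's mean inbreeding
F_TOLERANCE = 0.05


def _simulate_closed_population(
    n_breeders: int,
    n_generations: int,
    final_n_males: int,
    final_n_females: int,
    rng: np.random.Generator,
    flock: str,
) -> tuple[list[Individual], list[str], float]:
    """Random mating among ``n_breeders`` per generation, then one final
    cohort with the requested sex counts.  Returns (records, cohort ids,
    realized mean F of the cohort).  Kinship is carried incrementally."""
    n = n_breeders
    nm = max(1, n // 2)
    ids = [f"{flock}:f0_{k}" for k in range(n)]
    sexes = [MALE] * nm + [FEMALE] * (n - nm)
    records = [Individual(i, None, None, s, 0.0, flock) for i, s in zip(ids, sexes)]
    K = 0.5 * np.eye(n)
    F = np.zeros(n)
    for t in range(1, n_generations):
        males = [k for k in range(n) if sexes[k] == MALE]
        females = [k for k in range(n) if sexes[k] == FEMALE]
        s_idx = rng.choice(males, size=n)
        d_idx = rng.choice(females, size=n)
        K_new = 0.25 * (
            K[np.ix_(s_idx, s_idx)] + K[np.ix_(s_idx, d_idx)]
            + K[np.ix_(d_idx, s_idx)] + K[np.ix_(d_idx, d_idx)]
        )
        F = K[s_idx, d_idx].copy()
        np.fill_diagonal(K_new, 0.5 * (1.0 + F))
        new_ids = [f"{flock}:s{t}_{k}" for k in range(n)]
        records.extend(
            Individual(new_ids[k], ids[s_idx[k]], ids[d_idx[k]], sexes[k], float(t), flock)
            for k in range(n)
        )
        ids, K = new_ids, K_new
        # sexes stay balanced and deterministic within each generation
    # final reference cohort with the exact requested sex counts
    t = n_generations
    n_off = final_n_males + final_n_females
    males = [k for k in range(n) if sexes[k] == MALE]
    females = [k for k in range(n) if sexes[k] == FEMALE]
    s_idx = rng.choice(males, size=n_off)
    d_idx = rng.choice(females, size=n_off)
    off_sexes = np.array([MALE] * final_n_males + [FEMALE] * final_n_females)
    rng.shuffle(off_sexes)
    cohort_ids = [f"{flock}:c_{k}" for k in range(n_off)]
    records.extend(
        Individual(cohort_ids[k], ids[s_idx[k]], ids[d_idx[k]], off_sexes[k], float(t), flock)
        for k in range(n_off)
    )
    mean_f = float(K[s_idx, d_idx].mean())
    return records, cohort_ids, mean_f


def _pilot_mean_f(profile: ScenarioProfile, n_breeders: int, n_generations: int, seed: int) -> float:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(n_breeders,))
    )
    _, _, mean_f = _simulate_closed_population(
        n_breeders, n_generations, profile.n_males, profile.n_females, rng, profile.name
    )
    return mean_f


def generate_base_pedigree(
    profile: ScenarioProfile, seed: int | None = None
) -> tuple[Pedigree, list[str]]:
    """Generate a pedigree whose final cohort matches the profile.

    The number of generations equals the rounded depth target (a complete
    pedigree of depth ``g`` has EG exactly ``g``).  The breeder count is
    found by a pilot search around the closed-form guess
    ``N = 1 / (2 dF)`` with ``dF = 1 - (1 - F)^(1/(g-1))``; because pilot
    and final run share the derived seed, the returned cohort realizes
    exactly the pilot's mean F.  Raises when no breeder count lands
    within ``F_TOLERANCE`` of the inbreeding target.
    """
    if seed is not None:
        profile = replace(profile, seed=seed)
    g = max(1, round(profile.target_eg))
    if profile.target_mean_f <= 0.0:
        n_breeders = max(4, profile.n_males + profile.n_females)
    else:
        if g <= 1:
            raise ValueError("cannot reach positive inbreeding with depth target <= 1")
        df_target = 1.0 - (1.0 - profile.target_mean_f) ** (1.0 / (g - 1))
        guess = int(round(1.0 / (2.0 * df_target)))
        candidates = range(max(2, guess - 6), guess + 7)
        scored = {
            n: abs(_pilot_mean_f(profile, n, g, profile.seed) - profile.target_mean_f)
            for n in candidates
        }
        n_breeders = min(scored, key=lambda n: (scored[n], n))
        if scored[n_breeders] > F_TOLERANCE:
            scored = {
                n: abs(_pilot_mean_f(profile, n, g, profile.seed) - profile.target_mean_f)
                for n in range(2, 61)
            }
            n_breeders = min(scored, key=lambda n: (scored[n], n))
            if scored[n_breeders] > F_TOLERANCE:
                raise RuntimeError(
                    f"no breeder count reaches mean F {profile.target_mean_f} "
                    f"within {F_TOLERANCE} at depth {g}; adjust the profile targets"
                )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=profile.seed, spawn_key=(n_breeders,))
    )
    records, cohort_ids, _ = _simulate_closed_population(
        n_breeders, g, profile.n_males, profile.n_females, rng, profile.name
    )
    return Pedigree(records), cohort_ids


def random_mating_pedigree(
    n_founders: int, n_generations: int, seed: int, cohort_size: int | None = None
) -> tuple[Pedigree, list[str]]:
    """Unstructured random-union pedigree (drift control / calibration).

    ``n_founders`` breeders per generation for ``n_generations``, final
    cohort of ``cohort_size`` (default ``n_founders``) with balanced
    sexes.
    """
    if cohort_size is None:
        cohort_size = n_founders
    nm = max(1, cohort_size // 2)
    rng = np.random.default_rng(seed)
    records, cohort_ids, _ = _simulate_closed_population(
        n_founders, n_generations, nm, cohort_size - nm, rng, "random"
    )
    return Pedigree(records), cohort_ids
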