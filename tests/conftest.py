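from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from matekit import FEMALE, MALE, Individual, Pedigree


def make_random_pedigree(seed: int, n: int = 12) -> tuple[Pedigree, dict]:
    """Random valid pedigree of ``n`` individuals; parents drawn among
    earlier individuals (or left unknown).  Returns the pedigree and the
    raw parent mapping for the path-counting oracle."""
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    parents: dict[str, tuple[str | None, str | None]] = {}
    for k in range(n):
        id_ = f"i{k}"
        sex = MALE if rng.random() < 0.5 else FEMALE
        sire = dam = None
        if males and rng.random() < 0.7:
            sire = males[int(rng.integers(len(males)))]
        if females and rng.random() < 0.7:
            dam = females[int(rng.integers(len(females)))]
        inds.append(Individual(id_, sire, dam, sex, birth_time=float(k)))
        parents[id_] = (sire, dam)
        (males if sex == MALE else females).append(id_)
    return Pedigree(inds), parents


@pytest.fixture
def fullsib_pedigree() -> Pedigree:
    """Two founders, two full-sib offspring, and an offspring of the sibs."""
    return Pedigree(
        [
            Individual("A", sex=MALE, birth_time=0),
            Individual("B", sex=FEMALE, birth_time=0),
            Individual("S1", "A", "B", MALE, 1),
            Individual("S2", "A", "B", FEMALE, 1),
            Individual("X", "S1", "S2", MALE, 2),
        ]
    )


@pytest.fixture
def founder_group() -> Pedigree:
    """Four unrelated founders (2 males, 2 females)."""
    return Pedigree(
        [
            Individual("M1", sex=MALE),
            Individual("M2", sex=MALE),
            Individual("F1", sex=FEMALE),
            Individual("F2", sex=FEMALE),
        ]
    )
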