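"""Independent path-counting kinship oracle for cross-checking.

Implements Wright's classical path-counting rules directly: the
coancestry of two distinct individuals is the sum, over every common
ancestor A and every pair of ancestral paths that meet only at A, of
``(1/2)^(n1 + n2 + 1) * (1 + F_A)``.  Completely independent of the
tabular recursion used by the package: it enumerates explicit ancestral
paths through the pedigree DAG.  Exponential — use only on tiny
pedigrees.
"""

from __future__ import annotations

from functools import lru_cache


class PathKinship:
    """parents: mapping id -> (sire or None, dam or None)."""

    def __init__(self, parents: dict):
        self.parents = parents
        self._paths: dict = {}
        self._inb: dict = {}

    def paths_up(self, x):
        """All ancestral paths from x: (ancestor, length, frozenset of nodes)."""
        if x in self._paths:
            return self._paths[x]
        out = [(x, 0, frozenset([x]))]
        sire, dam = self.parents[x]
        for p in (sire, dam):
            if p is None:
                continue
            for anc, n, nodes in self.paths_up(p):
                out.append((anc, n + 1, nodes | {x}))
        self._paths[x] = out
        return out

    def inbreeding(self, x) -> float:
        if x not in self._inb:
            sire, dam = self.parents[x]
            self._inb[x] = (
                0.0 if sire is None or dam is None else self.kinship(sire, dam)
            )
        return self._inb[x]

    def kinship(self, x, y) -> float:
        if x == y:
            return 0.5 * (1.0 + self.inbreeding(x))
        total = 0.0
        for anc1, n1, nodes1 in self.paths_up(x):
            for anc2, n2, nodes2 in self.paths_up(y):
                if anc1 != anc2:
                    continue
                if nodes1 & nodes2 != {anc1}:
                    continue
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + self.inbreeding(anc1))
        return total
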