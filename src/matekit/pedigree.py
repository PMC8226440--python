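"""Pedigree parsing, validation and relationship computations.

A studbook-style pedigree is a directed acyclic graph in which every
individual points to at most one sire and one dam.  From that graph this
module computes the quantities that drive genetic management of small
captive populations:

* coancestry (kinship) ``C_jk`` — the probability that two alleles drawn
  at random, one from each of two individuals, are identical by descent;
* the inbreeding coefficient ``F_i = C(sire_i, dam_i)``;
* equivalent complete generations (EG), a pedigree-depth measure;
* the generation interval, i.e. the mean age of parents at the birth of
  the offspring that themselves go on to reproduce.

Individuals whose parents are both unrecorded are treated as unrelated,
non-inbred founders.  An unrecorded single parent contributes zero to the
kinship and EG recursions.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MALE = "M"
FEMALE = "F"

#: parent codes interpreted as "unknown" by default when reading files
DEFAULT_UNKNOWN_CODES = frozenset({"", "0", "UNK"})

_SEX_CODES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad parents...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record.

    Parameters
    ----------
    id :
        Unique identifier.
    sire_id, dam_id :
        Identifiers of the parents, or ``None`` when unrecorded.
    sex :
        ``"M"`` or ``"F"``.
    birth_time :
        Birth year for real studbooks, generation index for simulated
        pedigrees, or ``None``.
    flock :
        Location / herd label, or ``None``.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = FEMALE
    birth_time: float | None = None
    flock: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(f"individual {self.id!r}: sex must be 'M' or 'F', got {self.sex!r}")
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"cycle detected: individual {self.id!r} is its own parent")


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric coancestry matrix over an ordered set of individuals.

    ``values[i, j]`` is the coancestry ``C_ij``; the diagonal holds the
    self-coancestry ``(1 + F_i) / 2``.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match id list")
        object.__setattr__(self, "values", v)

    def index(self, id_: str) -> int:
        return self.ids.index(id_)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self.index(i) for i in ids]
        return KinshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")


@dataclass(frozen=True)
class PedigreeStats:
    """Structure summary of a reference cohort (counts, F, EG, interval)."""

    n_males: int
    n_females: int
    sex_ratio: float
    mean_F: float
    mean_F_males: float
    mean_F_females: float
    mean_EG: float
    sd_EG: float
    generation_interval: float | None

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


class Pedigree:
    """A validated, topologically sorted pedigree.

    Iteration and positional indexing follow a deterministic topological
    order (parents before offspring), so any two row orderings of the same
    records produce identical computations.
    """

    def __init__(self, individuals: Iterable[Individual], validate_birth_order: bool = True):
        inds = list(individuals)
        ids = [i.id for i in inds]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise PedigreeError(f"duplicate individual id {dup!r}")
        by_id = {i.id: i for i in inds}
        self._validate_parents(inds, by_id)
        self._inds = self._topo_sort(inds, by_id)
        self._index = {ind.id: k for k, ind in enumerate(self._inds)}
        self._sire = np.array(
            [self._index.get(i.sire_id, -1) if i.sire_id is not None else -1 for i in self._inds],
            dtype=np.int64,
        )
        self._dam = np.array(
            [self._index.get(i.dam_id, -1) if i.dam_id is not None else -1 for i in self._inds],
            dtype=np.int64,
        )
        if validate_birth_order:
            self._validate_birth_order()
        self._kinship_cache: np.ndarray | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _validate_parents(inds: list[Individual], by_id: Mapping[str, Individual]) -> None:
        as_sire = {i.sire_id for i in inds if i.sire_id is not None}
        as_dam = {i.dam_id for i in inds if i.dam_id is not None}
        both = as_sire & as_dam
        if both:
            raise PedigreeError(f"id(s) used both as sire and dam: {sorted(both)}")
        for ind in inds:
            for pid, want in ((ind.sire_id, MALE), (ind.dam_id, FEMALE)):
                if pid is None:
                    continue
                parent = by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"individual {ind.id!r} references missing parent {pid!r}"
                    )
                if parent.sex != want:
                    raise PedigreeError(
                        f"parent {pid!r} of {ind.id!r} has sex {parent.sex}, expected {want}"
                    )

    @staticmethod
    def _topo_sort(inds: list[Individual], by_id: Mapping[str, Individual]) -> list[Individual]:
        g = nx.DiGraph()
        g.add_nodes_from(by_id)
        for ind in inds:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        try:
            order = list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise PedigreeError(
                f"pedigree contains a cycle through {cycle[0][0]!r}"
            ) from None
        return [by_id[i] for i in order]

    def _validate_birth_order(self) -> None:
        for ind in self._inds:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is None or ind.birth_time is None:
                    continue
                pb = self[pid].birth_time
                if pb is not None and not (ind.birth_time > pb):
                    raise PedigreeError(
                        f"individual {ind.id!r} born at {ind.birth_time} not after "
                        f"parent {pid!r} born at {pb}"
                    )

    # -- container protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self._inds)

    def __iter__(self):
        return iter(self._inds)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def __getitem__(self, id_: str) -> Individual:
        return self._inds[self._index[id_]]

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self._inds]

    def position(self, id_: str) -> int:
        return self._index[id_]

    def append(self, individual: Individual) -> None:
        """Add one individual whose parents (if any) are already present.

        The topological order is maintained (the newcomer goes last) and
        cached relationship matrices are invalidated.
        """
        if individual.id in self._index:
            raise PedigreeError(f"duplicate individual id {individual.id!r}")
        self._validate_parents([individual], {**{i.id: i for i in self._inds},
                                              individual.id: individual})
        self._inds.append(individual)
        k = len(self._inds) - 1
        self._index[individual.id] = k
        self._sire = np.append(self._sire, self._index.get(individual.sire_id, -1)
                               if individual.sire_id is not None else -1)
        self._dam = np.append(self._dam, self._index.get(individual.dam_id, -1)
                              if individual.dam_id is not None else -1)
        self._kinship_cache = None

    # -- relationship computations ------------------------------------------

    def _full_kinship(self) -> np.ndarray:
        """Tabular kinship over the whole pedigree (cached)."""
        if self._kinship_cache is None:
            n = len(self._inds)
            f = np.zeros((n, n))
            s, d = self._sire, self._dam
            for i in range(n):
                si, di = s[i], d[i]
                if i > 0:
                    row_s = f[si, :i] if si >= 0 else 0.0
                    row_d = f[di, :i] if di >= 0 else 0.0
                    row = 0.5 * (row_s + row_d)
                    f[i, :i] = row
                    f[:i, i] = row
                fpar = f[si, di] if (si >= 0 and di >= 0) else 0.0
                f[i, i] = 0.5 * (1.0 + fpar)
            self._kinship_cache = f
        return self._kinship_cache

    def kinship(self, subset: Sequence[str] | None = None) -> KinshipMatrix:
        """Coancestry matrix for ``subset`` (default: everyone).

        Uses the tabular method: processing individuals parents-first,
        ``C_xy = (C(sire_x, y) + C(dam_x, y)) / 2`` for ``y`` preceding
        ``x``, and ``C_xx = (1 + C(sire_x, dam_x)) / 2``; an unknown
        parent contributes 0.
        """
        if subset is None:
            subset = self.ids
        subset = list(subset)
        if not subset:
            raise ValueError("kinship subset must not be empty")
        missing = [i for i in subset if i not in self._index]
        if missing:
            raise KeyError(f"ids not in pedigree: {missing}")
        f = self._full_kinship()
        idx = [self._index[i] for i in subset]
        return KinshipMatrix(tuple(subset), f[np.ix_(idx, idx)].copy())

    def inbreeding(self, id_: str | None = None):
        """Inbreeding coefficient(s): ``F_i`` = coancestry of the parents.

        With no argument, returns a ``pandas.Series`` for every individual.
        """
        f = self._full_kinship()
        s, d = self._sire, self._dam
        known = (s >= 0) & (d >= 0)
        F = np.where(known, f[s, d], 0.0)
        if id_ is None:
            return pd.Series(F, index=self.ids, name="F")
        return float(F[self._index[id_]])

    def equivalent_generations(self, id_: str | None = None):
        """Equivalent complete generations: sum of ``(1/2)^n`` over all
        known ancestors, ``n`` generations away.  Computed by the
        recursion ``EG_i = sum over known parents of (1 + EG_parent)/2``.
        """
        n = len(self._inds)
        eg = np.zeros(n)
        s, d = self._sire, self._dam
        for i in range(n):
            v = 0.0
            if s[i] >= 0:
                v += 0.5 * (1.0 + eg[s[i]])
            if d[i] >= 0:
                v += 0.5 * (1.0 + eg[d[i]])
            eg[i] = v
        if id_ is None:
            return pd.Series(eg, index=self.ids, name="EG")
        return float(eg[self._index[id_]])

    def parents_of_record(self) -> set[str]:
        """Ids of individuals that appear as a parent of someone."""
        out: set[str] = set()
        for ind in self._inds:
            if ind.sire_id is not None:
                out.add(ind.sire_id)
            if ind.dam_id is not None:
                out.add(ind.dam_id)
        return out

    def generation_interval(self) -> float | None:
        """Mean parental age at the birth of offspring kept for reproduction.

        Each (parent, offspring) link where the offspring itself has
        progeny and both birth times are known counts as one observation.
        Returns ``None`` when no such link exists.
        """
        reproducers = self.parents_of_record()
        gaps: list[float] = []
        for ind in self._inds:
            if ind.id not in reproducers or ind.birth_time is None:
                continue
            for pid in (ind.sire_id, ind.dam_id):
                if pid is None:
                    continue
                pb = self[pid].birth_time
                if pb is not None:
                    gaps.append(ind.birth_time - pb)
        if not gaps:
            return None
        return float(np.mean(gaps))

    def reference_cohort(
        self,
        flock: str | None = None,
        birth_window: tuple[float, float] | None = None,
    ) -> list[str]:
        """Ids matching a flock label and an inclusive birth window."""
        out = []
        for ind in self._inds:
            if flock is not None and ind.flock != flock:
                continue
            if birth_window is not None:
                lo, hi = birth_window
                if ind.birth_time is None or not (lo <= ind.birth_time <= hi):
                    continue
            out.append(ind.id)
        if not out:
            warnings.warn("reference cohort is empty", stacklevel=2)
        else:
            sexes = [self[i].sex for i in out]
            logger.info(
                "reference cohort: %d individuals (%d males, %d females)",
                len(out), sexes.count(MALE), sexes.count(FEMALE),
            )
        return out

    def stats(self, cohort_ids: Sequence[str]) -> PedigreeStats:
        """Cohort structure panel: counts, sex ratio, F and EG summaries,
        plus the whole-pedigree generation interval."""
        cohort = [self[i] for i in cohort_ids]
        males = [i.id for i in cohort if i.sex == MALE]
        females = [i.id for i in cohort if i.sex == FEMALE]
        F = self.inbreeding()
        eg = self.equivalent_generations()
        Fc = F[list(cohort_ids)]
        egc = eg[list(cohort_ids)]
        return PedigreeStats(
            n_males=len(males),
            n_females=len(females),
            sex_ratio=len(females) / len(males) if males else float("inf"),
            mean_F=float(Fc.mean()),
            mean_F_males=float(F[males].mean()) if males else float("nan"),
            mean_F_females=float(F[females].mean()) if females else float("nan"),
            mean_EG=float(egc.mean()),
            sd_EG=float(egc.std(ddof=1)) if len(cohort_ids) > 1 else 0.0,
            generation_interval=self.generation_interval(),
        )

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self._inds],
                "sire": [i.sire_id or "" for i in self._inds],
                "dam": [i.dam_id or "" for i in self._inds],
                "sex": [i.sex for i in self._inds],
                "birth": [i.birth_time if i.birth_time is not None else "" for i in self._inds],
                "flock": [i.flock or "" for i in self._inds],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- file reading ------------------------------------------------------------

_COLUMN_ALIASES = {
    "id": ("id", "individual", "animal", "ind", "studbook_id", "number"),
    "sire": ("sire", "father", "sire_id", "padre"),
    "dam": ("dam", "mother", "dam_id", "madre"),
    "sex": ("sex", "gender", "sexo"),
    "birth": ("birth", "birth_year", "year", "birthdate", "birth_date", "yob"),
    "flock": ("flock", "location", "herd", "site", "population"),
}


def _detect_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        counts = {sep: sample.count(sep) for sep in ("\t", ",", ";")}
        return max(counts, key=counts.get)


def _map_columns(columns: Sequence[str], overrides: Mapping[str, str] | None) -> dict[str, str]:
    overrides = dict(overrides or {})
    lower = {c.lower().strip(): c for c in columns}
    out: dict[str, str] = {}
    for role, aliases in _COLUMN_ALIASES.items():
        if role in overrides:
            out[role] = overrides[role]
            continue
        for a in aliases:
            if a in lower:
                out[role] = lower[a]
                break
    for required in ("id", "sire", "dam", "sex"):
        if required not in out:
            raise PedigreeError(
                f"could not locate a {required!r} column among {list(columns)}; "
                "pass an explicit column mapping"
            )
    return out


def read_pedigree(
    path,
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
    unknown_codes: Iterable[str] = DEFAULT_UNKNOWN_CODES,
    validate_birth_order: bool = True,
) -> Pedigree:
    """Read a delimited studbook-style pedigree file.

    The delimiter is auto-detected among tab / comma / semicolon unless
    given.  Column roles (id, sire, dam, sex, birth, flock) are matched
    case-insensitively against common aliases, or supplied explicitly via
    ``columns``.  Parent codes in ``unknown_codes`` map to "unknown".
    Sex codes accepted: M/F, male/female, 1/2 (case-insensitive).
    """
    unknown = {str(c).strip().lower() for c in unknown_codes} | {"nan"}
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if delimiter is None:
        delimiter = _detect_delimiter("\n".join(text.splitlines()[:50]))
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str, keep_default_na=False)
    roles = _map_columns(df.columns, columns)

    def clean_parent(v: str) -> str | None:
        v = str(v).strip()
        return None if v.lower() in unknown else v

    inds = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        sex_raw = str(rec[roles["sex"]]).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise PedigreeError(f"line {lineno}: unrecognised sex code {rec[roles['sex']]!r}")
        birth = None
        if "birth" in roles:
            braw = str(rec[roles["birth"]]).strip()
            if braw and braw.lower() not in unknown:
                try:
                    birth = float(braw[:4]) if not braw.replace(".", "").isdigit() else float(braw)
                except ValueError:
                    raise PedigreeError(f"line {lineno}: unparseable birth value {braw!r}")
        flock = None
        if "flock" in roles:
            fraw = str(rec[roles["flock"]]).strip()
            flock = fraw or None
        inds.append(
            Individual(
                id=str(rec[roles["id"]]).strip(),
                sire_id=clean_parent(rec[roles["sire"]]),
                dam_id=clean_parent(rec[roles["dam"]]),
                sex=_SEX_CODES[sex_raw],
                birth_time=birth,
                flock=flock,
            )
        )
    return Pedigree(inds, validate_birth_order=validate_birth_order)
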