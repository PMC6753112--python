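"""Pedigree representation, FAM-file I/O, kinship and relative-pair extraction.

A pedigree is a set of disjoint families of individuals, each with an
optional father and mother within the same family.  The expected additive
covariance between relatives is ``2 * Phi`` where ``Phi`` is the kinship
coefficient computed recursively from the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "KinshipMatrix",
    "RelativePairSet",
    "parse_pedigree",
    "write_fam",
    "kinship_matrix",
    "extract_relative_pairs",
]

MALE, FEMALE = 1, 2
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass(frozen=True)
class Individual:
    fid: str
    iid: str
    father: str = UNKNOWN   # IID within the same family, "0" if unknown
    mother: str = UNKNOWN
    sex: int = 0            # 1 male, 2 female, 0 unknown
    phenotyped: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


class Pedigree:
    """Validated collection of :class:`Individual` records.

    Validation enforces unique IDs within a family, acyclicity, and
    father/mother sex consistency.  A parent referenced but absent from the
    family is treated as unknown (founder on that side).
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._index = {ind.key: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            seen: set[tuple[str, str]] = set()
            for ind in self.individuals:
                if ind.key in seen:
                    raise PedigreeError(f"duplicate individual {ind.fid}:{ind.iid}")
                seen.add(ind.key)
        self.individuals = self._normalise_parents(self.individuals)
        self._index = {ind.key: i for i, ind in enumerate(self.individuals)}
        self._validate()

    @staticmethod
    def _normalise_parents(inds: list[Individual]) -> list[Individual]:
        present = {(i.fid, i.iid) for i in inds}
        out = []
        for ind in inds:
            fa = ind.father if (ind.fid, ind.father) in present else UNKNOWN
            mo = ind.mother if (ind.fid, ind.mother) in present else UNKNOWN
            if (fa, mo) != (ind.father, ind.mother):
                ind = replace(ind, father=fa, mother=mo)
            out.append(ind)
        return out

    def _validate(self) -> None:
        for ind in self.individuals:
            if ind.father == ind.iid or ind.mother == ind.iid:
                raise PedigreeError(f"{ind.fid}:{ind.iid} listed as own parent")
            if ind.father != UNKNOWN:
                pa = self[(ind.fid, ind.father)]
                if pa.sex == FEMALE:
                    raise PedigreeError(
                        f"father {ind.fid}:{ind.father} of {ind.iid} is recorded female"
                    )
            if ind.mother != UNKNOWN:
                mo = self[(ind.fid, ind.mother)]
                if mo.sex == MALE:
                    raise PedigreeError(
                        f"mother {ind.fid}:{ind.mother} of {ind.iid} is recorded male"
                    )
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, key: tuple[str, str]) -> Individual:
        return self.individuals[self._index[key]]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._index

    @property
    def ids(self) -> list[tuple[str, str]]:
        return [ind.key for ind in self.individuals]

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.fid, None)
        return list(seen)

    def family(self, fid: str) -> list[Individual]:
        return [i for i in self.individuals if i.fid == fid]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals
                if i.father == UNKNOWN and i.mother == UNKNOWN]

    def phenotyped_ids(self) -> list[tuple[str, str]]:
        return [i.key for i in self.individuals if i.phenotyped]

    def parents_of(self, key: tuple[str, str]) -> tuple[tuple[str, str] | None,
                                                        tuple[str, str] | None]:
        ind = self[key]
        fa = (ind.fid, ind.father) if ind.father != UNKNOWN else None
        mo = (ind.fid, ind.mother) if ind.mother != UNKNOWN else None
        return fa, mo

    def topological_order(self) -> list[tuple[str, str]]:
        """IDs with every parent before its children (Kahn's algorithm)."""
        children: dict[tuple[str, str], list[tuple[str, str]]] = {}
        indeg = {ind.key: 0 for ind in self.individuals}
        for ind in self.individuals:
            for par in self.parents_of(ind.key):
                if par is not None:
                    children.setdefault(par, []).append(ind.key)
                    indeg[ind.key] += 1
        queue = [k for k, d in indeg.items() if d == 0]
        order: list[tuple[str, str]] = []
        while queue:
            k = queue.pop()
            order.append(k)
            for ch in children.get(k, ()):
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(self.individuals):
            stuck = sorted(k for k, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree cycle involving {stuck[0][0]}:{stuck[0][1]}")
        return order

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "FID": [i.fid for i in self.individuals],
                "IID": [i.iid for i in self.individuals],
                "PAT": [i.father for i in self.individuals],
                "MAT": [i.mother for i in self.individuals],
                "SEX": [i.sex for i in self.individuals],
                "PHENO": [1 if i.phenotyped else -9 for i in self.individuals],
            }
        )


def parse_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK FAM-dialect file (FID IID PAT MAT SEX PHENO).

    Column 6 encodes phenotyped status: 0 or -9 means unphenotyped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     names=["FID", "IID", "PAT", "MAT", "SEX", "PHENO"])
    inds = [
        Individual(
            fid=r.FID, iid=r.IID, father=r.PAT, mother=r.MAT,
            sex=int(r.SEX), phenotyped=r.PHENO not in ("0", "-9"),
        )
        for r in df.itertuples()
    ]
    return Pedigree(inds)


def write_fam(ped: Pedigree, path: str | Path) -> None:
    ped.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Kinship coefficients Phi over an ordered set of individuals.

    The additive (numerator) relationship matrix is ``2 * values``;
    diagonal entries are ``0.5 * (1 + f)`` with inbreeding ``f``.
    Cross-family entries are exactly zero.
    """

    ids: list[tuple[str, str]]
    values: np.ndarray

    def relationship(self) -> np.ndarray:
        return 2.0 * self.values

    def subset(self, ids: Sequence[tuple[str, str]]) -> "KinshipMatrix":
        pos = {k: i for i, k in enumerate(self.ids)}
        idx = np.array([pos[k] for k in ids])
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


def kinship_matrix(ped: Pedigree,
                   ids: Sequence[tuple[str, str]] | None = None) -> KinshipMatrix:
    """Recursive pedigree kinship.

    Phi(i,i) = 0.5 * (1 + Phi(father_i, mother_i));
    Phi(i,j) = 0.5 * (Phi(father_i, j) + Phi(mother_i, j)) taking i as the
    later individual in topological order; unknown parents contribute 0.
    """
    order = ped.topological_order()
    pos = {k: i for i, k in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k in order:
        i = pos[k]
        fa, mo = ped.parents_of(k)
        fi = pos[fa] if fa is not None else None
        mi = pos[mo] if mo is not None else None
        phi[i, i] = 0.5 * (1.0 + (phi[fi, mi] if fi is not None and mi is not None
                                  else 0.0))
        # all previously-placed j: parents of i already have rows filled
        row = np.zeros(i)
        if fi is not None:
            row += 0.5 * phi[fi, :i]
        if mi is not None:
            row += 0.5 * phi[mi, :i]
        phi[i, :i] = row
        phi[:i, i] = row
    out_ids = list(ids) if ids is not None else ped.ids
    sel = np.array([pos[k] for k in out_ids])
    return KinshipMatrix(out_ids, phi[np.ix_(sel, sel)])


# ---------------------------------------------------------------------------
# Relative pairs
# ---------------------------------------------------------------------------

PAIR_CLASSES = ("sibling", "parent-child", "avuncular")


@dataclass
class RelativePairSet:
    """Relative pairs by class; each unordered pair appears once.

    Parent-child pairs are ordered parent-first; sibling and avuncular
    pairs are stored in a canonical (sorted) order.
    """

    pairs: dict[str, list[tuple[tuple[str, str], tuple[str, str]]]] = field(
        default_factory=dict)

    def __getitem__(self, cls: str):
        return self.pairs.get(cls, [])


def _full_sibs(ped: Pedigree, fid: str) -> list[tuple[Individual, Individual]]:
    fam = ped.family(fid)
    out = []
    for a_idx in range(len(fam)):
        for b_idx in range(a_idx + 1, len(fam)):
            a, b = fam[a_idx], fam[b_idx]
            if (a.father != UNKNOWN and a.mother != UNKNOWN
                    and a.father == b.father and a.mother == b.mother):
                out.append((a, b))
    return out


def extract_relative_pairs(ped: Pedigree,
                           classes: Sequence[str] = PAIR_CLASSES) -> RelativePairSet:
    """Enumerate sibling, parent-child and avuncular pairs.

    Avuncular = one member is a full sibling of a parent of the other.
    """
    out: dict[str, list] = {c: [] for c in classes}
    for fid in ped.family_ids:
        fam = ped.family(fid)
        if "sibling" in out:
            for a, b in _full_sibs(ped, fid):
                out["sibling"].append(tuple(sorted((a.key, b.key))))
        if "parent-child" in out:
            for ind in fam:
                for par in ped.parents_of(ind.key):
                    if par is not None:
                        out["parent-child"].append((par, ind.key))
        if "avuncular" in out:
            sib_lookup: dict[str, set[str]] = {}
            for a, b in _full_sibs(ped, fid):
                sib_lookup.setdefault(a.iid, set()).add(b.iid)
                sib_lookup.setdefault(b.iid, set()).add(a.iid)
            for ind in fam:
                for par in ped.parents_of(ind.key):
                    if par is None:
                        continue
                    for unc in sib_lookup.get(par[1], ()):
                        out["avuncular"].append(
                            tuple(sorted(((fid, unc), ind.key))))
    for c in out:
        out[c] = sorted(set(out[c]))
    return RelativePairSet(out)
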