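"""Independent reference implementations used only by the test suite.

These deliberately use different algorithms from the package: kinship by
Wright's path counting, Hardy-Weinberg by direct enumeration over
heterozygote counts, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from famh2.pedigree import FEMALE, MALE, Individual, Pedigree


# ---------------------------------------------------------------------------
# Wright's path-counting kinship
# ---------------------------------------------------------------------------

def _ancestor_paths(ped: Pedigree, key):
    """All upward paths from ``key``: list of (ancestor, depth, node-set)."""
    paths = [(key, 0, frozenset([key]))]
    for par in ped.parents_of(key):
        if par is not None:
            for anc, d, nodes in _ancestor_paths(ped, par):
                paths.append((anc, d + 1, nodes | {key}))
    return paths


def kinship_path_counting(ped: Pedigree, a, b) -> float:
    """Kinship via sum over common ancestors of 0.5^(u+v+1) (1 + f_anc),
    counting only path pairs that meet exclusively at the ancestor."""
    if a == b:
        fa, mo = ped.parents_of(a)
        f = kinship_path_counting(ped, fa, mo) if fa and mo else 0.0
        return 0.5 * (1.0 + f)
    total = 0.0
    for anc_a, u, nodes_a in _ancestor_paths(ped, a):
        for anc_b, v, nodes_b in _ancestor_paths(ped, b):
            if anc_a != anc_b:
                continue
            if nodes_a & nodes_b != {anc_a}:
                continue
            fa, mo = ped.parents_of(anc_a)
            f = kinship_path_counting(ped, fa, mo) if fa and mo else 0.0
            total += 0.5 ** (u + v + 1) * (1.0 + f)
    return total


def random_pedigree(rng: np.random.Generator, max_members: int = 40) -> Pedigree:
    """Random multi-generation single-family pedigree (DAG by construction).

    Parents are drawn from already-created individuals, so relatives may
    mate and inbreeding can arise -- the path-counting oracle handles it.
    """
    n = int(rng.integers(6, max_members + 1))
    inds: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(n):
        iid = str(i + 1)
        sex = MALE if rng.random() < 0.5 else FEMALE
        father = mother = "0"
        if i >= 2 and males and females and rng.random() < 0.7:
            father = males[int(rng.integers(len(males)))]
            mother = females[int(rng.integers(len(females)))]
        inds.append(Individual("FAM", iid, father, mother, sex))
        (males if sex == MALE else females).append(iid)
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# Hardy-Weinberg by enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _lgamma(k: int) -> float:
    return math.lgamma(k + 1)


def hwe_enumeration_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE P by direct enumeration of all heterozygote counts at the
    observed allele counts, with log-factorial probabilities."""
    n = n_het + n_hom1 + n_hom2
    n_hom_min, n_hom_maj = sorted((n_hom1, n_hom2))
    rare = 2 * n_hom_min + n_het

    def logprob(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (h * math.log(2.0) + _lgamma(n)
                - _lgamma(h) - _lgamma(hom_r) - _lgamma(hom_c)
                + _lgamma(rare) + _lgamma(2 * n - rare) - _lgamma(2 * n))

    hs = [h for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)]
    logs = np.array([logprob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
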