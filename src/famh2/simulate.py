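"""Synthetic family-cohort generator with known ground truth.

Emulates the statistical structure of an extended-family cardiovascular
phenotyping study: ~116 families with ~427 phenotyped members, polygenic
traits with target narrow-sense heritabilities, anthropometric and blood
pressure covariates, and the confounding structure in which ECG-derived
left-ventricular mass correlates with the lateral diameter of the chest
(target Spearman rho ~ 0.67).

Family structures are built from four templates (exact study structures
are unpublished); in each template some members -- typically one parent
and married-in spouses -- are unphenotyped connectors, which is what makes
a mean of ~3.8 phenotyped members per family reachable with nuclear and
three-generation families.

All randomness flows from a single seed through named substreams
(:mod:`famh2._streams`): identical (spec, seed) gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._streams import stream
from .genotypes import GenotypeMatrix, write_ped_map
from .pedigree import FEMALE, MALE, UNKNOWN, Individual, Pedigree, write_fam

__all__ = [
    "PedigreeSpec",
    "GenotypeSpec",
    "TraitModel",
    "SimulatedCohort",
    "simulate_pedigrees",
    "drop_genotypes",
    "simulate_polygenic",
    "simulate_traits",
    "simulate_cohort",
    "write_cohort",
    "TEMPLATE_NAMES",
]

# template name -> (total members, phenotyped members)
TEMPLATE_SIZES = {
    "nuclear-2child": (4, 3),
    "nuclear-3child": (5, 4),
    "three-generation": (7, 5),
    "sibship-with-avuncular": (7, 5),
}
TEMPLATE_NAMES = tuple(TEMPLATE_SIZES)

DEFAULT_TEMPLATES = (
    ("nuclear-2child", 0.5),
    ("nuclear-3child", 0.2),
    ("three-generation", 0.2),
    ("sibship-with-avuncular", 0.1),
)


@dataclass
class PedigreeSpec:
    n_families: int = 116
    family_templates: Sequence[tuple[str, float]] = DEFAULT_TEMPLATES
    target_total_individuals: int = 427
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        tot = sum(w for _, w in self.family_templates)
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("template relative frequencies must sum to 1")
        for name, _ in self.family_templates:
            if name not in TEMPLATE_SIZES:
                raise ValueError(f"unknown family template {name!r}")


@dataclass
class GenotypeSpec:
    n_snps: int = 2000
    n_causal: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    allele_freqs: np.ndarray | None = None   # per-SNP, optional

    def __post_init__(self):
        low, high = self.maf_range
        low = max(low, 1e-3)
        high = min(high, 0.5 - 1e-9)
        if not (0 < low <= high < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        self.maf_range = (low, high)
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")


@dataclass
class TraitModel:
    """Ground-truth parameters for the simulated cohort.

    ``h2`` gives each heritable component's narrow-sense heritability;
    ``residual_sd`` the SD of that component net of modelled covariates.
    ``chest_loading`` is the coefficient (mV per cm) of chest lateral
    diameter on the latent ECG voltage that feeds RaVL+SV3, which creates
    the chest-size confounding of ECG LVM.  ``voltage_scale`` is the
    scale at which the ECG-LVM equation should be applied to voltages in
    mV (recorded in the truth manifest).
    """

    h2: dict[str, float] = field(default_factory=lambda: {
        "height": 0.75,
        "chest": 0.60,
        "ecg_voltage": 0.60,
        "cmr_lvm": 0.20,
        "rv_mass": 0.44,
    })
    residual_sd: dict[str, float] = field(default_factory=lambda: {
        "height": 6.5,       # cm, net of sex
        "chest": 2.5,        # cm, net of height pathway
        "ecg_voltage": 2.5,  # mV, latent RaVL+SV3 component net of chest
        "cmr_lvm": 20.0,     # g, net of sex/weight/SBP
        "rv_mass": 10.0,     # g
    })
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "chest_per_height": 0.01,      # cm chest per cm height
        "chest_per_weight": 0.0,       # cm chest per kg
        "lvm_per_weight": 0.55,        # g per kg
        "lvm_per_sbp": 0.30,           # g per mmHg
        "rvm_per_weight": 0.30,
        "sl_per_chest": 0.50,          # SV1+RV5 mV per cm chest
        "sl_per_voltage": 0.90,        # SV1+RV5 mV per mV latent
        "sum_per_voltage": 3.0,        # 12-lead sum mV per mV latent
        "sum_per_chest": 1.2,
    })
    chest_loading: float = 4.8         # mV (RaVL+SV3) per cm chest diameter
    treatment_prevalence: float = 0.30
    ecg_missing_rate: float = 0.05     # mirrors study-scale ECG exclusions
    cmr_missing_rate: float = 0.05
    voltage_scale: float = 100.0

    def __post_init__(self):
        for t, v in self.h2.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"h2[{t!r}] outside [0, 1]")
        for t, v in self.residual_sd.items():
            if v <= 0:
                raise ValueError(f"residual_sd[{t!r}] must be positive")


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Pedigree templates
# ---------------------------------------------------------------------------

def _couple(iid_m: str, iid_f: str, sex_first: int):
    """Order (father, mother) given the sex of the first partner."""
    return (iid_m, iid_f) if sex_first == MALE else (iid_f, iid_m)


def _build_family(name: str, fid: str, rng: np.random.Generator) -> list[Individual]:
    def child_sex() -> int:
        return MALE if rng.random() < 0.5 else FEMALE

    if name == "nuclear-2child":
        inds = [Individual(fid, "1", sex=MALE, phenotyped=False),
                Individual(fid, "2", sex=FEMALE, phenotyped=True)]
        for iid in ("3", "4"):
            inds.append(Individual(fid, iid, "1", "2", child_sex(), True))
        return inds
    if name == "nuclear-3child":
        inds = [Individual(fid, "1", sex=MALE, phenotyped=False),
                Individual(fid, "2", sex=FEMALE, phenotyped=True)]
        for iid in ("3", "4", "5"):
            inds.append(Individual(fid, iid, "1", "2", child_sex(), True))
        return inds
    if name == "three-generation":
        s3 = child_sex()
        s4 = child_sex()
        inds = [Individual(fid, "1", sex=MALE, phenotyped=False),
                Individual(fid, "2", sex=FEMALE, phenotyped=True),
                Individual(fid, "3", "1", "2", s3, True),
                Individual(fid, "4", "1", "2", s4, True),
                Individual(fid, "5", sex=(FEMALE if s3 == MALE else MALE),
                           phenotyped=False)]
        fa, mo = _couple("3", "5", s3)
        for iid in ("6", "7"):
            inds.append(Individual(fid, iid, fa, mo, child_sex(), True))
        return inds
    if name == "sibship-with-avuncular":
        s3 = child_sex()
        inds = [Individual(fid, "1", sex=MALE, phenotyped=False),
                Individual(fid, "2", sex=FEMALE, phenotyped=True),
                Individual(fid, "3", "1", "2", s3, True),
                Individual(fid, "4", "1", "2", child_sex(), True),
                Individual(fid, "5", "1", "2", child_sex(), True),
                Individual(fid, "6", sex=(FEMALE if s3 == MALE else MALE),
                           phenotyped=False)]
        fa, mo = _couple("3", "6", s3)
        inds.append(Individual(fid, "7", fa, mo, child_sex(), True))
        return inds
    raise ValueError(f"unknown template {name!r}")


def _template_counts(spec: PedigreeSpec) -> dict[str, int]:
    names = [n for n, _ in spec.family_templates]
    weights = np.array([w for _, w in spec.family_templates])
    raw = weights * spec.n_families
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema)[: spec.n_families - counts.sum()]:
        counts[i] += 1
    cdict = dict(zip(names, counts))

    def total(c: dict[str, int]) -> int:
        return sum(n * TEMPLATE_SIZES[t][1] for t, n in c.items())

    target = spec.target_total_individuals
    tol = 0.05 * target
    sizes = {t: TEMPLATE_SIZES[t][1] for t in cdict}
    # greedy reassignment between templates to approach the target count
    while abs(total(cdict) - target) > tol:
        dev = total(cdict) - target
        moved = False
        for src in sorted(cdict, key=lambda t: sizes[t], reverse=bool(dev > 0)):
            if cdict[src] == 0:
                continue
            for dst in sorted(cdict, key=lambda t: sizes[t], reverse=bool(dev < 0)):
                delta = sizes[dst] - sizes[src]
                if (dev > 0 and delta < 0) or (dev < 0 and delta > 0):
                    if abs(dev + delta) < abs(dev):
                        cdict[src] -= 1
                        cdict[dst] += 1
                        moved = True
                        break
            if moved:
                break
        if not moved:
            raise ValueError(
                f"cannot reach ~{target} phenotyped individuals with "
                f"{spec.n_families} families from templates {list(cdict)}")
    return cdict


def simulate_pedigrees(spec: PedigreeSpec) -> Pedigree:
    """Generate ``spec.n_families`` disjoint families from the template mix.

    The phenotyped-member total is brought within 5% of
    ``target_total_individuals`` by adjusting template multiplicities;
    an unreachable target raises ``ValueError``.
    """
    rng = stream(spec.seed, "pedigree")
    counts = _template_counts(spec)
    assignment: list[str] = []
    for name, _ in spec.family_templates:
        assignment += [name] * counts[name]
    perm = rng.permutation(len(assignment))
    inds: list[Individual] = []
    width = max(4, len(str(spec.n_families)))
    for fnum, idx in enumerate(perm, start=1):
        fid = f"F{fnum:0{width}d}"
        inds += _build_family(assignment[idx], fid, rng)
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def drop_genotypes(ped: Pedigree, spec: GenotypeSpec, seed: int) -> GenotypeMatrix:
    """Gene-drop genotypes down the pedigree.

    Founder alleles are Bernoulli draws at each SNP's allele frequency;
    each non-founder allele is drawn uniformly from the corresponding
    parent's two alleles (an unknown parent contributes a fresh
    population-frequency draw).  Output is 0/1/2 dosage of the counted
    allele.
    """
    rng = stream(seed, "genotypes")
    m = spec.n_snps
    if spec.allele_freqs is not None:
        p = np.asarray(spec.allele_freqs, dtype=float)
        if p.shape != (m,):
            raise ValueError("allele_freqs length must equal n_snps")
    else:
        p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    order = ped.topological_order()
    pos = {k: i for i, k in enumerate(order)}
    n = len(order)
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)

    def transmit(parent_key):
        if parent_key is None:
            return (rng.random(m) < p).astype(np.int8)
        pi = pos[parent_key]
        pick = rng.random(m) < 0.5
        return np.where(pick, h1[pi], h2[pi])

    for k in order:
        i = pos[k]
        fa, mo = ped.parents_of(k)
        if fa is None and mo is None:
            h1[i] = rng.random(m) < p
            h2[i] = rng.random(m) < p
        else:
            h1[i] = transmit(fa)
            h2[i] = transmit(mo)
    dosage = (h1 + h2).astype(float)
    # reorder rows to pedigree order
    sel = np.array([pos[k] for k in ped.ids])
    snps = pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(m)],
        "chrom": np.ones(m, dtype=int),
        "pos": np.arange(1, m + 1) * 1000,
        "a1": ["A"] * m,
        "a2": ["B"] * m,
    })
    return GenotypeMatrix(list(ped.ids), snps, dosage[sel])


# ---------------------------------------------------------------------------
# Polygenic values and traits
# ---------------------------------------------------------------------------

def simulate_polygenic(ped: Pedigree, h2: float, mode: str = "pedigree-mvn",
                       genotypes: GenotypeMatrix | None = None,
                       seed: int = 0, n_causal: int = 20) -> np.ndarray:
    """Per-individual additive genetic values with variance ``h2``.

    pedigree-mvn: founders are independent N(0, h2); each non-founder is
    the mean of its parents' values plus an independent segregation
    deviate of variance h2/2 (non-inbred parents assumed).  The resulting
    covariance between relatives is ``2 Phi h2``.

    genotype-causal: sums standardized dosages at ``n_causal`` randomly
    chosen SNPs times N(0, h2 / n_causal) effects.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    rng = stream(seed, f"polygenic:{mode}")
    if h2 == 0.0:
        return np.zeros(len(ped))
    if mode == "pedigree-mvn":
        order = ped.topological_order()
        pos = {k: i for i, k in enumerate(order)}
        g = np.zeros(len(order))
        sg = math.sqrt(h2)
        for k in order:
            i = pos[k]
            fa, mo = ped.parents_of(k)
            if fa is None and mo is None:
                g[i] = rng.normal(0.0, sg)
            else:
                gf = g[pos[fa]] if fa is not None else rng.normal(0.0, sg)
                gm = g[pos[mo]] if mo is not None else rng.normal(0.0, sg)
                g[i] = 0.5 * (gf + gm) + rng.normal(0.0, sg / math.sqrt(2.0))
        sel = np.array([pos[k] for k in ped.ids])
        return g[sel]
    if mode == "genotype-causal":
        if genotypes is None:
            raise ValueError("genotype-causal mode requires genotypes")
        idx = rng.choice(genotypes.n_snps, size=min(n_causal, genotypes.n_snps),
                         replace=False)
        x = genotypes.dosage[:, idx]
        p = np.nanmean(x, axis=0) / 2.0
        z = (np.nan_to_num(x, nan=0.0) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        beta = rng.normal(0.0, math.sqrt(h2 / len(idx)), size=len(idx))
        g = z @ beta
        keys = {k: i for i, k in enumerate(genotypes.ids)}
        return np.array([g[keys[k]] for k in ped.ids])
    raise ValueError(f"unknown polygenic mode {mode!r}")


def _trunc_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


LEAD_WEIGHTS = np.array(
    [0.07, 0.09, 0.06, 0.05, 0.06, 0.07, 0.06, 0.10, 0.12, 0.12, 0.11, 0.09])
LEAD_NAMES = [f"lead_{i + 1}" for i in range(12)]


def simulate_traits(ped: Pedigree, model: TraitModel,
                    genetic: dict[str, np.ndarray], seed: int = 0) -> pd.DataFrame:
    """Build the per-individual covariate and raw-measurement table.

    ``genetic`` maps each heritable component named in ``model.h2`` to
    standardized genetic values (variance = the component's h2) aligned
    with ``ped.ids``.  Returns one row per phenotyped pedigree member.
    """
    for t in model.h2:
        if model.h2[t] > 0 and t not in genetic:
            raise ValueError(f"missing genetic values for heritable trait {t!r}")
    rng = stream(seed, "traits")
    n = len(ped)
    sexes = np.array([ind.sex for ind in ped.individuals])
    female = (sexes == FEMALE).astype(float)
    eff = model.covariate_effects
    sd = model.residual_sd
    h2 = model.h2

    def component(name: str) -> np.ndarray:
        g = genetic.get(name, np.zeros(n))
        e = rng.normal(0.0, math.sqrt(max(0.0, 1.0 - h2.get(name, 0.0))), n)
        return sd[name] * (g + e)

    age = _trunc_normal(rng, 59.7, 13.0, 18.0, 95.0, n)
    height = np.where(female == 1, 163.0, 176.0) + component("height")
    bmi = _trunc_normal(rng, 28.1, 4.8, 16.0, 50.0, n)
    weight = bmi * (height / 100.0) ** 2

    chest = (32.0
             + eff["chest_per_height"] * (height - 169.0)
             + eff["chest_per_weight"] * (weight - 79.3)
             + component("chest"))
    chest_ap = 22.0 + 0.08 * (weight - 79.3) + rng.normal(0.0, 1.5, n)
    chest_height = 24.0 + 0.07 * (height - 169.0) + rng.normal(0.0, 1.5, n)

    sbp_true = 140.5 + 0.25 * (weight - 79.3) + 0.3 * (age - 59.7) \
        + rng.normal(0.0, 15.0, n)
    dbp_true = 81.5 + 0.45 * (sbp_true - 140.5) + rng.normal(0.0, 8.0, n)
    treated = (rng.random(n) < model.treatment_prevalence)
    sbp = sbp_true - 15.0 * treated
    dbp = dbp_true - 10.0 * treated

    # CMR masses / volumes (tissue volume = mass / 1.05)
    lvm = (np.where(female == 1, 106.1, 149.2)
           + eff["lvm_per_weight"] * (weight - 79.3)
           + eff["lvm_per_sbp"] * (sbp_true - 140.5)
           + component("cmr_lvm"))
    lvm = np.clip(lvm, 40.0, None)
    rvm = (np.where(female == 1, 48.0, 66.0)
           + eff["rvm_per_weight"] * (weight - 79.3)
           + component("rv_mass"))
    rvm = np.clip(rvm, 15.0, None)
    lv_edv = np.clip(np.where(female == 1, 121.1, 149.4)
                     + 0.8 * (weight - 79.3) + rng.normal(0.0, 18.0, n), 50.0, None)
    ef = np.clip(rng.normal(0.70, 0.05, n), 0.45, 0.85)
    lv_esv = lv_edv * (1.0 - ef)
    rv_edv = np.clip(lv_edv + rng.normal(8.0, 12.0, n), 50.0, None)
    rv_esv = rv_edv * (1.0 - np.clip(rng.normal(0.62, 0.06, n), 0.40, 0.80))

    # ECG voltages (mV): latent myocardial component + chest-diameter loading
    myo = component("ecg_voltage")
    chest_dev = chest - chest.mean()
    c_raw = (np.where(female == 1, 11.1, 12.9)
             + model.chest_loading * chest_dev + myo)
    c_raw = np.clip(c_raw, 0.5, None)
    u = rng.uniform(0.30, 0.50, n)
    ravl = np.clip(u * c_raw, 0.05, None)
    sv3 = np.clip(c_raw - ravl, 0.05, None)

    sl_raw = (np.where(female == 1, 19.0, 21.1)
              + eff["sl_per_chest"] * chest_dev
              + eff["sl_per_voltage"] * myo + rng.normal(0.0, 3.0, n))
    sl_raw = np.clip(sl_raw, 1.0, None)
    u2 = rng.uniform(0.40, 0.60, n)
    sv1 = np.clip(u2 * sl_raw, 0.05, None)
    rv5 = np.clip(sl_raw - sv1, 0.05, None)

    total12 = (np.where(female == 1, 116.0, 129.3)
               + eff["sum_per_voltage"] * myo
               + eff["sum_per_chest"] * chest_dev + rng.normal(0.0, 12.0, n))
    total12 = np.clip(total12, 20.0, None)
    leads = total12[:, None] * LEAD_WEIGHTS[None, :] \
        * (1.0 + rng.normal(0.0, 0.05, (n, 12)))
    leads = np.clip(leads, 0.05, None)
    qrs = np.clip(rng.normal(88.0, 9.0, n), 60.0, 130.0)

    df = pd.DataFrame({
        "FID": [k[0] for k in ped.ids],
        "IID": [k[1] for k in ped.ids],
        "sex": sexes,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "sbp": sbp,
        "dbp": dbp,
        "treated": treated.astype(int),
        "chest_lat": chest,
        "chest_ap": chest_ap,
        "chest_height": chest_height,
        "lv_tissue_vol": lvm / 1.05,
        "rv_tissue_vol": rvm / 1.05,
        "lv_edv": lv_edv,
        "lv_esv": lv_esv,
        "rv_edv": rv_edv,
        "rv_esv": rv_esv,
        "sv1": sv1,
        "rv5": rv5,
        "ravl": ravl,
        "sv3": sv3,
        "qrs_ms": qrs,
    })
    for j, name in enumerate(LEAD_NAMES):
        df[name] = leads[:, j]

    # modality-specific missingness (ECG / CMR exclusions)
    ecg_cols = ["sv1", "rv5", "ravl", "sv3", "qrs_ms"] + LEAD_NAMES
    cmr_cols = ["lv_tissue_vol", "rv_tissue_vol", "lv_edv", "lv_esv",
                "rv_edv", "rv_esv", "chest_lat", "chest_ap", "chest_height"]
    miss_ecg = rng.random(n) < model.ecg_missing_rate
    miss_cmr = rng.random(n) < model.cmr_missing_rate
    df.loc[miss_ecg, ecg_cols] = np.nan
    df.loc[miss_cmr, cmr_cols] = np.nan

    phen = np.array([ind.phenotyped for ind in ped.individuals])
    return df[phen].reset_index(drop=True)


def simulate_cohort(ped_spec: PedigreeSpec | None = None,
                    geno_spec: GenotypeSpec | None = None,
                    model: TraitModel | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """End-to-end cohort simulation: pedigree, genotypes, traits, truth."""
    ped_spec = ped_spec or PedigreeSpec()
    geno_spec = geno_spec or GenotypeSpec()
    model = model or TraitModel()
    seed = ped_spec.seed if seed is None else seed
    ped_spec.seed = seed
    ped = simulate_pedigrees(ped_spec)
    geno = drop_genotypes(ped, geno_spec, seed)
    genetic = {
        t: simulate_polygenic(ped, model.h2[t], "pedigree-mvn",
                              seed=seed * 7919 + i)
        for i, t in enumerate(sorted(model.h2))
    }
    pheno = simulate_traits(ped, model, genetic, seed=seed)
    truth: dict = {"seed": seed, "n_families": ped_spec.n_families,
                   "template_note": "family structures are template approximations"}
    for t, v in model.h2.items():
        truth[f"h2:{t}"] = v
    for t, v in model.residual_sd.items():
        truth[f"residual_sd:{t}"] = v
    for t, v in model.covariate_effects.items():
        truth[f"effect:{t}"] = v
    truth["chest_loading"] = model.chest_loading
    truth["treatment_prevalence"] = model.treatment_prevalence
    truth["ecg_missing_rate"] = model.ecg_missing_rate
    truth["cmr_missing_rate"] = model.cmr_missing_rate
    truth["voltage_scale"] = model.voltage_scale
    return SimulatedCohort(ped, geno, pheno, truth)


def write_cohort(cohort: SimulatedCohort, directory: str | Path) -> dict[str, Path]:
    """Write FAM, PED/MAP, phenotype table and truth manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "fam": d / "cohort.fam",
        "ped": d / "cohort.ped",
        "map": d / "cohort.map",
        "pheno": d / "phenotypes.tsv",
        "truth": d / "truth.txt",
    }
    write_fam(cohort.pedigree, paths["fam"])
    write_ped_map(cohort.genotypes, cohort.pedigree, d / "cohort")
    cohort.phenotypes.to_csv(paths["pheno"], sep="\t", index=False,
                             na_rep="NA", float_format="%.6f")
    with open(paths["truth"], "w") as fh:
        for k, v in cohort.truth.items():
            fh.write(f"{k}={v}\n")
    return paths
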