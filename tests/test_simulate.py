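import filecmp

import numpy as np
import pandas as pd
import pytest

from famh2.genotypes import read_ped_map
from famh2.pedigree import Individual, Pedigree, parse_pedigree
from famh2.phenotypes import derive_phenotypes
from famh2.simulate import (GenotypeSpec, PedigreeSpec, TraitModel,
                            drop_genotypes, simulate_cohort,
                            simulate_pedigrees, simulate_polygenic,
                            simulate_traits, write_cohort)


def founders_only(n: int, seed: int = 0) -> Pedigree:
    return Pedigree([Individual(f"F{i}", "1", sex=1 + i % 2) for i in range(n)])


class TestPedigreeGeneration:
    def test_default_panel_scale(self):
        ped = simulate_pedigrees(PedigreeSpec(seed=4))
        assert len(ped.family_ids) == 116
        n_phen = len(ped.phenotyped_ids())
        assert 406 <= n_phen <= 448

    def test_single_nuclear_family(self):
        spec = PedigreeSpec(n_families=1,
                            family_templates=[("nuclear-2child", 1.0)],
                            target_total_individuals=3, seed=0)
        ped = simulate_pedigrees(spec)
        assert len(ped) == 4
        assert len(ped.founders()) == 2

    def test_infeasible_target_raises(self):
        spec = PedigreeSpec(n_families=5,
                            family_templates=[("nuclear-2child", 1.0)],
                            target_total_individuals=400, seed=0)
        with pytest.raises(ValueError, match="cannot reach"):
            simulate_pedigrees(spec)

    def test_determinism_bytes(self, tmp_path):
        for sub in ("a", "b"):
            cohort = simulate_cohort(
                PedigreeSpec(n_families=12, target_total_individuals=45, seed=9),
                GenotypeSpec(n_snps=40), TraitModel(), seed=9)
            write_cohort(cohort, tmp_path / sub)
        for name in ("cohort.fam", "cohort.ped", "cohort.map",
                     "phenotypes.tsv", "truth.txt"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name


class TestGeneDropping:
    def test_mendelian_consistency_exhaustive(self):
        ped = simulate_pedigrees(PedigreeSpec(
            n_families=10, target_total_individuals=38, seed=2))
        g = drop_genotypes(ped, GenotypeSpec(n_snps=60), seed=2)
        pos = {k: i for i, k in enumerate(g.ids)}
        for ind in ped.individuals:
            fa, mo = ped.parents_of(ind.key)
            if fa is None or mo is None:
                continue
            child = g.dosage[pos[ind.key]]
            df, dm = g.dosage[pos[fa]], g.dosage[pos[mo]]
            # allele from each parent: child in [fa_low + mo_low, fa_high + mo_high]
            lo = (df == 2).astype(int) + (dm == 2).astype(int)
            hi = 2 - ((df == 0).astype(int) + (dm == 0).astype(int))
            assert np.all(child >= lo) and np.all(child <= hi)

    def test_homozygous_parents_force_child(self):
        ped = Pedigree([
            Individual("F1", "1", sex=1), Individual("F1", "2", sex=2),
            Individual("F1", "3", "1", "2", 1),
        ])
        for _ in range(5):
            g = drop_genotypes(ped, GenotypeSpec(n_snps=200), seed=_)
            d = {k: g.dosage[i] for i, k in enumerate(g.ids)}
            both0 = (d[("F1", "1")] == 0) & (d[("F1", "2")] == 0)
            assert np.all(d[("F1", "3")][both0] == 0)
            opposite = (d[("F1", "1")] == 2) & (d[("F1", "2")] == 0)
            assert np.all(d[("F1", "3")][opposite] == 1)

    def test_founder_allele_frequency(self):
        ped = founders_only(10000)
        g = drop_genotypes(ped, GenotypeSpec(
            n_snps=1, n_causal=1, allele_freqs=np.array([0.3])), seed=5)
        assert g.allele_frequencies()[0] == pytest.approx(0.3, abs=0.01)


class TestPolygenic:
    def test_h2_zero_gives_zeros(self, default_panel):
        g = simulate_polygenic(default_panel, 0.0, seed=1)
        assert np.all(g == 0)

    def test_h2_out_of_range(self, default_panel):
        with pytest.raises(ValueError):
            simulate_polygenic(default_panel, 1.2)

    def test_sib_covariance(self):
        spec = PedigreeSpec(n_families=5000,
                            family_templates=[("nuclear-2child", 1.0)],
                            target_total_individuals=15000, seed=3)
        ped = simulate_pedigrees(spec)
        g = simulate_polygenic(ped, 1.0, seed=3)
        pos = {k: i for i, k in enumerate(ped.ids)}
        sib_a, sib_b, po_p, po_c = [], [], [], []
        for fid in ped.family_ids:
            sib_a.append(g[pos[(fid, "3")]])
            sib_b.append(g[pos[(fid, "4")]])
            po_p.append(g[pos[(fid, "2")]])
            po_c.append(g[pos[(fid, "3")]])
        cov_sib = np.cov(sib_a, sib_b)[0, 1]
        assert cov_sib == pytest.approx(0.5, abs=0.05)
        r_po = np.corrcoef(po_p, po_c)[0, 1]
        assert r_po == pytest.approx(0.5, abs=0.05)
        # founder variance calibration: founders have variance sigma_g^2 = 1
        founder_vals = [g[pos[k.key]] for k in ped.founders()]
        assert np.var(founder_vals) == pytest.approx(1.0, rel=0.05)

    def test_genotype_causal_mode_requires_genotypes(self, default_panel):
        with pytest.raises(ValueError, match="requires genotypes"):
            simulate_polygenic(default_panel, 0.5, "genotype-causal")

    def test_genotype_causal_variance(self):
        ped = founders_only(4000)
        geno = drop_genotypes(ped, GenotypeSpec(n_snps=400), seed=8)
        g = simulate_polygenic(ped, 0.6, "genotype-causal", genotypes=geno,
                               seed=8, n_causal=50)
        assert np.var(g) == pytest.approx(0.6, rel=0.35)


class TestTraits:
    @pytest.fixture(scope="class")
    def big_cohort(self):
        spec = PedigreeSpec(n_families=1400, target_total_individuals=5200,
                            seed=6)
        return simulate_cohort(spec, GenotypeSpec(n_snps=30), TraitModel(),
                               seed=6)

    def test_confounding_target(self, big_cohort):
        d = derive_phenotypes(big_cohort.phenotypes,
                              voltage_scale=big_cohort.truth["voltage_scale"])
        sub = d[["chest_lat", "ecg_lvm"]].dropna()
        rho = sub.corr(method="spearman").iloc[0, 1]
        assert 0.60 <= rho <= 0.75

    def test_zero_loading_independence(self):
        spec = PedigreeSpec(n_families=1400, target_total_individuals=5200,
                            seed=6)
        cohort = simulate_cohort(spec, GenotypeSpec(n_snps=30),
                                 TraitModel(chest_loading=0.0), seed=6)
        d = derive_phenotypes(cohort.phenotypes, voltage_scale=100.0)
        sub = d[["chest_lat", "ecg_lvm"]].dropna()
        rho = sub.corr(method="spearman").iloc[0, 1]
        assert abs(rho) < 0.05

    def test_treatment_prevalence_zero(self, default_panel):
        model = TraitModel(treatment_prevalence=0.0)
        genetic = {t: simulate_polygenic(default_panel, model.h2[t], seed=i)
                   for i, t in enumerate(sorted(model.h2))}
        df = simulate_traits(default_panel, model, genetic, seed=1)
        assert (df["treated"] == 0).all()

    def test_missing_genetic_values_error(self, default_panel):
        with pytest.raises(ValueError, match="missing genetic"):
            simulate_traits(default_panel, TraitModel(), {}, seed=1)

    def test_phenotyped_rows_only(self, big_cohort):
        ped = big_cohort.pedigree
        keys = set(zip(big_cohort.phenotypes["FID"], big_cohort.phenotypes["IID"]))
        assert keys == set(ped.phenotyped_ids())


class TestRoundTrips:
    def test_fam_and_genotype_roundtrip(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        ped2 = parse_pedigree(paths["fam"])
        assert ped2.ids == small_cohort.pedigree.ids
        for a, b in zip(ped2.individuals, small_cohort.pedigree.individuals):
            assert (a.father, a.mother, a.sex, a.phenotyped) == \
                   (b.father, b.mother, b.sex, b.phenotyped)
        g2 = read_ped_map(tmp_path / "cohort")
        assert g2.ids == small_cohort.genotypes.ids
        np.testing.assert_array_equal(g2.dosage, small_cohort.genotypes.dosage)

    def test_truth_manifest_complete(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        text = paths["truth"].read_text()
        model = TraitModel()
        for t in model.h2:
            assert f"h2:{t}=" in text
        for key in ("chest_loading", "treatment_prevalence", "voltage_scale"):
            assert f"{key}=" in text

    def test_phenotype_table_roundtrip(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        df = pd.read_csv(paths["pheno"], sep="\t", na_values="NA",
                         dtype={"FID": str, "IID": str})
        assert len(df) == len(small_cohort.phenotypes)
        np.testing.assert_allclose(df["height_cm"],
                                   small_cohort.phenotypes["height_cm"],
                                   atol=1e-6)
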