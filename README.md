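# famh2

Family-based heritability of ECG- and CMR-derived ventricular
phenotypes: a tested, reusable implementation of the full analysis
pipeline — phenotype derivation, covariate adjustment, pedigree and SNP
relationship kernels, and variance-components heritability estimation —
exercised on a synthetic family cohort generator with known ground
truth.

## The problem

Left-ventricular hypertrophy is a strong risk factor for heart failure
and cardiovascular death, and its measures are heritable — but *how*
heritable depends strikingly on the measurement modality. ECG-derived
left-ventricular mass (LVM) combines true myocardial signal with body
habitus: surface voltages depend on the tissue path between heart and
electrodes, so chest dimensions (themselves highly heritable) confound
the estimate. Quantifying this requires a pipeline that can (a) derive
the standard ECG hypertrophy indices and CMR mass/volume indices from
raw measurements, (b) adjust phenotypes for covariates exactly as a
family study would, and (c) estimate narrow-sense heritability two
independent ways:

* **h² (pedigree)** — maximum-likelihood variance components with the
  expected relationship kernel 2Φ from the pedigree, likelihood-ratio
  tested against an individual-specific-effects-only null, with the
  Wald-approximation SE = h²/√LRT;
* **h² (SNP, IBS > 0.05)** — GREML-style REML against a genetic
  relationship matrix whose off-diagonal entries below 0.05 are zeroed,
  so the signal is carried by close-relative sharing.

Both fit the model *y* ~ N(μ1, σ²g·K + σ²e·I), h² = σ²g/(σ²g+σ²e), via a
single eigendecomposition of K reused across fits.

Because the emulated study's raw data are not publicly deposited, the
package includes a first-class synthetic-data module: template-based
extended pedigrees (~116 families, ~427 phenotyped members),
gene-dropped genotypes, and traits with specified heritabilities —
including the confounding structure in which ECG LVM correlates with
chest lateral diameter (Spearman ρ ≈ 0.67) so that adjusting for chest
size attenuates the ECG-LVM heritability estimate.

Intended users: quantitative geneticists and methodologists who want a
transparent, scriptable re-implementation of this family-study design
for power analysis, teaching, or sensitivity analysis of the
modality-dependence mechanism.

## Worked example

Run the full pipeline on a simulated default-scale cohort (116
families, 2,000 SNPs), estimating four traits with two adjustment
recipes for ECG LVM:

```python
from famh2.pipeline import RunConfig, TraitRecipe, run_pipeline

CHEST = ["age", "sex01", "height_cm", "weight_kg", "bsa", "bmi",
         "sbp_adj", "dbp_adj", "chest_lat"]
cfg = RunConfig(
    traits=[TraitRecipe(name="cmr_lvm"),
            TraitRecipe(name="rv_mass"),
            TraitRecipe(name="ecg_lvm", label="ecg_lvm_unadj"),
            TraitRecipe(name="ecg_lvm", label="ecg_lvm_chestadj",
                        candidates=CHEST)],
    seed=11, out_dir="famh2_run", n_families=116, n_snps=2000)
print(run_pipeline(cfg).rows.to_string(index=False))
```

which prints (seed 11):

```
           trait  n_phenotyped  h2_pedigree  se_pedigree  p_pedigree  n_genotyped  h2_grm  se_grm  p_grm     selected_covariates
         cmr_lvm           422        0.201        0.094       0.016          420   0.234   0.104  0.007       sex01,bsa,sbp_adj
         rv_mass           422        0.528        0.097       0.000          420   0.497   0.105  0.000         sex01,weight_kg
   ecg_lvm_unadj           416        0.436        0.094       0.000          415   0.426   0.105  0.000               bsa,sex01
ecg_lvm_chestadj           399        0.241        0.091       0.004          398   0.233   0.104  0.006 bsa,chest_lat,sex01,bmi
```

Reading the table: CMR LVM recovers its true simulated heritability
(0.20) with a ~9-point SE; RV mass (true 0.44) is estimated at 0.53 ±
0.10; and the ECG-LVM estimate drops from 0.44 to 0.24 once chest
lateral diameter joins the covariate set — the confounding-attenuation
mechanism, since the chest-size pathway into the ECG voltages is itself
heritable. Pedigree-ML and thresholded-GRM REML estimates track each
other throughout.

The same stages are scriptable from the shell:

```bash
famh2 simulate --families 116 --individuals 427 --snps 2000 --seed 11 --out cohort/
famh2 h2 --kernel pedigree --fam cohort/cohort.fam \
         --pheno cohort/phenotypes.tsv --trait height_cm
famh2 power --h2 0.35 --reps 200 --seed 1
famh2 compare --r1 0.47 --n1 195 --r2 0.46 --n2 210 \
              --h2a 0.57 --sea 0.09 --h2b 0.62 --seb 0.09
# {"fisher_z": {"z": 0.127, "p": 0.899}, "heterogeneity": {"z": -0.393, "p": 0.694, ...}}
```

`famh2 run --config cfg.yaml` drives the full pipeline from a YAML file;
`famh2 qc`, `famh2 grm`, `famh2 adjust` and `famh2 derive` expose the
individual stages on PLINK-text/TSV files.

See `docs/methods.md` for the model details, the generator's design and
its calibration, and known limitations.

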