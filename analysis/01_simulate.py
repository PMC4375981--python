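"""Simulate the common-garden study: phenotypes, SNP panel, predictors.

Generates one synthetic realization of the study design — 4 randomized
complete blocks, 20 populations, 124 genotypes, 12 traits with known
variance components — plus a 5000-SNP Balding–Nichols panel at F = 0.05
and a climate/geography predictor table, and writes them under
results/analysis/.  Downstream scripts (03-07) start from these files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gardenqg import synth, traits

SEED = 20151
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)

design = synth.DesignSpec()
# trait ground truth spans the study's range: high differentiation for
# phenology/injury, moderate for growth, low for branching ratios
VARIANCES = {
    "H": (0.15, 0.10, 0.75), "D": (0.14, 0.08, 0.78), "VI": (0.15, 0.05, 0.80),
    "CD": (0.09, 0.10, 0.81), "NB": (0.06, 0.14, 0.80), "NSyll_log": (0.05, 0.13, 0.82),
    "RNB": (0.01, 0.11, 0.88), "RCD": (0.025, 0.09, 0.885),
    "d13C": (0.11, 0.10, 0.79), "BF": (0.07, 0.14, 0.79),
    "BS": (0.30, 0.09, 0.61), "I20": (0.21, 0.12, 0.67),
}
specs = [
    synth.TraitGenSpec(name=t, mu=0.0, sigma2_P=sp, sigma2_G=sg, sigma2_E=se,
                       block_effects=(0.0, 0.4, -0.2, 0.1))
    for t, (sp, sg, se) in VARIANCES.items()
]

# one-factor correlation structure shared by all three levels: growth and
# branch traits load strongly on a common "vigor" factor (genetically and
# through within-tree allometry of the residuals), bud flush negatively,
# bud set and cold injury weakly, with an extra direct bud-set/cold-injury
# correlation; carbon isotope ratio is uncorrelated
import numpy as np

lam = np.array([0.95, 0.95, 0.90, 0.90, 0.80, 0.75, 0.70, 0.70,
                0.00, -0.35, 0.40, 0.25])
corr = np.outer(lam, lam)
np.fill_diagonal(corr, 1.0)
i_bs, i_i20 = 10, 11
corr[i_bs, i_i20] = corr[i_i20, i_bs] = lam[i_bs] * lam[i_i20] + 0.43

pheno = synth.generate_phenotypes(
    design, specs, seed=SEED,
    genetic_corr=corr, population_corr=corr, residual_corr=corr,
)
pheno.to_csv(OUT / "phenotypes.csv", index=False)
print(f"phenotypes: {len(pheno)} ramets x {len(specs)} traits -> phenotypes.csv")

panel = synth.SNPGenSpec(n_snps=5000, fst_target=0.05, diploids_per_population=25)
matrix = synth.generate_snps(panel, design, seed=SEED + 1)
matrix.to_dosage_csv(OUT / "dosages.csv")
matrix.to_vcf(OUT / "snps.vcf")
print(f"SNP panel: {matrix.n_individuals} diploids x {matrix.n_snps} SNPs "
      "-> dosages.csv, snps.vcf")

predictors = synth.generate_predictors(design, n_climate_vars=22, seed=SEED + 2)
predictors.to_csv(OUT / "predictors.csv")
print(f"predictors: {predictors.shape[1]} columns for "
      f"{len(predictors)} populations -> predictors.csv")
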