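"""Q_ST, heritabilities with bootstrap CIs, and BLUP trait correlations.

Produces the study's two headline quantitative-genetic tables: per-trait
Q_ST / H2_G(P) / H2_G with 95% parametric-bootstrap intervals (1000
iterations), and the trait-by-trait matrix with genetic correlations
below the diagonal and Searle environmental correlations above.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gardenqg import quantgen, traits, varcomp

SEED = 20154
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
pheno = pd.read_csv(OUT / "phenotypes.csv")

fits = varcomp.fit_all_traits(pheno, traits.TRAIT_NAMES)
records, blups, h2 = [], {}, {}
for i, (t, fitted) in enumerate(fits.results.items()):
    rec = quantgen.bootstrap_ci(pheno, t, n_boot=1000, seed=SEED + i, fitted=fitted)
    records.append(rec)
    blups[t] = fitted[1]
    h2[t] = rec.h2_across

table = quantgen.records_to_frame(records)
table.to_csv(OUT / "qst_heritability.csv", index=False)
print(table.round(3).to_string(index=False))

triplets = quantgen.correlations(blups, pheno, h2)
matrix = quantgen.correlation_matrix_frame(triplets, list(blups))
matrix.to_csv(OUT / "correlations.csv")
strong = [t for t in triplets if abs(t.r) > 0.5]
print(f"\n{len(strong)} trait pairs with |genetic r| > 0.5")
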