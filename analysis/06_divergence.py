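"""Classify traits by Q_ST against the empirical F_ST 99th percentile.

Joins the quantitative-genetic table (04) with the neutral null (05):
traits whose Q_ST point estimate exceeds the 99th percentile of per-SNP
F_ST are candidates for divergent selection.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gardenqg import popgen, quantgen

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
qdf = pd.read_csv(OUT / "qst_heritability.csv")
fst = pd.read_csv(OUT / "per_snp_fst.csv")["fst"].to_numpy()

dist = popgen.FstDistribution(
    per_snp_fst=fst, n_used=len(fst),
    percentile_99=float(np.percentile(fst, 99.0)),
)
records = [
    quantgen.QstH2Record(
        trait=row["trait"], qst=row["QST"],
        h2_within=row["H2_GP"], h2_across=row["H2_G"],
    )
    for _, row in qdf.iterrows()
]
report = popgen.classify_traits(records, dist)
report.table.to_csv(OUT / "divergence.csv", index=False)

print(report.table.round(3).to_string(index=False))
print(f"\ntraits exceeding the 99th percentile ({dist.percentile_99:.3f}): "
      f"{', '.join(report.exceeding()) or 'none'}")
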