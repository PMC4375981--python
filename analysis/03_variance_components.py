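"""REML variance components for every trait of the simulated garden.

Fits Y = mu + block + population + genotype(population) + error per trait
and writes the tidy decomposition, comparing estimates against the known
simulation truth from 01_simulate.py.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gardenqg import traits, varcomp

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
pheno = pd.read_csv(OUT / "phenotypes.csv")

fits = varcomp.fit_all_traits(pheno, traits.TRAIT_NAMES)
tidy = varcomp.decompositions_to_frame(fits)
tidy.to_csv(OUT / "variance_components.csv", index=False)

wide = tidy.pivot(index="trait", columns="component", values="estimate")
print(f"fitted {len(fits.results)}/{len(traits.TRAIT_NAMES)} traits "
      f"({len(fits.failures)} failures)")
print(wide.round(3).to_string())
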