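"""Synthetic common-garden data with known ground truth.

Emulates the study design of a range-wide clonal common garden: a
randomized complete block design (4 blocks by default) with genotypes
nested in populations (20 populations, 124 genotypes by default, one ramet
per genotype per block).  Phenotypes follow the same Gaussian mixed model
the analysis fits (fixed block constants, Normal population and
genotype-within-population effects), so recovery tests are unbiased;
non-additive and maternal confounding present in real clonal data is
deliberately not simulated.  SNP panels follow the Balding–Nichols model
(Beta-distributed population allele frequencies around a uniform ancestral
frequency, parameterized by the target F_ST), and climate/geography
predictor tables are built with a configurable correlation to latitude
plus optional step-structured variables for regression-tree recovery
tests.

All draws descend from a single seed through spawned child streams (one
per trait / data product), so outputs are reproducible and insensitive to
the order in which products are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from gardenqg.exceptions import SpecValidationError
from gardenqg.popgen import GenotypeMatrix


def _default_genotype_counts() -> tuple[int, ...]:
    # 124 genotypes over 20 populations: four populations of 7, sixteen of 6
    return (7,) * 4 + (6,) * 16


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the common garden.

    Defaults reproduce the study design: 4 blocks, 20 populations,
    124 genotypes (6–7 per population), one ramet per genotype per block.
    """

    n_blocks: int = 4
    n_populations: int = 20
    genotypes_per_population: tuple[int, ...] = field(
        default_factory=_default_genotype_counts
    )
    ramets_per_genotype_block: int = 1
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_blocks < 1 or self.n_populations < 1:
            raise SpecValidationError("block and population counts must be >= 1")
        counts = tuple(self.genotypes_per_population)
        if len(counts) != self.n_populations:
            raise SpecValidationError(
                "genotypes_per_population length must equal n_populations"
            )
        if any(c < 1 for c in counts):
            raise SpecValidationError("every population needs >= 1 genotype")
        if self.ramets_per_genotype_block < 1:
            raise SpecValidationError("ramets_per_genotype_block must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecValidationError("missing_rate must be in [0, 1)")
        object.__setattr__(self, "genotypes_per_population", counts)

    @property
    def n_genotypes(self) -> int:
        return int(sum(self.genotypes_per_population))

    @property
    def n_rows(self) -> int:
        return self.n_genotypes * self.n_blocks * self.ramets_per_genotype_block

    def frame(self) -> pd.DataFrame:
        """Design skeleton: one row per ramet with block/population/genotype."""
        pops, genos = [], []
        g = 0
        for j, cnt in enumerate(self.genotypes_per_population):
            for _ in range(cnt):
                pops.append(f"pop{j + 1:02d}")
                genos.append(f"g{g + 1:03d}")
                g += 1
        base = pd.DataFrame({"population": pops, "genotype": genos})
        rows = []
        for b in range(self.n_blocks):
            for _ in range(self.ramets_per_genotype_block):
                block = base.copy()
                block.insert(0, "block", f"B{b + 1}")
                rows.append(block)
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class TraitGenSpec:
    """Ground-truth generative parameters for one trait.

    ``block_effects`` are fixed constants (length n_blocks, first entry
    conventionally 0 as the reference block).  ``climate_link`` optionally
    maps a per-population predictor column to additive population-mean
    shifts: a ``(predictor_name, fn)`` pair where ``fn`` takes the
    per-population predictor values and returns per-population offsets.
    """

    name: str
    mu: float = 0.0
    sigma2_P: float = 0.2
    sigma2_G: float = 0.1
    sigma2_E: float = 0.7
    block_effects: tuple[float, ...] | None = None
    climate_link: tuple[str, Callable[[np.ndarray], np.ndarray]] | None = None

    def __post_init__(self):
        if self.sigma2_P < 0 or self.sigma2_G < 0:
            raise SpecValidationError("variances must be non-negative")
        if self.sigma2_E <= 0:
            raise SpecValidationError("residual variance must be positive")


def _check_correlation(corr: np.ndarray, k: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise SpecValidationError(f"genetic_corr must be {k}x{k}")
    if not np.allclose(corr, corr.T):
        raise SpecValidationError("genetic_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise SpecValidationError("genetic_corr must have unit diagonal")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise SpecValidationError(
            f"genetic_corr is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )
    return corr


def generate_phenotypes(
    design: DesignSpec,
    traits: Sequence[TraitGenSpec],
    seed: int,
    *,
    genetic_corr: np.ndarray | None = None,
    population_corr: np.ndarray | None = None,
    residual_corr: np.ndarray | None = None,
    predictors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ramet-level phenotype table drawn from the nested Gaussian model.

    Each trait value is mu + block constant + population effect
    N(0, sigma2_P) + genotype effect N(0, sigma2_G) + residual
    N(0, sigma2_E).  With ``genetic_corr`` the genotype effects of the
    traits are drawn jointly with that correlation (variances still per
    trait); ``population_corr`` does the same for the population effects
    and ``residual_corr`` for the residuals, so strongly co-varying trait
    blocks (e.g. growth and branching, which share genetic control and
    within-tree allometry) can be emulated at every level.
    ``predictors`` (indexed by
    population) is consulted by traits with a ``climate_link``.  Missing
    cells are blanked completely at random at ``design.missing_rate``,
    independently per trait.
    """
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise SpecValidationError("duplicate trait names")
    n_traits = len(traits)
    if genetic_corr is not None:
        genetic_corr = _check_correlation(genetic_corr, n_traits)
    if population_corr is not None:
        population_corr = _check_correlation(population_corr, n_traits)
    if residual_corr is not None:
        residual_corr = _check_correlation(residual_corr, n_traits)

    df = design.frame()
    pops = df["population"].unique()
    genos = df["genotype"].unique()
    p_idx = df["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    g_idx = df["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    b_idx = df["block"].map(
        {b: i for i, b in enumerate(sorted(df["block"].unique()))}
    ).to_numpy()

    root = np.random.SeedSequence(seed)
    geno_stream = np.random.default_rng(root.spawn(1)[0])
    trait_streams = [np.random.default_rng(s) for s in root.spawn(n_traits + 1)[1:]]

    def joint_draws(stream, n_units, sds, corr):
        cov = np.outer(sds, sds) * corr
        # eigendecomposition handles PSD-but-singular correlation targets
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return stream.standard_normal((n_units, n_traits)) @ (v * np.sqrt(w)).T

    # joint genotype effects across traits (shared stream so the marginal
    # per-trait draws are unaffected by the presence of other traits only
    # when uncorrelated generation is not requested)
    sds = np.array([np.sqrt(t.sigma2_G) for t in traits])
    if genetic_corr is not None:
        geno_eff = joint_draws(geno_stream, len(genos), sds, genetic_corr)
    else:
        geno_eff = geno_stream.standard_normal((len(genos), n_traits)) * sds

    pop_eff_joint = None
    if population_corr is not None:
        pop_sds = np.array([np.sqrt(t.sigma2_P) for t in traits])
        pop_stream = np.random.default_rng(root.spawn(1)[0])
        pop_eff_joint = joint_draws(pop_stream, len(pops), pop_sds, population_corr)
    eps_joint = None
    if residual_corr is not None:
        eps_sds = np.array([np.sqrt(t.sigma2_E) for t in traits])
        eps_stream = np.random.default_rng(root.spawn(1)[0])
        eps_joint = joint_draws(eps_stream, len(df), eps_sds, residual_corr)

    for t_i, (spec, rng) in enumerate(zip(traits, trait_streams)):
        blocks = np.zeros(design.n_blocks)
        if spec.block_effects is not None:
            if len(spec.block_effects) != design.n_blocks:
                raise SpecValidationError(
                    f"trait {spec.name!r}: block_effects length != n_blocks"
                )
            blocks = np.asarray(spec.block_effects, dtype=float)
        pop_mu = np.full(len(pops), spec.mu)
        if spec.climate_link is not None:
            col, fn = spec.climate_link
            if predictors is None:
                raise SpecValidationError(
                    f"trait {spec.name!r} has a climate_link but no predictors given"
                )
            pop_mu = pop_mu + np.asarray(
                fn(predictors.loc[pops, col].to_numpy()), dtype=float
            )
        if pop_eff_joint is not None:
            pop_eff = pop_eff_joint[:, t_i]
        else:
            pop_eff = rng.normal(0.0, np.sqrt(spec.sigma2_P), size=len(pops))
        if eps_joint is not None:
            eps = eps_joint[:, t_i]
        else:
            eps = rng.normal(0.0, np.sqrt(spec.sigma2_E), size=len(df))
        vals = pop_mu[p_idx] + pop_eff[p_idx] + geno_eff[g_idx, t_i] + blocks[b_idx] + eps
        if design.missing_rate > 0:
            vals = np.where(rng.random(len(df)) < design.missing_rate, np.nan, vals)
        df[spec.name] = vals
    return df


@dataclass(frozen=True)
class SNPGenSpec:
    """Balding–Nichols SNP panel parameters."""

    n_snps: int = 5000
    fst_target: float = 0.05
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    diploids_per_population: int = 25

    def __post_init__(self):
        if not 0.0 < self.fst_target < 1.0:
            raise SpecValidationError("fst_target must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise SpecValidationError("ancestral_freq_range must be ordered within (0,1)")
        if self.n_snps < 1 or self.diploids_per_population < 1:
            raise SpecValidationError("counts must be >= 1")


def generate_snps(spec: SNPGenSpec, design: DesignSpec, seed: int) -> GenotypeMatrix:
    """Balding–Nichols SNP dosages for ``design.n_populations`` populations.

    Per SNP: ancestral frequency p ~ Uniform(ancestral_freq_range);
    population frequencies ~ Beta(p (1-F)/F, (1-p)(1-F)/F) with
    F = fst_target; dosages ~ Binomial(2, population frequency).
    Monomorphic SNPs are kept in the matrix (downstream estimators flag
    them) so panel size is exactly ``n_snps``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_pop = design.n_populations
    f = spec.fst_target
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=spec.n_snps)
    shape = (1.0 - f) / f
    pop_freq = rng.beta(
        np.broadcast_to(p_anc * shape, (n_pop, spec.n_snps)),
        np.broadcast_to((1.0 - p_anc) * shape, (n_pop, spec.n_snps)),
    )
    n_ind = spec.diploids_per_population
    dosages = rng.binomial(
        2, np.repeat(pop_freq, n_ind, axis=0)
    ).astype(np.int16)
    populations = np.repeat([f"pop{j + 1:02d}" for j in range(n_pop)], n_ind)
    snp_ids = np.array([f"snp{j + 1}" for j in range(spec.n_snps)], dtype=object)
    return GenotypeMatrix(dosages=dosages, populations=populations, snp_ids=snp_ids)


def generate_predictors(
    design: DesignSpec,
    n_climate_vars: int = 22,
    seed: int = 0,
    *,
    latitude_range: tuple[float, float] = (37.0, 58.0),
    latitude_correlation: float | Sequence[float] = 0.7,
    step_specs: dict[str, tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-population geography plus synthetic climate variables.

    Latitude is drawn uniformly over ``latitude_range`` (sorted so
    population index tracks a south-to-north gradient), longitude and
    altitude with weaker structure.  Each climate column is built as
    ``rho * z(latitude) + sqrt(1 - rho^2) * noise`` on a standardized
    scale, with ``rho`` the requested latitude correlation (scalar or one
    value per variable) — mimicking real climate tables where
    evapotranspiration-like variables track latitude strongly.

    ``step_specs`` adds deterministic step-structured columns for
    partition-recovery tests: ``name -> (by, breakpoint, jump)`` creates
    ``low + jump * (base > breakpoint)`` plus small within-group spread,
    where ``by`` is an existing column (e.g. "latitude").
    """
    if n_climate_vars < 1:
        raise SpecValidationError("n_climate_vars must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_pop = design.n_populations
    lat = np.sort(rng.uniform(*latitude_range, size=n_pop))
    lon = -(121.0 + 0.3 * (lat - lat.mean()) + rng.normal(0, 2.0, n_pop))
    alt = np.clip(rng.gamma(2.0, 150.0, n_pop) + 20.0 * (lat.max() - lat), 0, None)
    df = pd.DataFrame(
        {"latitude": lat, "longitude": lon, "altitude": alt},
        index=pd.Index([f"pop{j + 1:02d}" for j in range(n_pop)], name="population"),
    )
    rho = np.broadcast_to(
        np.asarray(latitude_correlation, dtype=float), (n_climate_vars,)
    )
    if np.any(np.abs(rho) > 1):
        raise SpecValidationError("latitude_correlation must be within [-1, 1]")
    z_lat = (lat - lat.mean()) / lat.std()
    for k in range(n_climate_vars):
        noise = rng.standard_normal(n_pop)
        noise = (noise - noise.mean()) / noise.std()
        df[f"clim{k + 1:02d}"] = rho[k] * z_lat + np.sqrt(1 - rho[k] ** 2) * noise
    if step_specs:
        for name, (by, breakpoint, jump) in step_specs.items():
            base = df[by].to_numpy()
            jitter = rng.normal(0.0, abs(jump) * 0.02, n_pop)
            df[name] = jump * (base > breakpoint).astype(float) + jitter
    return df


def planted_mrt_scenario(
    seed: int,
    *,
    design: DesignSpec | None = None,
    sigma2_G: float = 0.1,
    sigma2_E: float = 0.7,
):
    """Five-group climate-step scenario for regression-tree recovery tests.

    Twenty populations fall into five groups of four.  An
    evapotranspiration-like variable ("eref") steps between groups {1,2}
    (high, ~800) and {3,4,5} (low, ~650); a frost-free-period-like
    variable ("ffp") separates the remaining groups.  Three unstructured
    climate columns are included as distractors.  Population trait means
    follow the group structure with an among-population variance of ~0.2
    against sigma2_G + sigma2_E noise (the signal-to-noise ratio of the
    fitted study traits), carried by three traits whose dominant contrast
    aligns with the eref step — so a correct tree splits on eref first.

    Returns (phenotypes, predictors, groups): a ramet-level phenotype
    table with traits t1..t3, a per-population predictor table with
    columns [eref, ffp, clim1..clim3], and the population -> group map.
    """
    design = design or DesignSpec()
    if design.n_populations != 20:
        raise SpecValidationError("the planted scenario is defined for 20 populations")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]).spawn(1)[0])
    pops = [f"pop{j + 1:02d}" for j in range(20)]
    groups = np.repeat(np.arange(5), 4)
    eref = np.where(groups < 2, 800.0, 650.0) + rng.normal(0, 15.0, 20)
    ffp_means = np.array([170.0, 235.0, 240.0, 210.0, 180.0])[groups]
    ffp = ffp_means + rng.normal(0, 8.0, 20)
    predictors = pd.DataFrame(
        {"eref": eref, "ffp": ffp},
        index=pd.Index(pops, name="population"),
    )
    for k in range(3):
        predictors[f"clim{k + 1}"] = rng.standard_normal(20)

    # group trait means: as in real multi-trait clines, every trait's
    # dominant contrast follows the primary (eref) step, with the smaller
    # within-pair differences left for the ffp splits further down
    group_means = {
        "t1": np.array([0.55, 0.55, -0.37, -0.37, -0.37]),
        "t2": np.array([0.62, 0.32, -0.30, -0.45, -0.25]),
        "t3": np.array([-0.45, -0.60, 0.30, 0.42, 0.33]),
    }
    link_df = predictors.copy()
    link_df["grp"] = groups
    specs = [
        TraitGenSpec(
            name=t, mu=0.0, sigma2_P=0.0, sigma2_G=sigma2_G, sigma2_E=sigma2_E,
            climate_link=("grp", lambda g, m=m: m[g.astype(int)]),
        )
        for t, m in group_means.items()
    ]
    pheno = generate_phenotypes(design, specs, seed=seed, predictors=link_df)
    return pheno, predictors, pd.Series(groups, index=pops, name="group")


def generate_raw_measurements(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Plausible ramet-level raw field measurements for pipeline demos.

    Generates raw columns (heights, diameters, crown/insertion heights,
    branch counts, conductivities, isotope ratios, bud dates) with nested
    population/genotype/residual structure on each underlying latent
    scale, so the trait-derivation stage can be exercised end-to-end.
    The derived traits then have realistic but not analytically prescribed
    variance components; use :func:`generate_phenotypes` when exact ground
    truth is needed.
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    df = design.frame()
    n = len(df)
    pops = df["population"].unique()
    genos = df["genotype"].unique()
    p_idx = df["population"].map({p: i for i, p in enumerate(pops)}).to_numpy()
    g_idx = df["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()

    def nested(mu, sd_p, sd_g, sd_e, lo=None):
        v = (
            mu
            + rng.normal(0, sd_p, len(pops))[p_idx]
            + rng.normal(0, sd_g, len(genos))[g_idx]
            + rng.normal(0, sd_e, n)
        )
        return np.clip(v, lo, None) if lo is not None else v

    df["H"] = nested(300.0, 40.0, 25.0, 35.0, lo=50.0)            # cm
    df["D"] = nested(25.0, 4.0, 2.5, 3.0, lo=5.0)                 # mm
    cd = nested(120.0, 15.0, 10.0, 12.0, lo=20.0)
    df["CD_ns"] = cd + rng.normal(0, 5.0, n)
    df["CD_ew"] = cd + rng.normal(0, 5.0, n)
    i_low = np.clip(nested(30.0, 5.0, 4.0, 6.0), 1.0, None)
    span = np.clip(nested(0.6, 0.08, 0.05, 0.07), 0.05, 0.95)
    df["I_low"] = i_low
    df["I_high"] = np.maximum(np.minimum(i_low + span * df["H"], df["H"]), i_low)
    df["NB"] = rng.poisson(np.clip(nested(28.0, 5.0, 3.0, 0.5), 1.0, None))
    df["NSyll"] = rng.poisson(np.clip(nested(6.0, 2.0, 1.2, 0.3), 0.0, None))
    # isotope ratios around the PDB standard, giving d13C near -27 per mil
    r_sd = 0.0112372
    df["R_sd"] = r_sd
    df["R_sa"] = r_sd * (1.0 + nested(-27.0, 1.0, 0.7, 1.2) / 1000.0)
    # conductivities: controls leak ~10%, frozen samples 30-80%
    r0 = np.clip(nested(0.10, 0.01, 0.008, 0.015), 0.01, 0.5)
    rt = np.clip(r0 + nested(0.45, 0.08, 0.05, 0.07), 0.02, 0.98)
    df["L_k"] = nested(1000.0, 30.0, 20.0, 40.0, lo=500.0)
    df["L_t"] = rt * df["L_k"]
    df["L_d"] = nested(1000.0, 30.0, 20.0, 40.0, lo=500.0)
    df["L_0"] = r0 * df["L_d"]
    df["BF_date"] = np.round(nested(105.0, 6.0, 4.0, 3.0)).astype(int)
    df["BS_date"] = np.round(nested(255.0, 10.0, 6.0, 4.0)).astype(int)
    if design.missing_rate > 0:
        mask = rng.random(n) < design.missing_rate
        df.loc[mask, "H"] = np.nan
    return df
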