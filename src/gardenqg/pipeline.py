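"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order:

    phenotypes (load raw + derive, load derived, or simulate)
      -> variance components (REML per trait)
      -> Q_ST / heritabilities / bootstrap CIs and BLUP correlations
    genotypes (VCF / dosage CSV / simulated)
      -> empirical F_ST distribution
    quantgen + F_ST -> divergence classification
    phenotypes + predictors -> PCA + multivariate regression tree

A stage failure (e.g. no genotype input) skips only its downstream
dependents.  Every output directory carries a manifest recording the
seed, a hash of the configuration, and per-stage status and counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gardenqg import mrt, popgen, quantgen, synth, traits, varcomp
from gardenqg.exceptions import SpecValidationError

_log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run description (YAML-loadable).

    Exactly one of the real phenotype inputs (``phenotypes_csv`` /
    ``raw_phenotypes_csv``) or ``simulate=True`` must be set.
    """

    seed: int = 0
    output_dir: str = "results/run"
    # real inputs
    phenotypes_csv: str | None = None       # derived traits, ramet-level
    raw_phenotypes_csv: str | None = None   # raw measurements, to be derived
    vcf: str | None = None
    dosages_csv: str | None = None
    predictors_csv: str | None = None
    sample_populations_csv: str | None = None  # sample -> population, for VCF
    # synthetic inputs
    simulate: bool = False
    design: dict = field(default_factory=dict)
    trait_specs: list[dict] = field(default_factory=list)
    snp_spec: dict = field(default_factory=dict)
    n_climate_vars: int = 22
    # analysis settings
    traits: list[str] | None = None
    blup_scope: str = "total"
    fst_estimator: str = "wc"
    fst_percentile: float = 99.0
    n_boot: int = 1000
    ci_level: float = 0.95
    mrt_max_leaves: int = 5
    mrt_min_node_size: int = 5
    mrt_standardize: bool = True
    mrt_responses: list[str] | None = None

    def __post_init__(self):
        has_real = self.phenotypes_csv is not None or self.raw_phenotypes_csv is not None
        if has_real == self.simulate:
            raise SpecValidationError(
                "exactly one of {real phenotype input, simulate} must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise SpecValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_trait_specs() -> list[synth.TraitGenSpec]:
    return [
        synth.TraitGenSpec(name=t, mu=0.0, sigma2_P=0.2, sigma2_G=0.1, sigma2_E=0.7)
        for t in traits.TRAIT_NAMES
    ]


def _load_phenotypes(cfg: RunConfig, rng_seed: int):
    if cfg.simulate:
        design = synth.DesignSpec(**cfg.design)
        specs = (
            [synth.TraitGenSpec(**d) for d in cfg.trait_specs]
            if cfg.trait_specs
            else _default_trait_specs()
        )
        return synth.generate_phenotypes(design, specs, seed=rng_seed), design
    if cfg.raw_phenotypes_csv is not None:
        raw = pd.read_csv(cfg.raw_phenotypes_csv)
        return traits.derive_traits(raw), None
    return pd.read_csv(cfg.phenotypes_csv), None


def _load_genotypes(cfg: RunConfig, design, rng_seed: int):
    if cfg.simulate:
        spec = synth.SNPGenSpec(**cfg.snp_spec)
        return synth.generate_snps(spec, design, seed=rng_seed)
    if cfg.dosages_csv is not None:
        return popgen.GenotypeMatrix.from_dosage_csv(cfg.dosages_csv)
    if cfg.vcf is not None:
        if cfg.sample_populations_csv is None:
            raise SpecValidationError("VCF input needs sample_populations_csv")
        pops = pd.read_csv(cfg.sample_populations_csv, index_col=0).iloc[:, 0].to_dict()
        return popgen.GenotypeMatrix.from_vcf(cfg.vcf, pops)
    raise FileNotFoundError("no genotype input configured")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    pheno_seed, snp_seed, pred_seed, boot_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(4)
    ]
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def record(stage, status, **info):
        manifest["stages"][stage] = {"status": status, **info}

    # --- phenotypes ---------------------------------------------------------
    pheno, design = _load_phenotypes(config, pheno_seed)
    trait_list = config.traits or [
        c for c in pheno.columns if c not in traits.DESIGN_COLUMNS
    ]
    pheno.to_csv(out / "phenotypes.csv", index=False)
    record("phenotypes", "ok", n_rows=len(pheno), n_traits=len(trait_list))

    # --- variance components ------------------------------------------------
    fits = varcomp.fit_all_traits(pheno, trait_list, blup_scope=config.blup_scope)
    varcomp.decompositions_to_frame(fits).to_csv(out / "variance_components.csv", index=False)
    record(
        "varcomp", "ok" if fits.results else "failed",
        n_fitted=len(fits.results), failures=fits.failures,
    )

    # --- quantgen ------------------------------------------------------------
    records, blups, h2 = [], {}, {}
    if fits.results:
        for i, (t, fitted) in enumerate(fits.results.items()):
            rec = quantgen.bootstrap_ci(
                pheno, t,
                n_boot=config.n_boot, level=config.ci_level,
                seed=boot_seed + i, fitted=fitted,
            )
            records.append(rec)
            blups[t] = fitted[1]
            h2[t] = rec.h2_across
        quantgen.records_to_frame(records).to_csv(out / "qst_heritability.csv", index=False)
        trips = quantgen.correlations(blups, pheno, h2)
        quantgen.correlation_matrix_frame(trips, list(blups)).to_csv(
            out / "correlations.csv"
        )
        n_failed = sum(r.n_boot_failed for r in records)
        record("quantgen", "ok", n_traits=len(records), bootstrap_failures=n_failed)
    else:
        record("quantgen", "skipped", reason="no variance-component fits")

    # --- F_ST ----------------------------------------------------------------
    dist = None
    try:
        matrix = _load_genotypes(config, design, snp_seed)
        dist = popgen.empirical_distribution(
            matrix, estimator=config.fst_estimator, percentile=config.fst_percentile
        )
        pd.DataFrame(
            {"fst": dist.per_snp_fst}
        ).to_csv(out / "per_snp_fst.csv", index=False)
        dist.summary_frame().to_csv(out / "fst_summary.csv", index=False)
        record(
            "fst", "ok",
            n_used=dist.n_used, n_excluded=dist.n_excluded,
            percentile_99=dist.percentile_99,
        )
    except (FileNotFoundError, SpecValidationError) as exc:
        record("fst", "skipped", reason=str(exc))

    # --- divergence classification -------------------------------------------
    if dist is not None and records:
        report = popgen.classify_traits(records, dist)
        report.table.to_csv(out / "divergence.csv", index=False)
        record("classify", "ok", n_exceeding=len(report.exceeding()))
    else:
        record("classify", "skipped", reason="needs quantgen and fst stages")

    # --- MRT -----------------------------------------------------------------
    try:
        if config.simulate:
            predictors = synth.generate_predictors(
                design, n_climate_vars=config.n_climate_vars, seed=pred_seed
            )
        elif config.predictors_csv is not None:
            predictors = pd.read_csv(config.predictors_csv, index_col=0)
        else:
            raise FileNotFoundError("no predictor input configured")
        geno_means = pheno.groupby(["population", "genotype"])[trait_list].mean()
        growth_cols = [c for c in traits.GROWTH_BRANCH_TRAITS if c in geno_means]
        resp_cols = config.mrt_responses or [
            c for c in ("BS", "BF", "I20", "d13C") if c in geno_means
        ]
        blocks = []
        if len(growth_cols) >= 3:
            pca = mrt.pca_growth(geno_means[growth_cols])
            blocks.append(pca.scores)
            manifest["pca_variance_fraction"] = pca.cumulative_fraction
        if resp_cols:
            blocks.append(geno_means[resp_cols])
        responses = pd.concat(blocks, axis=1).dropna()
        pop_of_geno = responses.index.get_level_values("population")
        pred_rows = predictors.loc[pop_of_geno].set_index(responses.index)
        tree = mrt.fit_mrt(
            responses, pred_rows,
            max_leaves=config.mrt_max_leaves,
            min_node_size=config.mrt_min_node_size,
            standardize=config.mrt_standardize,
        )
        tree.to_json(out / "mrt.json")
        tree.leaf_membership().to_csv(out / "mrt_leaves.csv")
        mrt.leaf_profiles(tree, responses).to_csv(out / "mrt_profiles.csv", index=False)
        record(
            "mrt", "ok",
            n_leaves=tree.n_leaves, variance_explained=tree.variance_explained,
        )
    except FileNotFoundError as exc:
        record("mrt", "skipped", reason=str(exc))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
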