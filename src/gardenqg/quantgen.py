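"""Q_ST, broad-sense heritabilities, bootstrap CIs and trait correlations.

For a clonally replicated design the statistics are ratios of the REML
variance components:

    Q_ST      = sigma2_P / (sigma2_P + 2 sigma2_G(P))
    H2_G(P)   = sigma2_G / (sigma2_G + sigma2_eps)          (within pop.)
    H2_G      = (sigma2_P + sigma2_G) / (sigma2_P + sigma2_G + sigma2_eps)

Confidence intervals come from a parametric bootstrap: datasets are
simulated from the fitted Gaussian model on the observed design (including
its missingness pattern), refitted by REML, and the statistics recomputed;
percentile intervals are reported.  Genetic correlations r are Pearson
correlations of genotype BLUPs, phenotypic correlations R are correlations
of genotype means, and environmental correlations follow Searle:

    r' = (R - r sqrt(H2_G1 H2_G2)) / sqrt((1 - H2_G1)(1 - H2_G2))
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gardenqg.exceptions import DegenerateInputError
from gardenqg.varcomp import (
    BlupSet,
    VarianceDecomposition,
    _build_layout,
    _fit_components,
    fit_reml,
)


def qst(sigma2_P: float, sigma2_G: float) -> float:
    """Among-population differentiation for a clonal design.

    Q_ST = sigma2_P / (sigma2_P + 2 sigma2_G(P)).  With clonal (not
    half-sib) replication the genetic variance is broad-sense, so this is
    a conservative lower bound on the additive-based Q_ST.
    """
    if sigma2_P < 0 or sigma2_G < 0:
        raise ValueError("variance components must be non-negative")
    denom = sigma2_P + 2.0 * sigma2_G
    if denom == 0:
        raise DegenerateInputError("Q_ST undefined: both variance components are zero")
    return sigma2_P / denom


def heritabilities(decomp: VarianceDecomposition) -> tuple[float, float]:
    """(H2_G(P), H2_G): within-population and across-collection broad-sense.

    H2_G(P) = sigma2_G / (sigma2_G + sigma2_E);
    H2_G = (sigma2_P + sigma2_G) / (sigma2_P + sigma2_G + sigma2_E).
    """
    if decomp.sigma2_E <= 0:
        raise DegenerateInputError("zero residual variance: heritability degenerate")
    s_p, s_g, s_e = decomp.sigma2_P, decomp.sigma2_G, decomp.sigma2_E
    h2_within = s_g / (s_g + s_e)
    h2_across = (s_p + s_g) / (s_p + s_g + s_e)
    return h2_within, h2_across


@dataclass
class QstH2Record:
    """Point estimates and 95% bounds for one trait (Table-4 shape)."""

    trait: str
    qst: float
    h2_within: float
    h2_across: float
    qst_ci: tuple[float, float] | None = None
    h2_within_ci: tuple[float, float] | None = None
    h2_across_ci: tuple[float, float] | None = None
    n_boot_failed: int = 0
    reliable: bool = True


def _simulate_from_fit(
    decomp: VarianceDecomposition, design: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Draw one dataset from the fitted model on the observed design rows."""
    pops, p_idx = np.unique(design["population"].to_numpy(), return_inverse=True)
    key = pd.MultiIndex.from_arrays([design["population"], design["genotype"]])
    genos, g_idx = np.unique(np.asarray(key), return_inverse=True)
    blocks = design["block"].map(decomp.block_effects_hat).to_numpy(dtype=float)
    u_p = rng.normal(0.0, np.sqrt(decomp.sigma2_P), size=len(pops))
    u_g = rng.normal(0.0, np.sqrt(decomp.sigma2_G), size=len(genos))
    eps = rng.normal(0.0, np.sqrt(decomp.sigma2_E), size=len(design))
    p_of_row = u_p[p_idx]
    return decomp.mu_hat + blocks + p_of_row + u_g[g_idx] + eps


def bootstrap_ci(
    data: pd.DataFrame,
    trait: str,
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    fitted: tuple[VarianceDecomposition, BlupSet] | None = None,
    max_failure_fraction: float = 0.2,
) -> QstH2Record:
    """Parametric-bootstrap percentile intervals for Q_ST and both H2.

    ``n_boot`` datasets are simulated from the REML fit on the observed
    design (rows with a missing trait value stay missing), each refitted,
    and the (2.5, 97.5) percentiles of the recomputed statistics taken.
    Replicates whose refit fails are dropped; if more than
    ``max_failure_fraction`` fail the record is flagged unreliable.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a meaningful percentile interval")
    if fitted is None:
        fitted = fit_reml(data, trait)
    decomp, _ = fitted
    rng = np.random.default_rng(seed)

    # one layout, rebuilt responses: the design (and missingness pattern,
    # via case deletion) is identical across bootstrap replicates
    lay = _build_layout(data, trait)
    beta = np.concatenate(
        [[decomp.mu_hat], decomp.block_effects_hat.to_numpy()[1:]]
    )
    fixed = lay.X @ beta
    sd_p, sd_g, sd_e = (
        np.sqrt(decomp.sigma2_P),
        np.sqrt(decomp.sigma2_G),
        np.sqrt(decomp.sigma2_E),
    )
    n_pop = len(lay.population_labels)
    n_geno = len(lay.n_g)
    warm = (
        decomp.sigma2_P / decomp.sigma2_E,
        decomp.sigma2_G / decomp.sigma2_E,
    )

    stats = np.empty((n_boot, 3))
    failed = 0
    for b in range(n_boot):
        y = (
            fixed
            + (rng.normal(0.0, sd_p, n_pop))[lay.p_idx]
            + (rng.normal(0.0, sd_g, n_geno))[lay.g_idx]
            + rng.normal(0.0, sd_e, lay.n)
        )
        lay.set_y(y)
        try:
            s_p, s_g, s_e, _ = _fit_components(lay, tol=1e-8, x0=warm, grad_tol=3e-6)
            stats[b] = (
                qst(s_p, s_g),
                s_g / (s_g + s_e),
                (s_p + s_g) / (s_p + s_g + s_e),
            )
        except Exception:  # noqa: BLE001 — refit failures are counted, not fatal
            stats[b] = np.nan
            failed += 1

    ok = stats[~np.isnan(stats).any(axis=1)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(ok, [100 * alpha, 100 * (1 - alpha)], axis=0)
    h2w0, h2a0 = heritabilities(decomp)
    return QstH2Record(
        trait=trait,
        qst=qst(decomp.sigma2_P, decomp.sigma2_G),
        h2_within=h2w0,
        h2_across=h2a0,
        qst_ci=(lo[0], hi[0]),
        h2_within_ci=(lo[1], hi[1]),
        h2_across_ci=(lo[2], hi[2]),
        n_boot_failed=failed,
        reliable=failed <= max_failure_fraction * n_boot,
    )


@dataclass
class CorrelationTriplet:
    """Phenotypic (R), genetic (r) and environmental (r') correlations."""

    trait_a: str
    trait_b: str
    R: float
    r: float
    r_prime: float | None


def searle_environmental_correlation(R: float, r: float, h2_a: float, h2_b: float) -> float:
    """Searle's environmental correlation from R, r and two heritabilities."""
    if h2_a >= 1.0 or h2_b >= 1.0:
        raise DegenerateInputError("r' undefined when a heritability reaches 1")
    val = (R - r * np.sqrt(h2_a * h2_b)) / np.sqrt((1.0 - h2_a) * (1.0 - h2_b))
    if not -1.0 <= val <= 1.0:
        warnings.warn(
            f"Searle r' = {val:.3f} outside [-1, 1] (estimation noise); reported raw",
            stacklevel=2,
        )
    return float(val)


def correlations(
    blups: dict[str, BlupSet],
    data: pd.DataFrame,
    h2: dict[str, float],
) -> list[CorrelationTriplet]:
    """Pairwise R, r and r' for every trait pair.

    r is the Pearson correlation of genotype BLUPs, R the Pearson
    correlation of genotype phenotypic means; both are computed over the
    genotypes shared by the pair.  ``h2`` maps traits to their
    across-collection heritability H2_G (the scale on which Searle's
    decomposition applies).
    """
    traits = list(blups)
    geno_means = data.groupby(["population", "genotype"], sort=True)[traits].mean()
    out = []
    for a, b in itertools.combinations(traits, 2):
        shared = blups[a].genotype_blups.index.intersection(blups[b].genotype_blups.index)
        ga = blups[a].genotype_blups.loc[shared]
        gb = blups[b].genotype_blups.loc[shared]
        r = float(np.corrcoef(ga, gb)[0, 1])
        means = geno_means.loc[shared, [a, b]].dropna()
        R = float(np.corrcoef(means[a], means[b])[0, 1])
        try:
            rp = searle_environmental_correlation(R, r, h2[a], h2[b])
        except DegenerateInputError:
            rp = None
        out.append(CorrelationTriplet(a, b, R=R, r=r, r_prime=rp))
    return out


def records_to_frame(records: list[QstH2Record]) -> pd.DataFrame:
    """Table-4-shaped export: one row per trait with estimates and bounds."""
    rows = []
    for rec in records:
        row = {
            "trait": rec.trait,
            "QST": rec.qst,
            "H2_GP": rec.h2_within,
            "H2_G": rec.h2_across,
        }
        for name, ci in (
            ("QST", rec.qst_ci),
            ("H2_GP", rec.h2_within_ci),
            ("H2_G", rec.h2_across_ci),
        ):
            row[f"{name}_lower"], row[f"{name}_upper"] = ci if ci else (np.nan, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix_frame(
    triplets: list[CorrelationTriplet], traits: list[str]
) -> pd.DataFrame:
    """Square matrix with genetic r below the diagonal and r' above."""
    mat = pd.DataFrame(np.nan, index=traits, columns=traits)
    pos = {t: i for i, t in enumerate(traits)}
    for tr in triplets:
        i, j = pos[tr.trait_a], pos[tr.trait_b]
        lo, hi = (i, j) if i > j else (j, i)
        mat.iloc[lo, hi] = tr.r
        mat.iloc[hi, lo] = tr.r_prime if tr.r_prime is not None else np.nan
    return mat
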