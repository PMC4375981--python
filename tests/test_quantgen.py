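"""Tests for Q_ST, heritabilities, bootstrap CIs and trait correlations."""

import numpy as np
import pandas as pd
import pytest

from gardenqg import quantgen, synth, varcomp
from gardenqg.exceptions import DegenerateInputError
from gardenqg.quantgen import (
    bootstrap_ci,
    correlations,
    heritabilities,
    qst,
    searle_environmental_correlation,
)
from gardenqg.synth import DesignSpec, TraitGenSpec
from gardenqg.varcomp import VarianceDecomposition


def _decomp(s_p, s_g, s_e):
    return VarianceDecomposition(
        trait="t", sigma2_P=s_p, sigma2_G=s_g, sigma2_E=s_e,
        mu_hat=0.0, block_effects_hat=pd.Series([0.0]),
        logREML=0.0, converged=True, n_obs=0,
    )


class TestQst:
    @pytest.mark.parametrize(
        "s_p, s_g, expected",
        [
            (0.0, 0.5, 0.0),          # no among-population variance
            (0.3, 0.3, 1.0 / 3.0),    # equal components
            (0.2, 0.1, 0.5),          # the study-scale ground truth
            (1.0, 0.0, 1.0),
        ],
    )
    def test_known_values(self, s_p, s_g, expected):
        assert qst(s_p, s_g) == pytest.approx(expected)

    def test_both_zero_signaled(self):
        with pytest.raises(DegenerateInputError):
            qst(0.0, 0.0)

    def test_monotonicity(self):
        grid = np.linspace(0.01, 1.0, 25)
        up = [qst(v, 0.3) for v in grid]
        down = [qst(0.3, v) for v in grid]
        assert all(a < b for a, b in zip(up, up[1:]))
        assert all(a > b for a, b in zip(down, down[1:]))


class TestHeritabilities:
    def test_within_population_ratio(self):
        h2w, _ = heritabilities(_decomp(0.0, 1.0, 3.0))
        assert h2w == pytest.approx(0.25)

    def test_coincide_when_no_population_variance(self):
        h2w, h2a = heritabilities(_decomp(0.0, 0.4, 0.6))
        assert h2w == pytest.approx(h2a)

    def test_across_collection_value(self):
        _, h2a = heritabilities(_decomp(0.2, 0.1, 0.7))
        assert h2a == pytest.approx(0.3)

    def test_zero_residual_signaled(self):
        with pytest.raises(DegenerateInputError):
            heritabilities(_decomp(0.1, 0.1, 0.0))


class TestSearle:
    def test_vanishing_numerator(self):
        # R = r * sqrt(h1 h2) makes the environmental correlation zero
        assert searle_environmental_correlation(0.2, 0.8, 0.25, 0.25) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # (0.6 - 0.8*0.25) / 0.75 = 0.5333...
        val = searle_environmental_correlation(0.6, 0.8, 0.25, 0.25)
        assert val == pytest.approx((0.6 - 0.2) / 0.75)

    def test_unit_heritability_degenerate(self):
        with pytest.raises(DegenerateInputError):
            searle_environmental_correlation(0.5, 0.5, 1.0, 0.3)

    def test_out_of_range_warns_but_reports_raw(self):
        with pytest.warns(UserWarning, match="outside"):
            val = searle_environmental_correlation(0.99, -0.99, 0.9, 0.9)
        assert val > 1.0


@pytest.fixture(scope="module")
def small_fit():
    design = DesignSpec(n_populations=10, genotypes_per_population=(6,) * 10)
    spec = TraitGenSpec(name="t", mu=10.0, sigma2_P=0.2, sigma2_G=0.1,
                        sigma2_E=0.7, block_effects=(0.0, 0.5, -0.3, 0.1))
    df = synth.generate_phenotypes(design, [spec], seed=20)
    return df, varcomp.fit_reml(df, "t")


@pytest.fixture(scope="module")
def two_trait_fit():
    n_pop, gpp = 20, 12
    design = DesignSpec(n_populations=n_pop, genotypes_per_population=(gpp,) * n_pop)
    rho = 0.7
    specs = [
        TraitGenSpec(name=t, sigma2_P=0.05, sigma2_G=0.6, sigma2_E=0.05)
        for t in ("a", "b")
    ]
    corr = np.array([[1.0, rho], [rho, 1.0]])
    df = synth.generate_phenotypes(design, specs, seed=30, genetic_corr=corr)
    fits = varcomp.fit_all_traits(df, ["a", "b"])
    blups = {t: f[1] for t, f in fits.results.items()}
    h2 = {t: heritabilities(f[0])[1] for t, f in fits.results.items()}
    return df, blups, h2, rho


class TestBootstrap:

    def test_deterministic_given_seed(self, small_fit):
        df, fitted = small_fit
        a = bootstrap_ci(df, "t", n_boot=150, seed=5, fitted=fitted)
        b = bootstrap_ci(df, "t", n_boot=150, seed=5, fitted=fitted)
        assert a.qst_ci == b.qst_ci
        assert a.h2_across_ci == b.h2_across_ci

    def test_interval_brackets_point_estimate(self, small_fit):
        df, fitted = small_fit
        rec = bootstrap_ci(df, "t", n_boot=200, seed=6, fitted=fitted)
        lo, hi = rec.qst_ci
        assert lo < hi
        assert lo <= rec.qst + 0.15 and hi >= rec.qst - 0.15
        assert rec.n_boot_failed == 0 and rec.reliable

    def test_zero_population_variance_truth_lower_bound_near_zero(self):
        design = DesignSpec(n_populations=10, genotypes_per_population=(6,) * 10)
        spec = TraitGenSpec(name="t", sigma2_P=0.0, sigma2_G=0.3, sigma2_E=0.7)
        df = synth.generate_phenotypes(design, [spec], seed=21)
        rec = bootstrap_ci(df, "t", n_boot=150, seed=3)
        assert rec.qst_ci[0] == pytest.approx(0.0, abs=0.02)

    def test_width_shrinks_with_more_genotypes(self):
        """Mean CI width decreases as genotypes per population grow.

        Averaged over replicate datasets because a single dataset's width
        depends strongly on where its point estimate happens to land.
        """
        mean_widths = []
        for gpp in (4, 16):
            design = DesignSpec(
                n_populations=12, genotypes_per_population=(gpp,) * 12
            )
            spec = TraitGenSpec(name="t", sigma2_P=0.2, sigma2_G=0.1, sigma2_E=0.7)
            widths = []
            for seed in range(6):
                df = synth.generate_phenotypes(design, [spec], seed=100 + seed)
                rec = bootstrap_ci(df, "t", n_boot=150, seed=seed)
                widths.append(rec.qst_ci[1] - rec.qst_ci[0])
            mean_widths.append(np.mean(widths))
        assert mean_widths[1] < mean_widths[0]

    def test_small_n_boot_rejected(self, small_fit):
        df, fitted = small_fit
        with pytest.raises(ValueError):
            bootstrap_ci(df, "t", n_boot=10, fitted=fitted)


class TestCorrelations:
    def test_genetic_correlation_recovers_planted_rho(self, two_trait_fit):
        df, blups, h2, rho = two_trait_fit
        trips = correlations(blups, df, h2)
        assert trips[0].r == pytest.approx(rho, abs=0.1)

    def test_self_correlation_identity(self, two_trait_fit):
        df, blups, h2, _ = two_trait_fit
        doubled = {"a": blups["a"], "a2": blups["a"]}
        df2 = df.copy()
        df2["a2"] = df2["a"]
        trips = correlations(doubled, df2, {"a": h2["a"], "a2": h2["a"]})
        assert trips[0].r == pytest.approx(1.0)
        assert trips[0].R == pytest.approx(1.0)

    def test_environmental_correlation_centers_on_zero(self):
        """Independent residuals give r' near zero even with genetic corr."""
        n_pop, gpp = 20, 12
        design = DesignSpec(
            n_populations=n_pop, genotypes_per_population=(gpp,) * n_pop
        )
        specs = [
            TraitGenSpec(name=t, sigma2_P=0.1, sigma2_G=0.4, sigma2_E=0.5)
            for t in ("a", "b")
        ]
        corr = np.eye(2)
        vals = []
        for seed in range(4):
            df = synth.generate_phenotypes(design, specs, seed=seed, genetic_corr=corr)
            fits = varcomp.fit_all_traits(df, ["a", "b"])
            blups = {t: f[1] for t, f in fits.results.items()}
            h2 = {t: heritabilities(f[0])[1] for t, f in fits.results.items()}
            trip = correlations(blups, df, h2)[0]
            if trip.r_prime is not None:
                vals.append(trip.r_prime)
        assert abs(np.mean(vals)) < 0.15

    def test_environmental_correlation_detects_planted_residual_corr(self):
        """Planted residual correlation shows up as clearly positive r'.

        The genotype-mean/BLUP estimator attenuates the magnitude of the
        residual correlation (genotype means average the residuals, and
        H2 is an individual-level fraction), so the check is for a clear
        positive signal with genetically independent traits — not for the
        raw planted value.
        """
        n_pop, gpp = 20, 12
        design = DesignSpec(
            n_populations=n_pop, genotypes_per_population=(gpp,) * n_pop
        )
        rho = 0.6
        specs = [
            TraitGenSpec(name=t, sigma2_P=0.1, sigma2_G=0.3, sigma2_E=0.6)
            for t in ("a", "b")
        ]
        res_corr = np.array([[1.0, rho], [rho, 1.0]])
        vals = []
        for seed in range(5):
            df = synth.generate_phenotypes(
                design, specs, seed=400 + seed,
                genetic_corr=np.eye(2), residual_corr=res_corr,
            )
            fits = varcomp.fit_all_traits(df, ["a", "b"])
            blups = {t: f[1] for t, f in fits.results.items()}
            h2 = {t: heritabilities(f[0])[1] for t, f in fits.results.items()}
            trip = correlations(blups, df, h2)[0]
            if trip.r_prime is not None:
                vals.append(trip.r_prime)
        assert np.mean(vals) > 0.10

    def test_matrix_layout(self, two_trait_fit):
        df, blups, h2, _ = two_trait_fit
        trips = correlations(blups, df, h2)
        mat = quantgen.correlation_matrix_frame(trips, ["a", "b"])
        assert mat.loc["b", "a"] == trips[0].r          # genetic below diagonal
        assert mat.loc["a", "b"] == trips[0].r_prime    # environmental above
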