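"""REML variance components for the clonal nested common-garden model.

The observation model is

    Y_ijk = mu + B_i + P_j + G_k(P_j) + eps_ijk

with block B_i fixed, population P_j ~ N(0, sigma2_P), genotype within
population G_k(P_j) ~ N(0, sigma2_G) and residual eps ~ N(0, sigma2_E),
all independent.  Because populations are mutually independent and
genotypes are nested, the marginal covariance is block-diagonal by
population with a two-level compound-symmetric structure inside.  The
restricted log-likelihood therefore reduces to closed-form expressions in
per-genotype and per-population sums (two nested Sherman–Morrison steps),
which makes a single likelihood evaluation O(n) with tiny constants.  The
fit profiles out sigma2_E and the fixed effects and searches over the two
variance ratios (sigma2_P/sigma2_E, sigma2_G/sigma2_E) on the log scale
with a damped Newton iteration driven by the analytic gradient of the
profiled criterion (a simplex fallback covers pathological surfaces, and
explicit 1-D boundary profiles handle ratios collapsing to zero).  This
keeps a refit in the low millisecond range, which the parametric
bootstrap relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from gardenqg.exceptions import ConvergenceError, IdentifiabilityError

_log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
#: variance ratios below this are pinned to the zero boundary
_BOUNDARY_RATIO = 1e-7


@dataclass
class VarianceDecomposition:
    """REML estimates for one trait."""

    trait: str
    sigma2_P: float
    sigma2_G: float
    sigma2_E: float
    mu_hat: float
    block_effects_hat: pd.Series  # effect per block, reference block = 0
    logREML: float
    converged: bool
    n_obs: int

    @property
    def total_variance(self) -> float:
        return self.sigma2_P + self.sigma2_G + self.sigma2_E


@dataclass
class BlupSet:
    """Predicted random effects at the REML optimum.

    ``genotype_blups`` holds total genetic values (population effect +
    genotype-within-population effect) under the default ``blup_scope=
    "total"``, or the within-population effect alone under ``"within"``.
    """

    genotype_blups: pd.Series
    population_blups: pd.Series
    scope: str = "total"


@dataclass
class _Layout:
    """Preprocessed design arrays for one trait (complete cases only)."""

    y: np.ndarray
    X: np.ndarray
    g_idx: np.ndarray       # genotype code per row
    p_of_g: np.ndarray      # population code per genotype
    p_idx: np.ndarray       # population code per row
    n_g: np.ndarray         # rows per genotype
    genotype_labels: np.ndarray
    population_labels: np.ndarray
    block_labels: np.ndarray
    # cached sufficient statistics
    C: np.ndarray = field(init=False)       # [X | y]
    CtC: np.ndarray = field(init=False)
    S: np.ndarray = field(init=False)       # per-genotype column sums of C
    M: np.ndarray = field(init=False)       # population-by-genotype indicator

    def __post_init__(self):
        self.C = np.column_stack([self.X, self.y])
        self.CtC = self.C.T @ self.C
        n_geno = len(self.n_g)
        S = np.zeros((n_geno, self.C.shape[1]))
        np.add.at(S, self.g_idx, self.C)
        self.S = S
        n_pop = len(self.population_labels)
        M = np.zeros((n_pop, n_geno))
        M[self.p_of_g, np.arange(n_geno)] = 1.0
        self.M = M

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def set_y(self, y: np.ndarray) -> None:
        """Swap the response in place, refreshing the cached statistics.

        The design part of the caches is unchanged, so this is O(n) and
        cheap — the parametric bootstrap relies on it to avoid rebuilding
        the layout from a DataFrame for every refit.
        """
        y = np.asarray(y, dtype=float)
        self.y = y
        self.C[:, -1] = y
        xty = self.X.T @ y
        self.CtC[:-1, -1] = xty
        self.CtC[-1, :-1] = xty
        self.CtC[-1, -1] = y @ y
        self.S[:, -1] = np.bincount(self.g_idx, weights=y, minlength=len(self.n_g))


def _build_layout(data: pd.DataFrame, trait: str) -> _Layout:
    cols = ["block", "population", "genotype", trait]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"phenotype table lacks columns: {missing}")
    df = data[cols].dropna()
    if df.empty:
        raise IdentifiabilityError(f"trait {trait!r}: no complete observations")

    blocks, b_idx = np.unique(df["block"].to_numpy(), return_inverse=True)
    pops, p_idx = np.unique(df["population"].to_numpy(), return_inverse=True)
    # genotype codes are nested: key on (population, genotype)
    geno_key = pd.MultiIndex.from_arrays([df["population"], df["genotype"]])
    genos, g_idx = np.unique(np.asarray(geno_key), return_inverse=True)
    n_g = np.bincount(g_idx)
    p_of_g = np.zeros(len(genos), dtype=int)
    p_of_g[g_idx] = p_idx

    if len(pops) < 2:
        raise IdentifiabilityError(
            "need >= 2 populations to estimate an among-population variance"
        )
    genos_per_pop = np.bincount(p_of_g, minlength=len(pops))
    if genos_per_pop.max() < 2 and n_g.max() < 2:
        raise IdentifiabilityError(
            "one genotype per population and one ramet per genotype: "
            "sigma2_G and sigma2_E are confounded"
        )

    n = len(df)
    X = np.zeros((n, len(blocks)))
    X[:, 0] = 1.0
    for j in range(1, len(blocks)):
        X[b_idx == j, j] = 1.0
    return _Layout(
        y=df[trait].to_numpy(dtype=float),
        X=X,
        g_idx=g_idx,
        p_of_g=p_of_g,
        p_idx=p_idx,
        n_g=n_g,
        genotype_labels=np.asarray(genos, dtype=object),
        population_labels=pops,
        block_labels=blocks,
    )


def _neg2_restricted_ll(lay: _Layout, gamma_p: float, gamma_g: float):
    """-2 * restricted log-likelihood, profiled over sigma2_E and betas.

    Returns (value, rss, logdetW, cho_Gxx, Gxy) so the caller can recover
    estimates at the optimum without re-evaluating.
    """
    if not (np.isfinite(gamma_p) and np.isfinite(gamma_g)):
        return np.inf, np.nan, np.nan, None, None
    d = 1.0 + gamma_g * lay.n_g                    # genotype-level factors
    Sd = lay.S / d[:, None]
    T1 = gamma_g * (Sd.T @ lay.S)
    t = lay.M @ (lay.n_g / d)                      # 1' A^-1 1 per population
    e = 1.0 + gamma_p * t
    U = lay.M @ Sd                                 # 1' A^-1 C per population
    T2 = (U * (gamma_p / e)[:, None]).T @ U
    Gm = lay.CtC - T1 - T2
    p = lay.p
    Gxx = Gm[:p, :p]
    Gxy = Gm[:p, p]
    try:
        cho = np.linalg.cholesky(Gxx)
    except np.linalg.LinAlgError:
        return np.inf, np.nan, np.nan, None, None
    beta_half = np.linalg.solve(cho, Gxy)
    rss = Gm[p, p] - beta_half @ beta_half
    if rss <= 0:
        return np.inf, np.nan, np.nan, None, None
    nmp = lay.n - p
    logdet_w = float(np.log(d).sum() + np.log(e).sum())
    logdet_gxx = 2.0 * float(np.log(np.diag(cho)).sum())
    val = nmp * (np.log(rss / nmp) + 1.0 + _LOG_2PI) + logdet_w + logdet_gxx
    return val, rss, logdet_w, cho, Gxy


def _reml_value_grad(lay: _Layout, gamma_p: float, gamma_g: float):
    """Profiled -2lR and its analytic gradient wrt (gamma_p, gamma_g).

    Every term of the restricted likelihood is an explicit function of the
    per-genotype factors d_g = 1 + gamma_g n_g and per-population factors
    e_j = 1 + gamma_p t_j, so the derivatives are closed-form; this keeps
    Newton iterations cheap and free of finite-difference noise.
    Returns (value, grad) with grad = (d/dgamma_p, d/dgamma_g), or
    (inf, None) on degeneracy.
    """
    n_g = lay.n_g
    d = 1.0 + gamma_g * n_g
    a = n_g / d
    S = lay.S
    Sd = S / d[:, None]
    t = lay.M @ a
    e = 1.0 + gamma_p * t
    U = lay.M @ Sd
    T1 = gamma_g * (Sd.T @ S)
    T2 = (U * (gamma_p / e)[:, None]).T @ U
    Gm = lay.CtC - T1 - T2
    p = lay.p
    Gxx = Gm[:p, :p]
    Gxy = Gm[:p, p]
    try:
        cho = np.linalg.cholesky(Gxx)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(cho.T, np.linalg.solve(cho, Gxy))
    rss = Gm[p, p] - Gxy @ beta
    if rss <= 0:
        return np.inf, None
    nmp = lay.n - p
    value = (
        nmp * (np.log(rss / nmp) + 1.0 + _LOG_2PI)
        + float(np.log(d).sum() + np.log(e).sum())
        + 2.0 * float(np.log(np.diag(cho)).sum())
    )

    # gradient pieces
    q = lay.M @ (a * a)                       # sum of (n_g/d_g)^2 per pop
    V = lay.M @ (S * (n_g / d**2)[:, None])   # d u_j / d gamma_g = -V rows
    inv_e = 1.0 / e
    # dG/dgamma_g = -S'S/d^2 + gp[(V'U + U'V)/e] - gp^2 (U' diag(q/e^2) U)
    dG_g = (
        -((S / d[:, None] ** 2).T @ S)
        + gamma_p * ((V * inv_e[:, None]).T @ U + (U * inv_e[:, None]).T @ V)
        - gamma_p**2 * ((U * (q * inv_e**2)[:, None]).T @ U)
    )
    dG_p = -((U * (inv_e**2)[:, None]).T @ U)

    gxx_inv = np.linalg.inv(Gxx)

    def dir_deriv(dG):
        dxx = dG[:p, :p]
        dxy = dG[:p, p]
        dyy = dG[p, p]
        d_rss = dyy - 2.0 * (beta @ dxy) + beta @ dxx @ beta
        return nmp * d_rss / rss + float((gxx_inv * dxx).sum())

    grad_p = dir_deriv(dG_p) + float((t * inv_e).sum())
    grad_g = (
        dir_deriv(dG_g)
        + float(a.sum())
        - gamma_p * float((q * inv_e).sum())
    )
    return value, np.array([grad_p, grad_g])


def _moment_start(lay: _Layout) -> tuple[float, float]:
    """Crude method-of-moments variance ratios used to seed the search."""
    y = lay.y
    g_mean = np.bincount(lay.g_idx, y) / lay.n_g
    resid = y - g_mean[lay.g_idx]
    df_e = max(lay.n - len(lay.n_g), 1)
    sig_e = max(float(resid @ resid) / df_e, 1e-12)
    nbar = float(lay.n_g.mean())
    pops_n = np.bincount(lay.p_of_g)
    p_mean = np.bincount(lay.p_of_g, weights=g_mean) / pops_n
    within = g_mean - p_mean[lay.p_of_g]
    df_g = max(len(lay.n_g) - len(pops_n), 1)
    sig_g = max(float(within @ within) / df_g - sig_e / nbar, 0.0)
    sig_p = max(float(np.var(p_mean, ddof=1)) - sig_g / max(pops_n.mean(), 1.0), 0.0)
    return sig_p / sig_e, sig_g / sig_e


def fit_reml(
    data: pd.DataFrame,
    trait: str,
    *,
    blup_scope: str = "total",
    tol: float = 1e-10,
) -> tuple[VarianceDecomposition, BlupSet]:
    """Fit the nested mixed model for one trait by REML.

    Parameters
    ----------
    data
        Ramet-level table with columns block, population, genotype and the
        trait; rows with a missing trait value are dropped (case deletion).
    trait
        Column to analyze.
    blup_scope
        ``"total"`` (default): genotype BLUP = population effect + genotype
        effect, the total genetic value used for across-collection
        correlations.  ``"within"``: genotype effect alone.
    tol
        Convergence tolerance on the restricted log-likelihood.

    Returns
    -------
    (VarianceDecomposition, BlupSet)
    """
    if blup_scope not in ("total", "within"):
        raise ValueError("blup_scope must be 'total' or 'within'")
    lay = _build_layout(data, trait)
    gamma_p, gamma_g, converged = _optimize(lay, tol)
    return _finish(lay, trait, gamma_p, gamma_g, converged, blup_scope)


def _newton2d(lay, x0, max_iter=40, h=1e-5, grad_tol=1e-8):
    """Damped Newton minimization over (log gamma_p, log gamma_g).

    Uses the analytic gradient of the profiled restricted likelihood; the
    Hessian is built by finite-differencing the gradient (two extra
    evaluations per iteration), floored and step-capped so the near-flat
    log-space directions at gamma -> 0 cannot derail the search.
    Converges when the log-space gradient norm drops below ``grad_tol``.
    Returns (x, fx, converged); converged=False hands over to the
    caller's simplex fallback or boundary profiles.
    """

    def fg(x):
        if np.any(x > 45.0):
            return np.inf, None
        with np.errstate(all="ignore"):
            val, grad = _reml_value_grad(lay, float(np.exp(x[0])), float(np.exp(x[1])))
        if grad is None or not np.all(np.isfinite(grad)):
            return val, None
        return val, grad * np.exp(x)  # chain rule to the log scale

    x = np.asarray(x0, dtype=float)
    fx, gx = fg(x)
    if not np.isfinite(fx) or gx is None:
        return x, fx, False
    for _ in range(max_iter):
        if float(np.max(np.abs(gx))) < grad_tol:
            return x, fx, True
        _, g1 = fg(x + [h, 0.0])
        _, g2 = fg(x + [0.0, h])
        if g1 is None or g2 is None:
            return x, fx, False
        H = np.column_stack([(g1 - gx) / h, (g2 - gx) / h])
        H = (H + H.T) / 2.0
        w = np.linalg.eigvalsh(H)
        floor = max(1e-6, 1e-3 * float(np.abs(w).max()))
        if w[0] < floor:
            H = H + (floor - w[0]) * np.eye(2)
        step = np.linalg.solve(H, gx)
        norm = float(np.max(np.abs(step)))
        if norm > 3.0:
            step *= 3.0 / norm
        t, improved = 1.0, False
        while t >= 1e-4:
            cand_x = x - t * step
            cand_f, cand_g = fg(cand_x)
            if np.isfinite(cand_f) and cand_f < fx and cand_g is not None:
                x, fx, gx = cand_x, cand_f, cand_g
                improved = True
                break
            t /= 2.0
        if not improved:
            # stalled: accept only if already at a (numerically) flat point
            return x, fx, float(np.max(np.abs(gx))) < 1e-6
        if np.min(x) < np.log(_BOUNDARY_RATIO / 10):
            return x, fx, False
    return x, fx, float(np.max(np.abs(gx))) < 1e-6


def _optimize(
    lay: _Layout,
    tol: float,
    x0: tuple[float, float] | None = None,
    grad_tol: float = 1e-8,
) -> tuple[float, float, bool]:
    def f(theta):
        if np.any(theta > 45.0):  # e^45 ratios: numerically meaningless
            return np.inf
        with np.errstate(all="ignore"):
            return _neg2_restricted_ll(lay, np.exp(theta[0]), np.exp(theta[1]))[0]

    if x0 is None:
        gp0, gg0 = _moment_start(lay)
    else:
        gp0, gg0 = x0
    start = np.log([max(gp0, 1e-3), max(gg0, 1e-3)])
    xo, fo, ok = _newton2d(lay, start, grad_tol=grad_tol)
    if not ok and np.min(xo) > np.log(1e-4):
        # genuinely stuck in the interior: fall back to a simplex search;
        # boundary-headed stalls skip this and rely on the 1-D profiles
        res = optimize.minimize(
            f, xo, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol, "maxiter": 600, "maxfev": 600},
        )
        xo, fo, ok = res.x, res.fun, res.success
    cand = [(fo, float(np.exp(xo[0])), float(np.exp(xo[1])), ok)]

    def profile_1d(fixed_p: bool):
        # Brent misbehaves on non-finite values, so clamp them
        def obj(lg):
            if lg > 45.0:
                return 1e300
            with np.errstate(all="ignore"):
                g = float(np.exp(lg))
                v = _neg2_restricted_ll(
                    lay, 0.0 if fixed_p else g, g if fixed_p else 0.0
                )[0]
            return v if np.isfinite(v) else 1e300

        g0 = max(gg0 if fixed_p else gp0, 1e-3)
        return optimize.minimize_scalar(
            obj,
            bracket=(np.log(g0) - 1, np.log(g0) + 1),
            method="brent", options={"xtol": 1e-10},
        )

    near_zero_p = cand[0][1] < 1e-4
    near_zero_g = cand[0][2] < 1e-4
    if near_zero_p or not ok:
        r = profile_1d(fixed_p=True)
        cand.append((r.fun, 0.0, float(np.exp(r.x)), True))
    if near_zero_g or not ok:
        r = profile_1d(fixed_p=False)
        cand.append((r.fun, float(np.exp(r.x)), 0.0, True))
    if (near_zero_p and near_zero_g) or not ok:
        cand.append((_neg2_restricted_ll(lay, 0.0, 0.0)[0], 0.0, 0.0, True))

    fun, gamma_p, gamma_g, ok = min(cand, key=lambda c: c[0])
    if not np.isfinite(fun):
        raise ConvergenceError("restricted likelihood is degenerate everywhere tried")
    if gamma_p < _BOUNDARY_RATIO:
        gamma_p = 0.0
    if gamma_g < _BOUNDARY_RATIO:
        gamma_g = 0.0
    return gamma_p, gamma_g, bool(ok)


def _fit_components(
    lay: _Layout,
    tol: float = 1e-8,
    x0: tuple[float, float] | None = None,
    grad_tol: float = 1e-8,
) -> tuple[float, float, float, bool]:
    """Variance components only (no BLUPs/fixed effects) for a prebuilt layout.

    ``x0`` optionally warm-starts the search at known variance ratios;
    the parametric bootstrap passes the parent fit's ratios here.
    """
    gamma_p, gamma_g, converged = _optimize(lay, tol, x0=x0, grad_tol=grad_tol)
    _, rss, _, _, _ = _neg2_restricted_ll(lay, gamma_p, gamma_g)
    sigma2_e = rss / (lay.n - lay.p)
    return gamma_p * sigma2_e, gamma_g * sigma2_e, sigma2_e, converged


def _finish(lay, trait, gamma_p, gamma_g, converged, blup_scope):
    val, rss, _, cho, Gxy = _neg2_restricted_ll(lay, gamma_p, gamma_g)
    sigma2_E = rss / (lay.n - lay.p)
    beta = np.linalg.solve(cho.T, np.linalg.solve(cho, Gxy))

    # BLUPs: u_P = gamma_p * 1_j' W^-1 r, u_G = gamma_g * 1_g' W^-1 r
    r = lay.y - lay.X @ beta
    d = 1.0 + gamma_g * lay.n_g
    sr = np.bincount(lay.g_idx, weights=r, minlength=len(lay.n_g))
    a_inv_r = r - (gamma_g / d)[lay.g_idx] * sr[lay.g_idx]
    q = lay.M @ (sr / d)
    e = 1.0 + gamma_p * (lay.M @ (lay.n_g / d))
    z = a_inv_r - gamma_p * (q / e)[lay.p_idx] / d[lay.g_idx]
    u_g = gamma_g * np.bincount(lay.g_idx, weights=z, minlength=len(lay.n_g))
    u_p = gamma_p * np.bincount(lay.p_idx, weights=z, minlength=len(lay.population_labels))

    pop_series = pd.Series(u_p, index=pd.Index(lay.population_labels, name="population"))
    geno_index = pd.MultiIndex.from_tuples(
        list(lay.genotype_labels), names=["population", "genotype"]
    )
    if blup_scope == "total":
        geno_vals = u_g + u_p[lay.p_of_g]
    else:
        geno_vals = u_g
    geno_series = pd.Series(geno_vals, index=geno_index)

    block_effects = pd.Series(
        np.concatenate([[0.0], beta[1:]]), index=pd.Index(lay.block_labels, name="block")
    )
    decomp = VarianceDecomposition(
        trait=trait,
        sigma2_P=gamma_p * sigma2_E,
        sigma2_G=gamma_g * sigma2_E,
        sigma2_E=sigma2_E,
        mu_hat=float(beta[0]),
        block_effects_hat=block_effects,
        logREML=-0.5 * val,
        converged=converged,
        n_obs=lay.n,
    )
    return decomp, BlupSet(geno_series, pop_series, scope=blup_scope)


@dataclass
class MultiTraitFit:
    """Per-trait fits with failures isolated."""

    results: dict[str, tuple[VarianceDecomposition, BlupSet]]
    failures: dict[str, str]


def fit_all_traits(
    data: pd.DataFrame,
    traits: list[str],
    *,
    blup_scope: str = "total",
) -> MultiTraitFit:
    """Fit every trait independently; a failing trait does not abort the rest."""
    if not traits:
        raise ValueError("empty trait list")
    results, failures = {}, {}
    for t in traits:
        try:
            results[t] = fit_reml(data, t, blup_scope=blup_scope)
        except Exception as exc:  # noqa: BLE001 — isolation contract
            _log.warning("trait %s failed: %s", t, exc)
            failures[t] = str(exc)
    return MultiTraitFit(results=results, failures=failures)


def decompositions_to_frame(fits: MultiTraitFit) -> pd.DataFrame:
    """Tidy (trait, component, estimate) export of variance components."""
    rows = []
    for t, (dec, _) in fits.results.items():
        for comp, val in (
            ("sigma2_P", dec.sigma2_P),
            ("sigma2_G", dec.sigma2_G),
            ("sigma2_E", dec.sigma2_E),
        ):
            rows.append({"trait": t, "component": comp, "estimate": val})
    return pd.DataFrame(rows)
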