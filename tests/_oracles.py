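"""Independent oracles used by the test suite.

Each oracle is written directly from the published formulas or by brute
force, deliberately sharing no code with the implementation paths it
checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def anova_variance_components(df: pd.DataFrame, trait: str):
    """Expected-mean-squares estimators for the balanced nested RCB design.

    Requires a fully balanced layout: b blocks, p populations, g genotypes
    per population, one ramet per genotype per block.  Returns
    (sigma2_P, sigma2_G, sigma2_E); REML equals these when the estimates
    are interior.
    """
    b = df["block"].nunique()
    p = df["population"].nunique()
    g_counts = df.groupby("population")["genotype"].nunique()
    assert g_counts.nunique() == 1, "oracle requires equal genotypes per population"
    g = int(g_counts.iloc[0])
    y = df[trait]
    grand = y.mean()
    pop_means = df.groupby("population")[trait].mean()
    geno_means = df.groupby(["population", "genotype"])[trait].mean()
    block_means = df.groupby("block")[trait].mean()
    ss_pop = b * g * ((pop_means - grand) ** 2).sum()
    ss_geno = b * (
        (geno_means - pop_means.reindex(geno_means.index.get_level_values(0)).values)
        ** 2
    ).sum()
    ss_block = p * g * ((block_means - grand) ** 2).sum()
    ss_err = ((y - grand) ** 2).sum() - ss_pop - ss_geno - ss_block
    ms_pop = ss_pop / (p - 1)
    ms_geno = ss_geno / (p * (g - 1))
    ms_err = ss_err / ((b - 1) * (p * g - 1))
    return (ms_pop - ms_geno) / (b * g), (ms_geno - ms_err) / b, ms_err


def wc_theta_from_genotype_counts(tables):
    """Weir & Cockerham (1984) theta from per-population genotype counts.

    ``tables`` is a sequence of (n_AA, n_Aa, n_aa) tuples, one per
    population, counting individuals homozygous reference, heterozygous
    and homozygous alternate.  Scalar Python arithmetic, written straight
    from the published component definitions (a, b, c with n_bar, n_c,
    p_bar, s^2, h_bar).  Returns theta, or None for degenerate input
    (monomorphic overall, < 2 populations with data).
    """
    sizes, freqs, hets = [], [], []
    for n_aa, n_ab, n_bb in tables:
        n = n_aa + n_ab + n_bb
        if n == 0:
            continue
        sizes.append(n)
        freqs.append((n_ab + 2 * n_bb) / (2 * n))  # alternate-allele frequency
        hets.append(n_ab / n)
    r = len(sizes)
    if r < 2:
        return None
    total_alt = sum(n * p for n, p in zip(sizes, freqs))
    if total_alt == 0 or total_alt == sum(sizes):
        return None  # monomorphic in the analyzed sample
    n_bar = sum(sizes) / r
    n_c = (r * n_bar - sum(n * n for n in sizes) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(sizes, freqs)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(sizes, freqs)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(sizes, hets)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


def _ss(Y: np.ndarray) -> float:
    return float(((Y - Y.mean(axis=0)) ** 2).sum())


def _all_splits(x: np.ndarray, min_node_size: int):
    xs = np.unique(x)
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = (lo + hi) / 2.0
        n_left = int((x < thr).sum())
        if n_left >= min_node_size and len(x) - n_left >= min_node_size:
            yield thr


def exhaustive_depth2_ss(Y: np.ndarray, X: np.ndarray, min_node_size: int) -> float:
    """Minimal total within-leaf SS over ALL trees of depth <= 2.

    Dynamic programming: for every root split, each child is optimized
    independently (leaf vs its own best split); the root may also stay a
    leaf.  Brute-force scans every (predictor, midpoint) candidate.
    """

    def best_child(rows: np.ndarray) -> float:
        best = _ss(Y[rows])
        if len(rows) >= 2 * min_node_size:
            for j in range(X.shape[1]):
                for thr in _all_splits(X[rows, j], min_node_size):
                    mask = X[rows, j] < thr
                    cand = _ss(Y[rows[mask]]) + _ss(Y[rows[~mask]])
                    best = min(best, cand)
        return best

    rows = np.arange(len(Y))
    best = _ss(Y)
    if len(rows) >= 2 * min_node_size:
        for j in range(X.shape[1]):
            for thr in _all_splits(X[:, j], min_node_size):
                mask = X[:, j] < thr
                cand = best_child(rows[mask]) + best_child(rows[~mask])
                best = min(best, cand)
    return best


def naive_greedy_tree_ss(
    Y: np.ndarray, X: np.ndarray, min_node_size: int, max_leaves: int, max_depth=None
) -> float:
    """Total leaf SS of a best-first greedy tree, computed naively.

    Re-implements the greedy strategy with explicit per-candidate child-SS
    computation (no incremental prefix-sum algebra), as a check on the
    optimized implementation.
    """

    def best_split(rows):
        best = None
        for j in range(X.shape[1]):
            for thr in _all_splits(X[rows, j], min_node_size):
                mask = X[rows, j] < thr
                gain = _ss(Y[rows]) - _ss(Y[rows[mask]]) - _ss(Y[rows[~mask]])
                if gain > 0 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, j, thr)
        return best

    leaves = [(np.arange(len(Y)), 0)]
    while len(leaves) < max_leaves:
        cands = []
        for i, (rows, depth) in enumerate(leaves):
            if max_depth is not None and depth >= max_depth:
                continue
            if len(rows) < 2 * min_node_size:
                continue
            bs = best_split(rows)
            if bs is not None:
                cands.append((bs[0], i, bs))
        if not cands:
            break
        _, i, (gain, j, thr) = max(cands, key=lambda c: c[0])
        rows, depth = leaves.pop(i)
        mask = X[rows, j] < thr
        leaves.append((rows[mask], depth + 1))
        leaves.append((rows[~mask], depth + 1))
    return sum(_ss(Y[rows]) for rows, _ in leaves)
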