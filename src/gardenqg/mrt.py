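"""Multivariate regression trees over genotype-level phenotypes.

A multivariate regression tree (MRT) extends CART to a multivariate
response: starting from all observations in a root node, the data are
split by repeated binary partitions on the predictor columns (here
geography or climate), each split chosen greedily to minimize the summed
within-child sum of squares over all response columns.  The fitted tree
reports its explained variance 1 - sum(leaf SS) / total SS, per-node
equally good alternative splits (the "could also have been made on
latitude" readout), and per-leaf multivariate trait profiles.

Because the response columns (principal-component scores, Julian days,
percent injury, per-mil isotope ratios) are incommensurate, they are
z-scored by default before SS computation; raw-scale fitting is available
and the choice materially affects the splits.

PCA preprocessing of the eight growth/branching traits lives here too,
delegating the decomposition to scikit-learn.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

# --- PCA preprocessing ------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame          # rows aligned with the input
    loadings: pd.DataFrame        # variables x components
    variance_fractions: np.ndarray

    @property
    def cumulative_fraction(self) -> float:
        return float(self.variance_fractions.sum())


def pca_growth(
    traits: pd.DataFrame, n_components: int = 2, *, scale: bool = True
) -> PcaResult:
    """PCA of the growth/branching trait block.

    Columns are centered and (by default) scaled to unit variance —
    correlation-matrix PCA — before the decomposition.  Constant columns
    are dropped with a warning.  Requires at least 3 complete rows.
    """
    df = traits.dropna()
    if len(df) < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    sds = df.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    pca = PCA(n_components=n_components)
    X = df - df.mean()
    if scale:
        X = X / df.std(ddof=1)
    scores = pca.fit_transform(X.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=df.columns, columns=comp_names),
        variance_fractions=pca.explained_variance_ratio_.copy(),
    )


# --- response container -----------------------------------------------------


@dataclass
class ResponseMatrix:
    """Response block for the tree, with optional per-column z-scoring."""

    values: pd.DataFrame
    standardized: bool
    column_means: pd.Series
    column_sds: pd.Series

    @classmethod
    def build(cls, responses: pd.DataFrame, *, standardize: bool = True) -> "ResponseMatrix":
        df = responses.dropna()
        if df.shape[1] < 1:
            raise ValueError("response matrix needs >= 1 column")
        means = df.mean()
        sds = df.std(ddof=1)
        if standardize:
            if (sds == 0).any():
                bad = sds[sds == 0].index.tolist()
                raise ValueError(f"cannot standardize constant response columns: {bad}")
            df = (df - means) / sds
        return cls(
            values=df, standardized=standardize, column_means=means, column_sds=sds
        )


# --- tree structure ---------------------------------------------------------


@dataclass
class Node:
    node_id: int
    depth: int
    rows: np.ndarray              # positional row indices into the response
    ss: float                     # multivariate within-node SS
    mean: np.ndarray              # node mean vector (fitting scale)
    split_var: str | None = None
    split_threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass
class MRTree:
    root: Node
    response_columns: list[str]
    predictor_columns: list[str]
    total_ss: float
    index: pd.Index               # row labels, aligned with positional indices
    standardized: bool

    def leaves(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return sorted(out, key=lambda nd: nd.node_id)

    def internal_nodes(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.right, node.left])
        return sorted(out, key=lambda nd: nd.node_id)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def variance_explained(self) -> float:
        if self.total_ss == 0:
            return 0.0
        return 1.0 - sum(leaf.ss for leaf in self.leaves()) / self.total_ss

    def leaf_membership(self) -> pd.Series:
        lab = np.empty(len(self.index), dtype=int)
        for leaf in self.leaves():
            lab[leaf.rows] = leaf.node_id
        return pd.Series(lab, index=self.index, name="leaf")

    # --- serialization ---

    def _node_dict(self, node: Node) -> dict:
        d = {
            "id": node.node_id,
            "n": node.n,
            "ss": node.ss,
            "mean": dict(zip(self.response_columns, node.mean.tolist())),
        }
        if not node.is_leaf:
            d["split"] = {"variable": node.split_var, "threshold": node.split_threshold}
            d["left"] = self._node_dict(node.left)
            d["right"] = self._node_dict(node.right)
        return d

    def to_json(self, path=None) -> str:
        doc = {
            "responses": self.response_columns,
            "predictors": self.predictor_columns,
            "standardized_responses": self.standardized,
            "total_ss": self.total_ss,
            "variance_explained": self.variance_explained,
            "n_leaves": self.n_leaves,
            "tree": self._node_dict(self.root),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def render(self) -> str:
        lines = []

        def walk(node: Node, indent: int):
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}leaf #{node.node_id}: n={node.n}, SS={node.ss:.3f}")
            else:
                lines.append(
                    f"{pad}node #{node.node_id}: {node.split_var} < "
                    f"{node.split_threshold:.4g} (n={node.n})"
                )
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


# --- fitting ----------------------------------------------------------------


def _node_ss(Y: np.ndarray, rows: np.ndarray) -> tuple[float, np.ndarray]:
    sub = Y[rows]
    mean = sub.mean(axis=0)
    return float(((sub - mean) ** 2).sum()), mean


def _best_split(Y, X, columns, rows, min_node_size):
    """Best (var, threshold, gain) at a node; gain is the SS reduction.

    Scans every predictor and every midpoint between consecutive distinct
    sorted values; ties are broken by predictor column order, then by the
    lower threshold (first strictly better candidate wins).
    """
    n = len(rows)
    if n < 2 * min_node_size:
        return None
    sub_y = Y[rows]
    tot = sub_y.sum(axis=0)
    base = float(tot @ tot) / n
    best = None
    for ci, col in enumerate(columns):
        x = X[rows, ci]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = sub_y[order]
        csum = np.cumsum(ys, axis=0)
        nl = np.arange(1, n)
        valid = (xs[1:] != xs[:-1]) & (nl >= min_node_size) & (n - nl >= min_node_size)
        if not valid.any():
            continue
        L = csum[:-1]
        R = tot - L
        obj = (L**2).sum(axis=1) / nl + (R**2).sum(axis=1) / (n - nl)
        obj = np.where(valid, obj, -np.inf)
        k = int(np.argmax(obj))
        gain = float(obj[k]) - base
        if gain > 0 and (best is None or gain > best[2] + 1e-12):
            thr = float((xs[k] + xs[k + 1]) / 2.0)
            best = (col, thr, gain)
    return best


def fit_mrt(
    responses: pd.DataFrame | ResponseMatrix,
    predictors: pd.DataFrame,
    *,
    max_leaves: int = 5,
    min_node_size: int = 5,
    max_depth: int | None = None,
    standardize: bool = True,
) -> MRTree:
    """Greedy multivariate regression tree.

    Parameters
    ----------
    responses
        Genotype-level response block (rows = observations); z-scored per
        column by default.  Pass a prebuilt :class:`ResponseMatrix` to
        control scaling explicitly.
    predictors
        Numeric predictor table aligned (by index) with the responses.
    max_leaves, min_node_size, max_depth
        Stopping rules.  Growth is best-first: the leaf whose best split
        removes the most SS is split next, so explained variance is
        non-decreasing in ``max_leaves``.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix.build(responses, standardize=standardize)
    rdf = responses.values
    pred = predictors.reindex(rdf.index)
    if pred.isna().any().any():
        raise ValueError("predictors missing for some response rows")
    if not all(np.issubdtype(dt, np.number) for dt in pred.dtypes):
        raise ValueError("all predictors must be numeric")
    Y = rdf.to_numpy(dtype=float)
    X = pred.to_numpy(dtype=float)
    columns = list(pred.columns)

    counter = 0

    def new_node(rows, depth):
        nonlocal counter
        ss, mean = _node_ss(Y, rows)
        node = Node(node_id=counter, depth=depth, rows=rows, ss=ss, mean=mean)
        counter += 1
        return node

    root = new_node(np.arange(len(rdf)), 0)
    total_ss = root.ss
    # best-first growth: (node, best-split) candidates ordered by gain
    frontier: list[tuple[Node, tuple]] = []

    def push(node):
        if max_depth is not None and node.depth >= max_depth:
            return
        cand = _best_split(Y, X, columns, node.rows, min_node_size)
        if cand is not None:
            frontier.append((node, cand))

    push(root)
    n_leaves = 1
    while frontier and n_leaves < max_leaves:
        idx = max(range(len(frontier)), key=lambda i: frontier[i][1][2])
        node, (col, thr, _gain) = frontier.pop(idx)
        ci = columns.index(col)
        mask = X[node.rows, ci] < thr
        node.split_var = col
        node.split_threshold = thr
        node.left = new_node(node.rows[mask], node.depth + 1)
        node.right = new_node(node.rows[~mask], node.depth + 1)
        push(node.left)
        push(node.right)
        n_leaves += 1

    return MRTree(
        root=root,
        response_columns=list(rdf.columns),
        predictor_columns=columns,
        total_ss=total_ss,
        index=rdf.index,
        standardized=responses.standardized,
    )


def surrogate_equivalent_splits(
    tree: MRTree,
    responses: pd.DataFrame | ResponseMatrix,
    predictors: pd.DataFrame,
    *,
    tol: float = 1e-9,
) -> dict[int, list[tuple[str, float]]]:
    """Per internal node, every (variable, threshold) split whose SS
    reduction matches the node's chosen split within ``tol``.

    Re-scans all predictors and all candidate thresholds at each internal
    node, so duplicated or collinear predictors surface as equivalent
    alternatives.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix.build(responses, standardize=tree.standardized)
    Y = responses.values.to_numpy(dtype=float)
    pred = predictors.reindex(responses.values.index)
    X = pred.to_numpy(dtype=float)
    columns = list(pred.columns)
    out: dict[int, list[tuple[str, float]]] = {}
    for node in tree.internal_nodes():
        rows = node.rows
        n = len(rows)
        sub_y = Y[rows]
        tot = sub_y.sum(axis=0)
        base = float(tot @ tot) / n
        best_gain = node.ss - (node.left.ss + node.right.ss)
        equiv = []
        for ci, col in enumerate(columns):
            x = X[rows, ci]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            ys = sub_y[order]
            csum = np.cumsum(ys, axis=0)
            nl = np.arange(1, n)
            valid = xs[1:] != xs[:-1]
            L = csum[:-1]
            R = tot - L
            obj = (L**2).sum(axis=1) / nl + (R**2).sum(axis=1) / (n - nl)
            gains = obj - base
            hits = np.nonzero(valid & (np.abs(gains - best_gain) <= tol * max(1.0, abs(best_gain))))[0]
            for k in hits:
                equiv.append((col, float((xs[k] + xs[k + 1]) / 2.0)))
        out[node.node_id] = equiv
    return out


def leaf_profiles(tree: MRTree, responses: pd.DataFrame) -> pd.DataFrame:
    """Per-leaf trait means, n, and deviations from the grand mean in SDs.

    ``responses`` is the original (unstandardized) response table used to
    fit the tree; rows are matched by label.
    """
    df = responses.loc[tree.index]
    grand = df.mean()
    sds = df.std(ddof=1)
    membership = tree.leaf_membership()
    rows = []
    for leaf_id, group in df.groupby(membership):
        mean = group.mean()
        for col in df.columns:
            rows.append(
                {
                    "leaf": leaf_id,
                    "n": len(group),
                    "trait": col,
                    "mean": mean[col],
                    "deviation_sd": (mean[col] - grand[col]) / sds[col]
                    if sds[col] > 0
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def select_max_leaves_cv(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    *,
    candidate_leaves: range | list[int] = range(2, 9),
    k_folds: int = 10,
    seed: int = 0,
    min_node_size: int = 5,
    standardize: bool = True,
    parsimony_tol: float = 0.1,
) -> tuple[int, pd.DataFrame]:
    """Pick a tree size by K-fold cross-validated prediction SS.

    For each candidate ``max_leaves`` the tree is fitted on K-1 folds and
    held-out rows are predicted by the mean of the leaf they fall into.
    Following the usual one-standard-error parsimony convention, the
    smallest size whose CV error is within ``parsimony_tol`` (relative)
    of the minimum is returned along with the CV table, so noise-level
    differences between sizes do not select a larger tree.
    """
    resp = ResponseMatrix.build(responses, standardize=standardize)
    rdf = resp.values
    rng = np.random.default_rng(seed)
    n = len(rdf)
    fold = rng.permutation(n) % k_folds
    records = []
    for leaves in candidate_leaves:
        err = 0.0
        for f in range(k_folds):
            train = rdf.index[fold != f]
            test = rdf.index[fold == f]
            if len(train) < 2 * min_node_size or len(test) == 0:
                continue
            tree = fit_mrt(
                ResponseMatrix(
                    values=rdf.loc[train],
                    standardized=resp.standardized,
                    column_means=resp.column_means,
                    column_sds=resp.column_sds,
                ),
                predictors,
                max_leaves=leaves,
                min_node_size=min_node_size,
            )
            pred_test = predictors.reindex(test).to_numpy(dtype=float)
            y_test = rdf.loc[test].to_numpy(dtype=float)
            cols = {c: i for i, c in enumerate(tree.predictor_columns)}
            for i in range(len(test)):
                node = tree.root
                while not node.is_leaf:
                    xv = pred_test[i, cols[node.split_var]]
                    node = node.left if xv < node.split_threshold else node.right
                err += float(((y_test[i] - node.mean) ** 2).sum())
        records.append({"max_leaves": leaves, "cv_ss": err})
    table = pd.DataFrame(records)
    threshold = table["cv_ss"].min() * (1.0 + parsimony_tol)
    ok = table[table["cv_ss"] <= threshold]
    best = int(ok["max_leaves"].min())
    return best, table
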