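"""Moderated mixed graphical model via nodewise EBIC-regularized LASSO.

Each symptom item is regressed on all other items, on G-1 moderator-group
dummies (reference group omitted), and on item x group interaction
columns; the LASSO path is solved per node and the penalty selected by
the Extended Bayesian Information Criterion (EBIC, gamma = 0.5 by
default). Nodewise coefficients are aggregated into undirected edges by
the OR-rule (an edge is kept if either of its two nodewise coefficients
is nonzero; its weight is the mean of the two absolute coefficients,
signed), and interaction coefficients analogously yield group-specific
moderation increments. Conditioning on a group adds that group's
increments to the shared base network, so groups without moderation
effects share an identical network.

Likert items are treated as continuous Gaussian nodes after
standardization — the practical regime of the estimator for 0-3 scales,
and consistent with reporting real-valued weighted networks per group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .datasets import SymptomDataset
from .preprocess import CompletedDatasets

__all__ = [
    "EstimatorConfig",
    "ModeratedMGM",
    "ModeratedNetworkModel",
    "lasso_path_fit",
    "ebic_score",
    "build_moderated_design",
    "fit_moderated_mgm",
    "condition_on_group",
]


@dataclass
class EstimatorConfig:
    """Settings of the moderated-network estimator.

    gamma : EBIC model-space penalty (>= 0; 0 recovers plain BIC).
    n_lambdas, lambda_min_ratio : regularization path, ``n_lambdas``
        log-spaced values from the per-node lambda_max down to
        ``lambda_max * lambda_min_ratio``.
    rule : 'OR' keeps an edge if either nodewise coefficient is nonzero;
        'AND' requires both.
    reference_group : moderator level absorbed into the base network
        (default: the largest group).
    covariate_nodes : optional covariate columns (e.g. age, sex, site)
        entering every nodewise regression as main effects only.
    standardize_interactions : z-score interaction columns after forming
        the product, for penalty-scale comparability.
    aggregate : how multiply-imputed datasets combine — 'average'
        (element-wise mean of all selected parameters) or 'first'.
    """

    gamma: float = 0.5
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    rule: str = "OR"
    moderator_name: str = "group"
    reference_group: str | None = None
    covariate_nodes: tuple[str, ...] = ()
    standardize: bool = True
    standardize_interactions: bool = True
    aggregate: str = "average"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambdas < 2:
            raise ValueError("lambda path must have length >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.rule not in ("OR", "AND"):
            raise ValueError("rule must be 'OR' or 'AND'")
        if self.aggregate not in ("average", "first"):
            raise ValueError("aggregate must be 'average' or 'first'")


def lasso_path_fit(y: np.ndarray, X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Penalized least-squares coefficients along a decreasing lambda path.

    Solves min_b (1/2n)||y - Xb||^2 + lambda ||b||_1 by coordinate
    descent for each lambda. Requires standardized inputs: columns of X
    mean 0 and variance 1, y mean 0. Returns an array of shape
    ``(len(lambdas), n_features)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X)) and np.all(np.isfinite(lambdas))):
        raise ValueError("non-finite values in lasso inputs")
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambdas must be strictly decreasing")
    n = len(y)
    if abs(y.mean()) > 1e-6:
        raise ValueError("response must be centered")
    col_means = X.mean(axis=0)
    col_vars = X.var(axis=0)
    if np.any(np.abs(col_means) > 1e-6) or np.any(np.abs(col_vars - 1) > 1e-4):
        raise ValueError("design columns must be standardized (mean 0, variance 1)")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the 1e-10 duality-gap tolerance occasionally trips the solver's
        # iteration cap by a hair's width; accuracy is oracle-checked
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = _sk_lasso_path(X, y, alphas=lambdas, tol=1e-10, max_iter=100_000)
    return coefs.T  # (n_lambdas, p), ordered as the given decreasing path


def ebic_score(rss: float, n: int, k: int, P: int, gamma: float) -> float:
    """Extended BIC: n ln(rss/n) + k ln(n) + 2 gamma k ln(P).

    ``k`` counts nonzero coefficients and ``P`` the candidate predictors
    of the nodewise regression; gamma = 0 gives the standard BIC.
    """
    if rss <= 0:
        raise ValueError("rss must be > 0 (degenerate saturated fit)")
    if n <= 0 or k < 0 or P < max(k, 1):
        raise ValueError(f"invalid EBIC arguments n={n}, k={k}, P={P}")
    return n * np.log(rss / n) + k * np.log(n) + 2 * gamma * k * np.log(P)


def _reference_and_levels(
    groups: pd.Series, config: EstimatorConfig
) -> tuple[str, list[str]]:
    """Reference group (largest; lexicographic tie-break) and sorted others.

    The ordering is a function of the label multiset only, so fits are
    invariant to permuting participant order.
    """
    sizes = groups.value_counts()
    if config.reference_group is not None:
        reference = config.reference_group
        if reference not in sizes.index:
            raise ValueError(f"reference group {reference!r} not present in data")
    else:
        top = sizes[sizes == sizes.max()]
        reference = sorted(top.index)[0]
    nonref = sorted(g for g in sizes.index if g != reference)
    return reference, nonref


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"column {name!r} is constant")
    return (v - v.mean()) / sd


def build_moderated_design(
    items: pd.DataFrame | SymptomDataset,
    node: str,
    config: EstimatorConfig,
    groups: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple], list[str]]:
    """Response and standardized design matrix for one nodewise regression.

    Predictors are all items except ``node``, G-1 group dummies (reference
    omitted), item x dummy interaction products for every non-reference
    group, and optional covariate main effects. Returns
    ``(y, X, column_map, dropped)`` where ``column_map`` tags each column
    as ``('item', name)``, ``('dummy', group)``,
    ``('interaction', name, group)`` or ``('covariate', name)`` and
    ``dropped`` lists constant columns removed from the design.
    """
    if isinstance(items, SymptomDataset):
        groups = items.groups
        covariates = items.covariates
        items = items.items
    if groups is None:
        raise ValueError("group labels required")
    if node not in items.columns:
        raise ValueError(f"unknown node {node!r}")
    if items.isna().any().any():
        raise ValueError("design requires a completed (no-missing) dataset")

    sizes = groups.value_counts()
    small = [g for g in sizes.index if sizes[g] < 2]
    if small:
        raise ValueError(f"groups with < 2 participants: {small}")
    reference, nonref = _reference_and_levels(groups, config)

    y_raw = items[node].to_numpy(dtype=float)
    if y_raw.std() == 0:
        raise ValueError(f"item {node!r} is constant")
    y = _zscore(y_raw, node)

    others = [c for c in items.columns if c != node]
    cols: list[np.ndarray] = []
    colmap: list[tuple] = []
    dropped: list[str] = []
    z_items: dict[str, np.ndarray] = {}

    for it in others:
        v = items[it].to_numpy(dtype=float)
        if v.std() == 0:
            dropped.append(it)
            continue
        z = _zscore(v, it)
        z_items[it] = z
        cols.append(z)
        colmap.append(("item", it))
    for g in nonref:
        d = (groups == g).to_numpy(dtype=float)
        cols.append(_zscore(d, f"dummy[{g}]"))
        colmap.append(("dummy", g))
    for g in nonref:
        d = (groups == g).to_numpy(dtype=float)
        for it in others:
            if it not in z_items:
                continue
            prod = z_items[it] * d
            if prod.std() == 0:
                dropped.append(f"{it}:{g}")
                continue
            if config.standardize_interactions:
                prod = _zscore(prod, f"{it}:{g}")
            cols.append(prod)
            colmap.append(("interaction", it, g))
    for cv in config.covariate_nodes:
        if covariates is None or cv not in covariates.columns:
            raise ValueError(f"covariate {cv!r} not available")
        v = covariates[cv]
        if not np.issubdtype(v.dtype, np.number):
            levels = sorted(v.unique())
            if len(levels) < 2:
                dropped.append(cv)
                continue
            v = v.map({lv: k for k, lv in enumerate(levels)})
        v = v.to_numpy(dtype=float)
        if v.std() == 0:
            dropped.append(cv)
            continue
        cols.append(_zscore(v, cv))
        colmap.append(("covariate", cv))

    X = np.column_stack(cols)
    return y, X, colmap, dropped


def _fit_node(y: np.ndarray, X: np.ndarray, config: EstimatorConfig):
    """EBIC-selected LASSO fit for one nodewise regression."""
    n, P = X.shape
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max == 0:
        return np.zeros(P), 0.0, ebic_score(float((y**2).sum()), n, 0, P, config.gamma)
    lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)
    coefs = lasso_path_fit(y, X, lambdas)
    coefs[np.abs(coefs) < 1e-10] = 0.0  # solver round-off is not support
    resid = y[None, :] - coefs @ X.T
    rss = (resid**2).sum(axis=1)
    ks = (coefs != 0).sum(axis=1)
    # guard: never keep more coefficients than observations
    ok = ks < n
    scores = np.array(
        [
            ebic_score(max(r, 1e-12), n, int(k), P, config.gamma) if o else np.inf
            for r, k, o in zip(rss, ks, ok)
        ]
    )
    best = int(np.argmin(scores))  # ties resolve to the larger lambda
    return coefs[best], float(lambdas[best]), float(scores[best])


def _combine_pair(b_ij: float, b_ji: float, rule: str) -> tuple[float, bool]:
    """Aggregate the two nodewise coefficients of one undirected edge."""
    nz_i, nz_j = b_ij != 0, b_ji != 0
    present = (nz_i or nz_j) if rule == "OR" else (nz_i and nz_j)
    if not present:
        return 0.0, False
    if nz_i and nz_j and np.sign(b_ij) != np.sign(b_ji):
        return (b_ij + b_ji) / 2, True  # sign conflict: keep mean of signed values
    mag = (abs(b_ij) + abs(b_ji)) / 2
    sign = np.sign(b_ij) if nz_i else np.sign(b_ji)
    return float(sign * mag), False


@dataclass
class ModeratedMGM:
    """Fitted moderated network: shared base plus group-specific increments.

    ``conditioned[g]`` equals ``base_weights`` plus the moderation
    increments stored for group ``g``; the reference group's conditioned
    network is the base itself, and any two groups differ only on edges
    carrying a stored increment.
    """

    nodes: tuple[str, ...]
    groups: tuple[str, ...]
    reference_group: str
    base_weights: np.ndarray
    moderation: dict[tuple[str, str, str], float]
    selected_lambda: dict[str, float]
    ebic: dict[str, float]
    sign_conflicts: list[tuple] = field(default_factory=list)
    config: EstimatorConfig = field(default_factory=EstimatorConfig)

    @property
    def conditioned(self) -> dict[str, np.ndarray]:
        return {g: self.condition_on_group(g) for g in self.groups}

    def condition_on_group(self, group: str) -> np.ndarray:
        """Symmetric weight matrix of one moderator group's network."""
        if group not in self.groups:
            raise ValueError(f"unknown group {group!r}; model has {self.groups}")
        W = self.base_weights.copy()
        idx = {n: k for k, n in enumerate(self.nodes)}
        for (i, j, g), delta in self.moderation.items():
            if g == group:
                W[idx[i], idx[j]] += delta
                W[idx[j], idx[i]] += delta
        return W

    def moderation_keys(self) -> set[tuple[str, str, str]]:
        return set(self.moderation)

    def edge_list(self, group: str) -> pd.DataFrame:
        W = self.condition_on_group(group)
        rows = [
            {"node_i": self.nodes[i], "node_j": self.nodes[j], "weight": W[i, j]}
            for i in range(len(self.nodes))
            for j in range(i + 1, len(self.nodes))
            if W[i, j] != 0
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "nodes": list(self.nodes),
            "groups": list(self.groups),
            "reference_group": self.reference_group,
            "base_weights": self.base_weights.tolist(),
            "moderation": [
                {"node_i": i, "node_j": j, "group": g, "increment": v}
                for (i, j, g), v in sorted(self.moderation.items())
            ],
            "selected_lambda": self.selected_lambda,
            "ebic": self.ebic,
            "sign_conflicts": [list(c) for c in self.sign_conflicts],
            "config": asdict(self.config),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class ModeratedNetworkModel(BaseEstimator):
    """Group-moderated network estimator with a scikit-learn interface.

    ``fit(X, y)`` takes the completed item table ``X`` (DataFrame, one
    column per item, no missing values) and the moderator labels ``y``;
    the fitted network is exposed as ``model_`` with ``base_weights_``,
    ``moderation_`` and per-group ``conditioned_`` matrices. Covariate
    adjustment columns are passed via ``covariates`` at fit time and
    named in ``covariate_nodes``.
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 1e-4,
        rule: str = "OR",
        reference_group: str | None = None,
        covariate_nodes: tuple[str, ...] = (),
        standardize_interactions: bool = True,
        aggregate: str = "average",
    ):
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule
        self.reference_group = reference_group
        self.covariate_nodes = covariate_nodes
        self.standardize_interactions = standardize_interactions
        self.aggregate = aggregate

    def _config(self) -> EstimatorConfig:
        return EstimatorConfig(
            gamma=self.gamma,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            rule=self.rule,
            reference_group=self.reference_group,
            covariate_nodes=tuple(self.covariate_nodes),
            standardize_interactions=self.standardize_interactions,
            aggregate=self.aggregate,
        )

    def fit(
        self,
        X: pd.DataFrame,
        y,
        covariates: pd.DataFrame | None = None,
    ) -> "ModeratedNetworkModel":
        X = pd.DataFrame(X)
        groups = pd.Series(np.asarray(y), index=X.index, name="group")
        sizes = groups.value_counts()
        if len(sizes) < 2:
            raise ValueError("moderated model requires >= 2 groups")
        if sizes.min() < 10:
            raise ValueError(f"every group needs n >= 10; sizes: {sizes.to_dict()}")
        const = [c for c in X.columns if X[c].std() == 0]
        if const:
            raise ValueError(f"degenerate constant items: {const}")
        self.model_ = _fit_single(X, groups, covariates, self._config())
        self.nodes_ = self.model_.nodes
        self.base_weights_ = self.model_.base_weights
        self.moderation_ = self.model_.moderation
        self.conditioned_ = self.model_.conditioned
        return self

    def transform(self, group: str) -> np.ndarray:
        return self.model_.condition_on_group(group)


def _fit_single(
    items: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None,
    config: EstimatorConfig,
) -> ModeratedMGM:
    nodes = tuple(items.columns)
    reference, nonref = _reference_and_levels(groups, config)
    group_levels = (reference, *nonref)

    main = {}      # (response, predictor) -> coefficient
    inter = {}     # (response, predictor, group) -> coefficient
    sel_lambda, sel_ebic = {}, {}
    for s in nodes:
        y, X, colmap, _ = build_moderated_design(
            items, s, config, groups=groups, covariates=covariates
        )
        beta, lam, score = _fit_node(y, X, config)
        sel_lambda[s], sel_ebic[s] = lam, score
        for b, tag in zip(beta, colmap):
            if tag[0] == "item":
                main[(s, tag[1])] = float(b)
            elif tag[0] == "interaction":
                inter[(s, tag[1], tag[2])] = float(b)

    p = len(nodes)
    base = np.zeros((p, p))
    conflicts: list[tuple] = []
    moderation: dict[tuple[str, str, str], float] = {}
    for a in range(p):
        for b in range(a + 1, p):
            ni, nj = nodes[a], nodes[b]
            w, conflict = _combine_pair(
                main.get((ni, nj), 0.0), main.get((nj, ni), 0.0), config.rule
            )
            base[a, b] = base[b, a] = w
            if conflict:
                conflicts.append((ni, nj))
            for g in group_levels[1:]:
                d, dconf = _combine_pair(
                    inter.get((ni, nj, g), 0.0), inter.get((nj, ni, g), 0.0), config.rule
                )
                if d != 0.0:
                    moderation[(ni, nj, g)] = d
                if dconf:
                    conflicts.append((ni, nj, g))

    return ModeratedMGM(
        nodes=nodes,
        groups=group_levels,
        reference_group=reference,
        base_weights=base,
        moderation=moderation,
        selected_lambda=sel_lambda,
        ebic=sel_ebic,
        sign_conflicts=conflicts,
        config=config,
    )


def fit_moderated_mgm(
    completed_datasets: CompletedDatasets | SymptomDataset | list[SymptomDataset],
    config: EstimatorConfig | None = None,
) -> ModeratedMGM:
    """Fit the moderated network, pooling multiply-imputed copies.

    With m > 1 completed datasets the per-copy fits are combined
    according to ``config.aggregate``: 'average' takes the element-wise
    mean of base weights and moderation increments over all copies
    (unselected parameters count as zero), 'first' keeps the first
    copy's fit.
    """
    config = config or EstimatorConfig()
    if isinstance(completed_datasets, SymptomDataset):
        datasets = [completed_datasets]
    elif isinstance(completed_datasets, CompletedDatasets):
        datasets = list(completed_datasets)
    else:
        datasets = list(completed_datasets)
    if not datasets:
        raise ValueError("no completed datasets given")

    fits = []
    for ds in datasets:
        est = ModeratedNetworkModel(**_estimator_kwargs(config))
        est.fit(ds.items, ds.groups, covariates=ds.covariates)
        fits.append(est.model_)
        if config.aggregate == "first":
            break

    if len(fits) == 1:
        return fits[0]
    m = len(fits)
    base = sum(f.base_weights for f in fits) / m
    keys = set().union(*(f.moderation.keys() for f in fits))
    moderation = {k: sum(f.moderation.get(k, 0.0) for f in fits) / m for k in keys}
    first = fits[0]
    lam = {s: float(np.mean([f.selected_lambda[s] for f in fits])) for s in first.nodes}
    ebic = {s: float(np.mean([f.ebic[s] for f in fits])) for s in first.nodes}
    conflicts = sorted({c for f in fits for c in f.sign_conflicts})
    return ModeratedMGM(
        nodes=first.nodes,
        groups=first.groups,
        reference_group=first.reference_group,
        base_weights=base,
        moderation=moderation,
        selected_lambda=lam,
        ebic=ebic,
        sign_conflicts=conflicts,
        config=config,
    )


def _estimator_kwargs(config: EstimatorConfig) -> dict:
    return {
        "gamma": config.gamma,
        "n_lambdas": config.n_lambdas,
        "lambda_min_ratio": config.lambda_min_ratio,
        "rule": config.rule,
        "reference_group": config.reference_group,
        "covariate_nodes": config.covariate_nodes,
        "standardize_interactions": config.standardize_interactions,
        "aggregate": config.aggregate,
    }


def condition_on_group(model: ModeratedMGM, group: str) -> np.ndarray:
    """Weight matrix of ``group``'s network (base plus its increments)."""
    return model.condition_on_group(group)
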