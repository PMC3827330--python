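"""Path analysis with backwards elimination over a declared causal order.

Each variable, taken in causal (temporal) order, is regressed on every
variable that precedes it; predictors are removed one at a time — always
the one with the largest p-value at or above the significance threshold —
and the model refitted, until all survivors are significant.  Standardized
betas on the retained edges form a directed acyclic "backbone" graph that
can be exported as DOT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PathEdge",
    "PathModel",
    "ols_standardized",
    "backwards_eliminate",
    "fit_backbone",
    "export_dot",
]


@dataclass(frozen=True)
class PathEdge:
    source: str
    target: str
    beta: float
    p: float
    retained: bool = True


@dataclass
class PathModel:
    """Ordered variables plus the retained directed edges."""

    order: list[str]
    edges: list[PathEdge] = field(default_factory=list)
    n_per_target: dict[str, int] = field(default_factory=dict)
    threshold: float = 0.05
    removal_log: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rank = {v: i for i, v in enumerate(self.order)}
        for e in self.edges:
            if rank[e.source] >= rank[e.target]:
                raise ValueError(f"edge {e.source}->{e.target} violates the causal order")
            if e.retained and e.p >= self.threshold:
                raise ValueError(f"retained edge {e.source}->{e.target} not significant")

    def edges_into(self, target: str) -> list[PathEdge]:
        return [e for e in self.edges if e.target == target and e.retained]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "beta": e.beta,
                "p": e.p,
                "n": self.n_per_target.get(e.target, np.nan),
            }
            for e in self.edges
            if e.retained
        ]
        return pd.DataFrame(rows, columns=["source", "target", "beta", "p", "n"])


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def ols_standardized(y, X: pd.DataFrame) -> tuple[pd.Series, pd.Series, int]:
    """Standardized OLS coefficients with two-sided t-test p-values.

    Both the outcome and the predictors are z-scored on the complete cases,
    so the coefficients are path (beta) weights.  Returns (betas, p-values,
    n complete cases).
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    data = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n, k = data.shape[0], X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} complete cases, have {n}")
    Xm = data[X.columns].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm - Xm.mean(axis=0)) < k:
        # name the offending columns for the caller
        corr = np.corrcoef(Xm, rowvar=False)
        bad = [
            f"{X.columns[i]}~{X.columns[j]}"
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear predictors: {bad or list(X.columns)}")
    ys = _standardize(data["__y__"].to_numpy()[:, None]).ravel()
    Xs = _standardize(Xm)
    fit = sm.OLS(ys, sm.add_constant(Xs)).fit()
    betas = pd.Series(fit.params[1:], index=X.columns)
    pvals = pd.Series(fit.pvalues[1:], index=X.columns)
    return betas, pvals, n


def backwards_eliminate(
    y, X: pd.DataFrame, threshold: float = 0.05
) -> tuple[pd.Series, pd.Series, int, list[str]]:
    """Backwards elimination: drop the least significant predictor until
    every survivor has p below the threshold.

    One predictor is removed per step (the largest p at or above the
    threshold; ties broken by removing the later column first); removed
    predictors never re-enter.  An empty survivor set is a valid outcome.
    Returns (betas, p-values, n, removal order).
    """
    X = pd.DataFrame(X).copy()
    removed: list[str] = []
    while len(X.columns):
        betas, pvals, n = ols_standardized(y, X)
        worst_p = pvals.max()
        if worst_p < threshold:
            return betas, pvals, n, removed
        # ties: remove the later-ordered (rightmost) column first
        candidates = pvals[pvals == worst_p].index
        drop = candidates[-1]
        removed.append(drop)
        X = X.drop(columns=[drop])
    # everything eliminated: report n on y's non-missing values
    n = int(pd.Series(np.asarray(y, dtype=float)).notna().sum())
    return pd.Series(dtype=float), pd.Series(dtype=float), n, removed


def fit_backbone(
    table: pd.DataFrame,
    order: list[str] | None = None,
    threshold: float = 0.05,
    covariates: list[str] | None = None,
) -> PathModel:
    """Fit the full ordered path model over a cohort table.

    Each variable from the second onward is regressed on all causally prior
    variables (plus any covariates) with backwards elimination at the given
    threshold.  Variables with no non-missing values are skipped with a
    warning.  The first-ordered variable has no incoming edges.
    """
    if order is None:
        order = list(table.columns)
    if len(order) < 2:
        raise ValueError("need at least 2 ordered variables")
    missing_cols = [v for v in order if v not in table.columns]
    if missing_cols:
        raise ValueError(f"variables not in table: {missing_cols}")
    covariates = covariates or []

    usable = []
    for v in order:
        if table[v].notna().sum() == 0:
            warnings.warn(f"variable {v!r} has no observed values; skipped", stacklevel=2)
        else:
            usable.append(v)

    model = PathModel(order=usable, threshold=threshold)
    for i, target in enumerate(usable[1:], start=1):
        priors = usable[:i] + [c for c in covariates if c not in usable[:i] and c != target]
        betas, pvals, n, removed = backwards_eliminate(
            table[target], table[priors], threshold
        )
        model.n_per_target[target] = n
        model.removal_log[target] = removed
        for src in betas.index:
            model.edges.append(
                PathEdge(src, target, float(betas[src]), float(pvals[src]), True)
            )
    # re-validate edges against ordering/threshold
    PathModel(
        order=model.order, edges=model.edges, n_per_target=model.n_per_target,
        threshold=model.threshold, removal_log=model.removal_log,
    )
    return model


_STAGE_COLORS = {
    "pre": "#c6dbef",       # pre-medical-school attainment
    "medical": "#a1d99b",   # medical-school assessments
    "postgraduate": "#fdae6b",
}


def export_dot(
    model: PathModel,
    stages: dict[str, str] | None = None,
    base_penwidth: float = 6.0,
) -> str:
    """Render the path model as left-to-right DOT text.

    Edge pen-width is ``base_penwidth * |beta|``, so arrow thickness is
    proportional to effect size.  ``stages`` maps variable name to one of
    ``pre`` / ``medical`` / ``postgraduate`` for the three fill colours.
    """
    stages = stages or {}
    lines = [
        "digraph backbone {",
        "  rankdir=LR;",
        '  node [shape=box, style="rounded,filled", fillcolor="#eeeeee"];',
    ]
    for v in model.order:
        color = _STAGE_COLORS.get(stages.get(v, ""), "#eeeeee")
        lines.append(f'  "{v}" [fillcolor="{color}"];')
    for e in model.edges:
        if not e.retained:
            continue
        pw = base_penwidth * abs(e.beta)
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[penwidth={pw:.3f}, label="{e.beta:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
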