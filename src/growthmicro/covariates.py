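"""Co-factor analyses: diet pruning, scalar regressions, best subsets,
and joint functional regressions of growth curves on microbiota plus diet.

Scalar regressions are ordinary least squares (statsmodels); best-subset
selection exhaustively enumerates all covariate subsets (p <= 20) and picks
the argmin of an information criterion (BIC by default).  Categorical
covariates enter via reference-level dummy coding with the first declared
level as reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidArgumentError, JoinError, SingularDesignError
from .fosr import FoSRFit, fit_fosr

log = logging.getLogger(__name__)

# declared order matters for the greedy correlation pruning: base categories
# (dairy, vegetables) precede their derived near-duplicates so the latter are
# the ones eliminated
DIET_COLUMNS = [
    "sugar_sweetened_beverages", "dairy", "milk", "fruit", "vegetables",
    "vegetables_no_potato", "snacks", "sweets", "meats", "fried_foods",
]
FACTOR_COLUMNS = [
    "sex", "antibiotics", "acid_reducers", "delivery_mode", "intervention",
    "gestational_diabetes", "gestational_weight_gain", "smoking", "income",
]


@dataclass
class CovariateTable:
    """Per-child covariates: categorical/binary factors plus weekly diet frequencies."""

    frame: pd.DataFrame                    # index: child_id
    factor_columns: list[str] = field(default_factory=lambda: list(FACTOR_COLUMNS))
    diet_columns: list[str] = field(default_factory=lambda: list(DIET_COLUMNS))

    def __post_init__(self):
        missing = [c for c in self.factor_columns + self.diet_columns
                   if c not in self.frame.columns]
        if missing:
            raise InvalidArgumentError(f"covariate table missing columns {missing}")
        diet = self.frame[self.diet_columns]
        if (diet.to_numpy() < 0).any():
            raise InvalidArgumentError("diet frequencies must be non-negative")

    @property
    def diet(self) -> pd.DataFrame:
        return self.frame[self.diet_columns]

    def dummies(self, columns=None) -> pd.DataFrame:
        """Reference-coded dummies for factors plus numeric diet columns."""
        columns = columns if columns is not None else (
            self.factor_columns + self.diet_columns)
        parts = []
        for col in columns:
            s = self.frame[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
                parts.append(d)
            else:
                parts.append(s.astype(float).to_frame(col))
        return pd.concat(parts, axis=1)

    def write(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "child_id"
        out.to_csv(path)

    @classmethod
    def read(cls, path, **kw) -> "CovariateTable":
        return cls(pd.read_csv(path, index_col=0), **kw)


@dataclass
class PruneResult:
    retained: list[str]
    dropped: list[tuple[str, str, float]]   # (dropped, kept, |r|)


def prune_correlated(diet_table: pd.DataFrame, cutoff: float = 0.7) -> PruneResult:
    """Greedy scan in declared column order; drop columns with |r| > cutoff
    against an already-retained column.  Constant columns (undefined
    correlation) are retained and logged."""
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in diet_table.columns:
        x = diet_table[col].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            log.warning("prune_correlated: column %r is constant; retained", col)
            retained.append(col)
            continue
        hit = None
        for kept in retained:
            y = diet_table[kept].to_numpy(dtype=float)
            if np.std(y) == 0.0:
                continue
            r = abs(float(np.corrcoef(x, y)[0, 1]))
            if r > cutoff:
                hit = (col, kept, r)
                break
        if hit is None:
            retained.append(col)
        else:
            dropped.append(hit)
    return PruneResult(retained=retained, dropped=dropped)


@dataclass
class RegressionSummary:
    response: str
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    f_pvalue: float
    rsquared_adj: float
    rsquared: float
    nobs: int

    def to_text(self) -> str:
        lines = [f"response: {self.response}  (n = {self.nobs})",
                 f"overall F p-value: {self.f_pvalue:.4g}   "
                 f"adjusted R^2: {self.rsquared_adj:.4f}",
                 f"{'term':<28}{'coef':>12}{'t':>10}{'p':>12}"]
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>12.4g}"
                         f"{self.tvalues[name]:>10.2f}{self.pvalues[name]:>12.3g}")
        return "\n".join(lines)


def multi_regression(response, predictors: pd.DataFrame,
                     response_name: str = "y") -> RegressionSummary:
    """OLS with per-coefficient t tests, overall F p-value and adjusted R^2."""
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidArgumentError(f"need n > p + 1 (n={n}, p={p})")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise SingularDesignError("regression design is rank deficient",
                                  columns=list(X.columns))
    fit = sm.OLS(y, Xc).fit()
    return RegressionSummary(
        response=response_name, params=fit.params, tvalues=fit.tvalues,
        pvalues=fit.pvalues, f_pvalue=float(fit.f_pvalue),
        rsquared_adj=float(fit.rsquared_adj), rsquared=float(fit.rsquared),
        nobs=int(fit.nobs),
    )


@dataclass
class SubsetSelectionResult:
    response: str
    selected: tuple[str, ...]
    criterion: str
    criterion_value: float
    n_subsets: int
    fit: RegressionSummary
    path: pd.DataFrame = field(repr=False, default=None)  # best value per size


def _criterion_value(rss: float, n: int, k: int, criterion: str) -> float:
    # Gaussian log-likelihood based criteria; k counts the intercept too
    ll_term = n * np.log(max(rss, 1e-300) / n)
    pen = k * (np.log(n) if criterion == "BIC" else 2.0)
    return float(ll_term + pen)


def best_subset(response, covariates: pd.DataFrame, criterion: str = "BIC",
                response_name: str = "y") -> SubsetSelectionResult:
    """Exhaustive best-subset OLS over all 2^p covariate subsets.

    The intercept is always included; the selected subset minimizes the
    criterion; the restricted model is refit and summarized.
    """
    if criterion not in ("BIC", "AIC"):
        raise InvalidArgumentError(f"criterion must be BIC or AIC, got {criterion!r}")
    y = np.asarray(response, dtype=float)
    X = covariates.astype(float)
    n, p = X.shape
    if p > 20:
        raise InvalidArgumentError(
            f"{p} covariates: exhaustive enumeration capped at 20; pre-screen first"
        )
    cols = list(X.columns)
    Xfull = np.column_stack([np.ones(n), X.to_numpy()])
    G = Xfull.T @ Xfull
    b = Xfull.T @ y
    yy = float(y @ y)

    best = (np.inf, ())
    by_size: dict[int, float] = {}
    n_subsets = 0
    for size in range(p + 1):
        for combo in itertools.combinations(range(p), size):
            n_subsets += 1
            idx = np.concatenate([[0], np.asarray(combo, dtype=int) + 1])
            Gs = G[np.ix_(idx, idx)]
            bs = b[idx]
            try:
                beta = np.linalg.solve(Gs, bs)
            except np.linalg.LinAlgError:
                continue
            rss = yy - bs @ beta
            val = _criterion_value(rss, n, idx.size, criterion)
            by_size[size] = min(by_size.get(size, np.inf), val)
            if val < best[0]:
                best = (val, combo)
    sel = tuple(cols[j] for j in best[1])
    refit = multi_regression(y, X[list(sel)] if sel else X.iloc[:, :0],
                             response_name=response_name) if sel else \
        _intercept_only_summary(y, response_name)
    path = pd.DataFrame({"size": sorted(by_size),
                         criterion: [by_size[s] for s in sorted(by_size)]})
    return SubsetSelectionResult(response=response_name, selected=sel,
                                 criterion=criterion, criterion_value=best[0],
                                 n_subsets=n_subsets, fit=refit, path=path)


def _intercept_only_summary(y: np.ndarray, response_name: str) -> RegressionSummary:
    n = y.size
    mean = float(np.mean(y))
    se = float(np.std(y, ddof=1) / np.sqrt(n))
    t = mean / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return RegressionSummary(
        response=response_name,
        params=pd.Series({"const": mean}), tvalues=pd.Series({"const": t}),
        pvalues=pd.Series({"const": p}), f_pvalue=np.nan,
        rsquared_adj=0.0, rsquared=0.0, nobs=n,
    )


def kruskal_by_factor(values, factor) -> float:
    """Kruskal-Wallis p-value of ``values`` across the levels of ``factor``
    (chi-squared approximation); for >2-level categorical co-factors."""
    values = np.asarray(values, dtype=float)
    factor = np.asarray(factor)
    groups = [values[factor == lvl] for lvl in pd.unique(factor)]
    groups = [g[np.isfinite(g)] for g in groups if np.isfinite(g).sum() >= 2]
    if len(groups) < 2:
        raise InvalidArgumentError("need at least two groups with >= 2 values")
    return float(stats.kruskal(*groups).pvalue)


def joint_fosr(curves, microbiota_summary, selected_diet: pd.DataFrame,
               **fosr_kwargs) -> FoSRFit:
    """Functional regression of curves on a microbiota summary plus diet.

    ``microbiota_summary`` is a named Series and ``selected_diet`` a
    DataFrame, both indexed by child id and matching the curve set's ids;
    id mismatches raise a join error listing the orphans.
    """
    from .curves import CurveSet

    if isinstance(curves, CurveSet):
        ids = pd.Index(curves.child_ids)
    elif isinstance(curves, pd.DataFrame):
        ids = curves.index
    else:
        raise InvalidArgumentError("joint_fosr needs a CurveSet or DataFrame of curves")
    if isinstance(microbiota_summary, pd.Series):
        microbiota_summary = microbiota_summary.to_frame()
    orphans: set = set()
    for part in (microbiota_summary, selected_diet):
        orphans |= set(ids.symmetric_difference(part.index))
    if orphans:
        raise JoinError(f"curves and predictors disagree on {len(orphans)} ids",
                        orphans=sorted(orphans))
    design = pd.concat([microbiota_summary, selected_diet], axis=1).loc[ids]
    # an all-zero covariate carries no information but would make the
    # normal equations singular; drop it with a log entry
    zero = [c for c in design.columns if (design[c] == 0).all()]
    if zero:
        log.warning("joint_fosr: dropping all-zero columns %s", zero)
        design = design.drop(columns=zero)
    return fit_fosr(curves, design, **fosr_kwargs)
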