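"""Random-intercept linear mixed models with estimated marginal means and
Tukey contrasts.

The model is

    y = X beta + Z b + e,    b ~ N(0, sigma_b^2 I),  e ~ N(0, sigma^2 I),

with Z the indicator matrix of a single grouping factor (individual ID).
Estimation is REML, profiled over the variance ratio lambda =
sigma_b^2 / sigma^2: for fixed lambda the GLS solution and the profiled
residual variance are closed-form, so the REML criterion

    (n - p) log(r' V^-1 r) + log|V| + log|X' V^-1 X|,   V = I + lambda Z Z',

is minimised over a single scalar. V^-1 is applied groupwise via the
Woodbury identity, so no n x n matrix is ever formed. Denominator degrees
of freedom for contrasts use the Satterthwaite approximation (delta method
on the REML information of the variance components), with a residual-df
fallback when the information matrix is singular (e.g. at the lambda = 0
boundary).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import studentized_range, t as t_dist

__all__ = [
    "ModelSpec",
    "LMMFit",
    "EMMResult",
    "EMMContrast",
    "DesignError",
    "GroupingError",
    "fit_lmm",
    "estimated_marginal_means",
    "tukey_contrasts",
]


class DesignError(ValueError):
    """Rank-deficient or otherwise invalid fixed-effects design."""


class GroupingError(ValueError):
    """Invalid random-effect grouping (e.g. a single individual)."""


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    Parameters
    ----------
    response
        Name of the response column.
    group
        Name of the random-intercept grouping column.
    numeric
        Names of continuous covariates, entered untransformed.
    factors
        Mapping of factor name to its ordered level list; the first level is
        the treatment-coding reference. ``None`` levels are inferred (sorted
        unique values, first as reference).
    interactions
        Pairs of factor names whose interaction enters the model.
    log_response
        Natural-log transform the response before fitting.
    """

    response: str
    group: str
    numeric: list[str] = field(default_factory=list)
    factors: dict[str, list[str] | None] = field(default_factory=dict)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    log_response: bool = False


def _resolve_levels(df: pd.DataFrame, spec: ModelSpec) -> dict[str, list[str]]:
    levels = {}
    for fac, lv in spec.factors.items():
        observed = [str(v) for v in pd.unique(df[fac].astype(str))]
        if lv is None:
            levels[fac] = sorted(set(observed))
        else:
            lv = [str(x) for x in lv]
            extra = set(observed) - set(lv)
            if extra:
                raise DesignError(f"factor {fac}: unexpected level(s) {sorted(extra)}")
            levels[fac] = [l for l in lv if l in set(observed)] or lv
    return levels


def _design_columns(
    df: pd.DataFrame, spec: ModelSpec, levels: dict[str, list[str]]
) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for num in spec.numeric:
        cols.append(df[num].to_numpy(dtype=float))
        names.append(num)
    ind = {}
    for fac, lv in levels.items():
        vals = df[fac].astype(str).to_numpy()
        for l in lv:
            ind[(fac, l)] = (vals == l).astype(float)
        for l in lv[1:]:
            cols.append(ind[(fac, l)])
            names.append(f"{fac}[{l}]")
    for f1, f2 in spec.interactions:
        for l1 in levels[f1][1:]:
            for l2 in levels[f2][1:]:
                cols.append(ind[(f1, l1)] * ind[(f2, l2)])
                names.append(f"{f1}[{l1}]:{f2}[{l2}]")
    return np.column_stack(cols), names


def _drop_and_check(X: np.ndarray, names: list[str]):
    """Drop all-zero columns (unpopulated cells) and verify full rank."""
    nz = ~np.all(X == 0, axis=0)
    dropped = [n for n, keep in zip(names, nz) if not keep]
    if dropped:
        warnings.warn(
            f"dropping empty design column(s): {dropped}", UserWarning, stacklevel=3
        )
    X = X[:, nz]
    names = [n for n, keep in zip(names, nz) if keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(len(names)) if i >= rank or diag[i] < tol]
        raise DesignError(f"rank-deficient design; aliased term(s): {sorted(set(aliased))}")
    return X, names


@dataclass
class LMMFit:
    """Fitted random-intercept mixed model."""

    spec: ModelSpec
    params: pd.Series
    cov_beta: np.ndarray
    sigma2: float
    sigma2_group: float
    lam: float
    n: int
    n_groups: int
    rank: int
    levels: dict[str, list[str]]
    numeric_means: dict[str, float]
    observed_pairs: dict[tuple[str, str], set[tuple[str, str]]]
    X: np.ndarray
    y: np.ndarray
    group_index: list[np.ndarray]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.params.index)

    @property
    def resid_df(self) -> float:
        """Fallback denominator df: n - rank - N_groups + 1 (at least 1)."""
        return float(max(1, self.n - self.rank - self.n_groups + 1))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params.to_numpy()

    def fitted(self) -> np.ndarray:
        return self.predict(self.X)

    def back_transform(self, value):
        """Return predictions on the response's original scale."""
        return np.exp(value) if self.spec.log_response else value


def _profiled_quantities(X, y, group_index, group_sizes, lam):
    """GLS quantities for V = I + lam * Z Z' applied via Woodbury per group."""

    def vinv(M):
        out = M.astype(float).copy()
        for rows, ni in zip(group_index, group_sizes):
            shrink = lam / (1.0 + lam * ni)
            out[rows] -= shrink * M[rows].sum(axis=0)
        return out

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    A = X.T @ ViX
    u = X.T @ Viy
    beta = np.linalg.solve(A, u)
    r = y - X @ beta
    q = float(r @ vinv(r[:, None])[:, 0])
    logdet_v = float(np.sum(np.log1p(lam * np.asarray(group_sizes))))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise DesignError("X'V^-1X not positive definite")
    return A, beta, q, logdet_v, logdet_a


def _reml_criterion(X, y, group_index, group_sizes, lam):
    n, p = X.shape
    _, _, q, logdet_v, logdet_a = _profiled_quantities(
        X, y, group_index, group_sizes, lam
    )
    return (n - p) * math.log(q) + logdet_v + logdet_a


def fit_lmm(df: pd.DataFrame, spec: ModelSpec) -> LMMFit:
    """Fit a single-random-intercept LMM by profiled REML.

    When the estimated random-intercept variance is zero the fixed effects
    coincide with the ordinary least-squares solution (singular fits are
    reported, not errors).
    """
    cols = [spec.response, spec.group] + spec.numeric + list(spec.factors)
    data = df.dropna(subset=[c for c in cols if c in df.columns]).copy()
    if data.empty:
        raise ValueError("no complete rows for the requested model")
    y = data[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y <= 0):
            bad = list(np.flatnonzero(y <= 0))
            raise ValueError(f"non-positive response for log transform at row(s) {bad}")
        y = np.log(y)

    levels = _resolve_levels(data, spec)
    X, names = _design_columns(data, spec, levels)
    X, names = _drop_and_check(X, names)
    n, p = X.shape

    codes, uniques = pd.factorize(data[spec.group].astype(str).to_numpy())
    n_groups = len(uniques)
    if n_groups < 2:
        raise GroupingError("need at least 2 individuals for a random intercept")
    group_index = [np.flatnonzero(codes == g) for g in range(n_groups)]
    group_sizes = [len(ix) for ix in group_index]

    # perfect-fit guard: with zero residual the REML criterion is degenerate
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    if rss_ols <= 1e-18 * max(1.0, float(y @ y)):
        A = X.T @ X
        sigma2 = rss_ols / (n - p)
        return LMMFit(
            spec=spec,
            params=pd.Series(beta_ols, index=names),
            cov_beta=sigma2 * np.linalg.inv(A),
            sigma2=float(sigma2),
            sigma2_group=0.0,
            lam=0.0,
            n=n,
            n_groups=n_groups,
            rank=p,
            levels=levels,
            numeric_means={
                num: float(data[num].astype(float).mean()) for num in spec.numeric
            },
            observed_pairs={
                (f1, f2): set(zip(data[f1].astype(str), data[f2].astype(str)))
                for f1, f2 in spec.interactions
            },
            X=X,
            y=y,
            group_index=group_index,
        )

    crit = lambda lam: _reml_criterion(X, y, group_index, group_sizes, lam)

    # coarse log-grid bracket, then scalar refinement
    grid = np.concatenate([[0.0], np.logspace(-8, 6, 57)])
    values = np.array([crit(l) for l in grid])
    k = int(np.argmin(values))
    if k == 0:
        lam_hat = 0.0
    else:
        lo = grid[max(k - 1, 1)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda u: crit(math.exp(u)),
            bounds=(math.log(lo), math.log(max(hi, lo * 1.0001))),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat = float(math.exp(res.x))
        if crit(0.0) <= crit(lam_hat) + 1e-9:
            # flat or boundary criterion: prefer the OLS limit
            lam_hat = 0.0

    A, beta, q, _, _ = _profiled_quantities(X, y, group_index, group_sizes, lam_hat)
    sigma2 = q / (n - p)
    cov_beta = sigma2 * np.linalg.inv(A)

    obs_pairs = {}
    for f1, f2 in spec.interactions:
        obs_pairs[(f1, f2)] = set(
            zip(data[f1].astype(str), data[f2].astype(str))
        )

    return LMMFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        sigma2_group=float(lam_hat * sigma2),
        lam=lam_hat,
        n=n,
        n_groups=n_groups,
        rank=p,
        levels=levels,
        numeric_means={
            num: float(data[num].astype(float).mean()) for num in spec.numeric
        },
        observed_pairs=obs_pairs,
        X=X,
        y=y,
        group_index=group_index,
    )


# ---------------------------------------------------------------------------
# Satterthwaite denominator degrees of freedom


def _m2ll_and_covc(fit: LMMFit, theta, c):
    """-2 REML log-likelihood at theta=(sigma_b^2, sigma^2), and c'Cov(beta)c."""
    sb2, s2 = theta
    lam = sb2 / s2
    group_sizes = [len(ix) for ix in fit.group_index]
    A, _, q, logdet_v_lam, logdet_a_lam = _profiled_quantities(
        fit.X, fit.y, fit.group_index, group_sizes, lam
    )
    n, p = fit.X.shape
    m2ll = (
        n * math.log(s2)
        + logdet_v_lam
        + (logdet_a_lam - p * math.log(s2))
        + q / s2
    )
    covc = float(s2 * (c @ np.linalg.solve(A, c)))
    return m2ll, covc


def satterthwaite_df(fit: LMMFit, c: np.ndarray) -> float:
    """Approximate denominator df for the contrast c'beta.

    Delta method: df = 2 f^2 / (g' Cov(theta) g) with f = c'Cov(beta)c,
    g its gradient in the variance components and Cov(theta) the inverse
    observed REML information. Falls back to the residual df when the
    information matrix is singular (e.g. zero random-intercept variance).
    """
    c = np.asarray(c, dtype=float)
    if fit.lam <= 0 or fit.sigma2_group <= 0:
        return fit.resid_df
    theta = np.array([fit.sigma2_group, fit.sigma2])
    h = 1e-4 * theta

    def f(th):
        return _m2ll_and_covc(fit, th, c)

    try:
        # gradient of c'Cov(beta)c
        g = np.empty(2)
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            g[j] = (f(tp)[1] - f(tm)[1]) / (2 * h[j])
        # Hessian of -2 log-likelihood (central differences)
        def shifted(d0, d1):
            th = theta.copy()
            th[0] += d0
            th[1] += d1
            return f(th)[0]

        f0 = f(theta)[0]
        H = np.empty((2, 2))
        H[0, 0] = (shifted(h[0], 0) - 2 * f0 + shifted(-h[0], 0)) / h[0] ** 2
        H[1, 1] = (shifted(0, h[1]) - 2 * f0 + shifted(0, -h[1])) / h[1] ** 2
        H[0, 1] = H[1, 0] = (
            shifted(h[0], h[1])
            - shifted(h[0], -h[1])
            - shifted(-h[0], h[1])
            + shifted(-h[0], -h[1])
        ) / (4 * h[0] * h[1])
        cov_theta = 2.0 * np.linalg.inv(H)
        denom = float(g @ cov_theta @ g)
        fval = f(theta)[1]
        if denom <= 0 or not np.isfinite(denom):
            return fit.resid_df
        df = 2.0 * fval**2 / denom
    except np.linalg.LinAlgError:
        warnings.warn("Satterthwaite information singular; using residual df")
        return fit.resid_df
    if not np.isfinite(df) or df < 1:
        return fit.resid_df
    return float(min(df, fit.n - fit.rank))


# ---------------------------------------------------------------------------
# Estimated marginal means and Tukey contrasts


@dataclass
class EMMResult:
    """Estimated marginal means over a reference grid.

    ``table`` has one row per requested level combination with columns
    for the factor levels plus emmean, se, df; ``L`` holds the averaging
    vectors (rows) applied to the coefficient vector.
    """

    factors: list[str]
    table: pd.DataFrame
    L: np.ndarray
    fit: LMMFit


def _grid_design_row(fit: LMMFit, assignment: dict[str, str]) -> np.ndarray:
    spec, levels = fit.spec, fit.levels
    row = {"(Intercept)": 1.0}
    for num in spec.numeric:
        row[num] = fit.numeric_means[num]
    for fac, lv in levels.items():
        for l in lv[1:]:
            row[f"{fac}[{l}]"] = 1.0 if assignment[fac] == l else 0.0
    for f1, f2 in spec.interactions:
        for l1 in levels[f1][1:]:
            for l2 in levels[f2][1:]:
                row[f"{f1}[{l1}]:{f2}[{l2}]"] = (
                    1.0 if (assignment[f1] == l1 and assignment[f2] == l2) else 0.0
                )
    return np.array([row.get(name, 0.0) for name in fit.params.index])


def estimated_marginal_means(fit: LMMFit, factors: list[str]) -> EMMResult:
    """Model-based means for the levels of ``factors``.

    Predictions are averaged uniformly over a reference grid spanning every
    factor in the model, with continuous covariates fixed at their observed
    means. Grid cells corresponding to unobserved level combinations of an
    interacting factor pair are dropped with a warning (they would
    extrapolate outside the data).
    """
    unknown = [f for f in factors if f not in fit.levels]
    if unknown:
        raise ValueError(f"factor(s) not in model: {unknown}")
    all_factors = list(fit.levels)
    grid = [
        dict(zip(all_factors, combo))
        for combo in itertools.product(*(fit.levels[f] for f in all_factors))
    ]
    kept = []
    for cell in grid:
        ok = True
        for (f1, f2), pairs in fit.observed_pairs.items():
            if (cell[f1], cell[f2]) not in pairs:
                ok = False
        kept.append(ok)
    if not all(kept):
        n_drop = kept.count(False)
        warnings.warn(
            f"dropping {n_drop} unobserved interaction cell(s) from the EMM grid",
            UserWarning,
        )
    grid = [c for c, k in zip(grid, kept) if k]
    if not grid:
        raise ValueError("no populated reference-grid cells")

    combos = sorted(
        set(tuple(cell[f] for f in factors) for cell in grid),
        key=lambda c: tuple(fit.levels[f].index(l) for f, l in zip(factors, c)),
    )
    rows, L_rows = [], []
    for combo in combos:
        members = [
            c for c in grid if tuple(c[f] for f in factors) == combo
        ]
        L = np.mean([_grid_design_row(fit, c) for c in members], axis=0)
        est = float(L @ fit.params.to_numpy())
        se = float(math.sqrt(L @ fit.cov_beta @ L))
        df = satterthwaite_df(fit, L)
        rows.append(dict(zip(factors, combo)) | {"emmean": est, "se": se, "df": df})
        L_rows.append(L)
    return EMMResult(
        factors=list(factors),
        table=pd.DataFrame(rows),
        L=np.vstack(L_rows),
        fit=fit,
    )


@dataclass(frozen=True)
class EMMContrast:
    """One Tukey-adjusted pairwise difference of estimated marginal means."""

    level_a: tuple
    level_b: tuple
    estimate: float
    se: float
    df: float
    t: float
    p_tukey: float
    p_unadjusted: float


def tukey_contrasts(emms: EMMResult) -> list[EMMContrast]:
    """All pairwise EMM differences with studentized-range (Tukey) p-values.

    With k means and denominator df nu, the adjusted p-value of an observed
    |t| is P(Q_{k,nu} >= sqrt(2)|t|); at k = 2 this equals the unadjusted
    two-sided t-test p-value.
    """
    k = len(emms.table)
    if k < 2:
        raise ValueError("need at least 2 levels for contrasts")
    fit = emms.fit
    out = []
    labels = [tuple(r) for r in emms.table[emms.factors].to_numpy()]
    for i, j in itertools.combinations(range(k), 2):
        L = emms.L[i] - emms.L[j]
        est = float(L @ fit.params.to_numpy())
        se = float(math.sqrt(L @ fit.cov_beta @ L))
        df = satterthwaite_df(fit, L)
        tval = est / se if se > 0 else math.inf
        p_un = float(2 * t_dist.sf(abs(tval), df))
        p_tk = float(studentized_range.sf(abs(tval) * math.sqrt(2.0), k, df))
        p_tk = min(1.0, max(p_tk, p_un if k > 1 else 0.0))
        out.append(
            EMMContrast(
                level_a=labels[i],
                level_b=labels[j],
                estimate=est,
                se=se,
                df=df,
                t=tval,
                p_tukey=p_tk,
                p_unadjusted=min(1.0, p_un),
            )
        )
    return out
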