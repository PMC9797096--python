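"""Random-intercept linear mixed model with REML, Type-III ANOVA and
estimated-marginal-mean contrasts.

The model is y = X beta + Z b + e with a single random intercept per group
(b ~ N(0, tau2), e ~ N(0, sigma2)).  The variance ratio lambda = tau2/sigma2
is profiled out of the REML criterion and optimised as a scalar; fixed
effects follow by GLS.  Factors are coded sum-to-zero so that the marginal
(Type-III) hypothesis for each term is simply that its coefficient block is
zero.  Denominator degrees of freedom use the Satterthwaite approximation,
with the variance-parameter covariance taken from a finite-difference
Hessian of the REML criterion; contrast z-ratios use the asymptotic normal
reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

REML_TOL = 1e-10
LAMBDA_MAX = 1e7
BOUNDARY_TAU2 = 1e-8


# ---------------------------------------------------------------------------
# Design construction (categorical factors, sum-to-zero coding)

@dataclass
class DesignInfo:
    terms: "list[str]"
    term_slices: "dict[str, slice]"
    column_names: "list[str]"
    factor_levels: "dict[str, list[str]]"


def _sum_code(values: pd.Series, levels: "list[str]") -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level = -1 row."""
    k = len(levels)
    idx = pd.Categorical(values, categories=levels).codes
    if (idx < 0).any():
        raise ValueError(f"values outside declared levels for {values.name}")
    out = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        out[idx == j, j] = 1.0
    out[idx == k - 1, :] = -1.0
    return out


def build_design(df: pd.DataFrame, fixed_terms: "list[str]"):
    """Design matrix with intercept plus sum-coded main effects and
    interaction products, and the bookkeeping needed for Type-III tests."""
    factors = sorted({f for t in fixed_terms for f in t.split(":")})
    levels = {}
    coded = {}
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} not in table")
        lv = sorted(map(str, pd.unique(df[f].astype(str))))
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        levels[f] = lv
        coded[f] = _sum_code(df[f].astype(str), lv)

    cols = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    slices: dict[str, slice] = {}
    start = 1
    for term in fixed_terms:
        parts = term.split(":")
        mats = [coded[p] for p in parts]
        prod = mats[0]
        for m in mats[1:]:
            prod = np.einsum("ni,nj->nij", prod, m).reshape(len(df), -1)
        cols.append(prod)
        n_new = prod.shape[1]
        base = [
            "x".join(c) for c in itertools.product(
                *[[f"{p}[{l}]" for l in levels[p][:-1]] for p in parts])
        ]
        names.extend(base)
        slices[term] = slice(start, start + n_new)
        start += n_new
    X = np.hstack(cols)
    return X, DesignInfo(terms=list(fixed_terms), term_slices=slices,
                         column_names=names, factor_levels=levels)


# ---------------------------------------------------------------------------
# REML machinery

@dataclass
class LmmFormula:
    response: str
    fixed: "list[str]"
    random: str


@dataclass
class ModelFit:
    formula: LmmFormula
    info: DesignInfo
    beta: np.ndarray
    cov_beta: np.ndarray          # Vb at the REML estimate
    sigma2: float
    tau2: float
    lam: float
    neg2_reml: float
    n_obs: int
    n_params: int
    n_groups: int
    boundary: bool                # tau2 at (or near) zero
    converged: bool = True
    # internals for Satterthwaite
    _P: np.ndarray = field(repr=False, default=None)
    _Q1: np.ndarray = field(repr=False, default=None)
    _Q2: np.ndarray = field(repr=False, default=None)
    _theta_cov: np.ndarray = field(repr=False, default=None)

    @property
    def resid_df(self) -> float:
        return self.n_obs - self.n_params


class _RemlWork:
    """Sufficient statistics for the profiled REML criterion."""

    def __init__(self, X: np.ndarray, y: np.ndarray, group_codes: np.ndarray):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        order = np.argsort(group_codes, kind="stable")
        Xs, ys, gs = X[order], y[order], group_codes[order]
        _, starts, counts = np.unique(gs, return_index=True, return_counts=True)
        self.ng = counts.astype(float)
        self.G = len(counts)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums
        self.Sx = np.add.reduceat(Xs, starts, axis=0)
        self.Sy = np.add.reduceat(ys, starts)

    def pieces(self, lam: float):
        w = lam / (1.0 + lam * self.ng)
        XtWX = self.XtX - self.Sx.T @ (w[:, None] * self.Sx)
        XtWy = self.Xty - self.Sx.T @ (w * self.Sy)
        yWy = self.yty - float(w @ (self.Sy ** 2))
        return w, XtWX, XtWy, yWy

    def profiled(self, lam: float):
        w, XtWX, XtWy, yWy = self.pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = yWy - float(beta @ XtWy)
        rss = max(rss, 1e-300)
        sigma2 = rss / (self.n - self.p)
        sign, logdet = np.linalg.slogdet(XtWX)
        crit = ((self.n - self.p) * np.log(sigma2)
                + float(np.sum(np.log1p(lam * self.ng)))
                + logdet + (self.n - self.p))
        return crit, beta, sigma2, XtWX, XtWy, rss

    def neg2_reml_theta(self, sigma2: float, tau2: float) -> float:
        """Unprofiled criterion as a function of (sigma2, tau2)."""
        lam = tau2 / sigma2
        _, XtWX, XtWy, yWy = self.pieces(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = yWy - float(beta @ XtWy)
        _, logdet = np.linalg.slogdet(XtWX)
        return ((self.n - self.p) * np.log(sigma2)
                + float(np.sum(np.log1p(lam * self.ng)))
                + logdet + rss / sigma2)


def _theta_cov(work: _RemlWork, sigma2: float, tau2: float) -> np.ndarray:
    """Asymptotic Cov(sigma2, tau2) = 2 H^-1, H the finite-difference
    Hessian of the REML criterion."""
    th = np.array([sigma2, max(tau2, 0.0)])
    h = np.maximum(1e-8, 1e-4 * np.maximum(th, np.array([sigma2, sigma2])))
    f = work.neg2_reml_theta

    def ev(d0, d1):
        return f(max(th[0] + d0, 1e-12), max(th[1] + d1, 0.0))

    H = np.empty((2, 2))
    for i in range(2):
        d = np.zeros(2)
        d[i] = h[i]
        H[i, i] = (ev(*d) - 2 * ev(0, 0) + ev(*(-d))) / h[i] ** 2
    H[0, 1] = H[1, 0] = (
        ev(h[0], h[1]) - ev(h[0], -h[1]) - ev(-h[0], h[1]) + ev(-h[0], -h[1])
    ) / (4 * h[0] * h[1])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return cov


def fit_lmm(table: pd.DataFrame, formula: LmmFormula) -> ModelFit:
    """REML fit of the random-intercept model defined by ``formula``."""
    df = table.reset_index(drop=True)
    y = np.asarray(df[formula.response], dtype=np.float64)
    X, info = build_design(df, formula.fixed)
    groups = pd.Categorical(df[formula.random].astype(str)).codes
    if len(np.unique(groups)) < 2:
        raise ValueError("random factor needs >= 2 levels")
    counts = np.bincount(groups)
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")

    work = _RemlWork(X, y, groups)

    def f(u):  # u = log lambda
        return work.profiled(float(np.exp(u)))[0]

    res = optimize.minimize_scalar(
        f, bounds=(np.log(1e-10), np.log(LAMBDA_MAX)), method="bounded",
        options={"xatol": REML_TOL})
    lam_hat = float(np.exp(res.x))
    crit_hat = res.fun
    crit0 = work.profiled(0.0)[0]
    if crit0 <= crit_hat + 1e-10:
        lam_hat, crit_hat = 0.0, crit0

    crit, beta, sigma2, XtWX, XtWy, rss = work.profiled(lam_hat)
    tau2 = lam_hat * sigma2
    P = np.linalg.inv(XtWX)
    cov_beta = sigma2 * P

    w = lam_hat / (1.0 + lam_hat * work.ng)
    Q1 = work.XtX - work.Sx.T @ ((w * (2.0 - w * work.ng))[:, None] * work.Sx)
    Q2 = work.Sx.T @ (((1.0 - w * work.ng) ** 2)[:, None] * work.Sx)
    boundary = tau2 < BOUNDARY_TAU2 * sigma2
    theta_cov = (None if boundary else _theta_cov(work, sigma2, tau2))

    return ModelFit(formula=formula, info=info, beta=beta, cov_beta=cov_beta,
                    sigma2=float(sigma2), tau2=float(tau2), lam=lam_hat,
                    neg2_reml=float(crit), n_obs=work.n, n_params=work.p,
                    n_groups=work.G, boundary=bool(boundary),
                    _P=P, _Q1=Q1, _Q2=Q2, _theta_cov=theta_cov)


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom

def _satterthwaite_1df(fit: ModelFit, ell: np.ndarray) -> float:
    """Satterthwaite df for a single contrast row ell (on beta)."""
    if fit.boundary or fit._theta_cov is None or not np.isfinite(
            fit._theta_cov).all():
        return float(fit.resid_df)
    f_val = float(ell @ fit.cov_beta @ ell)
    Pl = fit._P @ ell
    g = np.array([float(Pl @ fit._Q1 @ Pl), float(Pl @ fit._Q2 @ Pl)])
    denom = float(g @ fit._theta_cov @ g)
    if denom <= 0:
        return float(fit.resid_df)
    return max(1.0, 2.0 * f_val ** 2 / denom)


def contrast_test(fit: ModelFit, L: np.ndarray):
    """F test of L beta = 0 with Satterthwaite denominator df."""
    L = np.atleast_2d(np.asarray(L, dtype=np.float64))
    q = L.shape[0]
    M = L @ fit.cov_beta @ L.T
    Minv = np.linalg.pinv(M)
    est = L @ fit.beta
    F = float(est @ Minv @ est) / q
    if fit.boundary:
        df_den = float(fit.resid_df)
    else:
        d_vals, P = np.linalg.eigh(M)
        keep = d_vals > 1e-12 * d_vals.max()
        nus = []
        for i in np.nonzero(keep)[0]:
            ell = P[:, i] @ L
            nus.append(_satterthwaite_1df(fit, ell))
        nus = np.asarray(nus)
        good = nus > 2.0
        if good.sum() == 0:
            df_den = float(fit.resid_df)
        else:
            E = float(np.sum(nus[good] / (nus[good] - 2.0)))
            df_den = 2.0 * E / (E - good.sum()) if E > good.sum() else np.inf
    if not np.isfinite(df_den):
        p = float(stats.chi2.sf(q * F, q))
        df_den = np.inf
    else:
        p = float(stats.f.sf(F, q, df_den))
    return F, q, df_den, p


def anova_type3(fit: ModelFit) -> pd.DataFrame:
    """Type-III (marginal) ANOVA table; valid because all factors are
    sum-to-zero coded."""
    rows = []
    p_tot = len(fit.beta)
    for term in fit.info.terms:
        sl = fit.info.term_slices[term]
        q = sl.stop - sl.start
        L = np.zeros((q, p_tot))
        L[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        F, df_num, df_den, p = contrast_test(fit, L)
        rows.append({"term": term, "F": F, "df_num": df_num,
                     "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimated marginal means and contrasts

def _grid_row(fit: ModelFit, assign: "dict[str, str]") -> np.ndarray:
    """X row for a cell of the reference grid: assigned factors at their
    level's sum coding, unassigned factors averaged over levels (coded 0)."""
    info = fit.info
    row = np.zeros(len(fit.beta))
    row[0] = 1.0
    for term in info.terms:
        parts = term.split(":")
        sl = info.term_slices[term]
        mats = []
        for p_ in parts:
            lv = info.factor_levels[p_]
            k = len(lv)
            if p_ in assign:
                code = np.zeros(k - 1)
                j = lv.index(str(assign[p_]))
                if j < k - 1:
                    code[j] = 1.0
                else:
                    code[:] = -1.0
            else:
                code = np.zeros(k - 1)  # average over levels
            mats.append(code)
        prod = mats[0]
        for m in mats[1:]:
            prod = np.outer(prod, m).ravel()
        row[sl] = prod
    return row


def emmeans(fit: ModelFit, factors: "list[str]") -> pd.DataFrame:
    """EMMs over the cross of ``factors``, other factors averaged."""
    for f in factors:
        if f not in fit.info.factor_levels:
            raise ValueError(f"{f!r} is not a factor of the model")
    grids = [fit.info.factor_levels[f] for f in factors]
    rows = []
    for combo in itertools.product(*grids):
        assign = dict(zip(factors, combo))
        x = _grid_row(fit, assign)
        est = float(x @ fit.beta)
        se = float(np.sqrt(max(x @ fit.cov_beta @ x, 0.0)))
        rows.append({**assign, "emmean": est, "se": se})
    return pd.DataFrame(rows)


def _z_p(est: float, se: float) -> tuple[float, float]:
    z = est / se if se > 0 else np.sign(est) * np.inf
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return float(z), p


def effect_contrasts(fit: ModelFit, factor: str,
                     by: "str | None" = None) -> pd.DataFrame:
    """Effect contrasts: each level of ``factor`` versus the mean of the
    remaining levels, optionally within each level of ``by``.  Bonferroni
    family = every contrast in the returned table."""
    levels = fit.info.factor_levels[factor]
    by_levels = fit.info.factor_levels[by] if by else [None]
    rows = []
    for b in by_levels:
        for m in levels:
            others = [l for l in levels if l != m]
            assign_m = {factor: m, **({by: b} if by else {})}
            x = _grid_row(fit, assign_m).copy()
            for o in others:
                x = x - _grid_row(fit, {factor: o, **({by: b} if by else {})}
                                  ) / len(others)
            est = float(x @ fit.beta)
            se = float(np.sqrt(max(x @ fit.cov_beta @ x, 0.0)))
            z, p = _z_p(est, se)
            row = {factor: m, "estimate": est, "se": se, "z_ratio": z, "p": p}
            if by:
                row[by] = b
            rows.append(row)
    out = pd.DataFrame(rows)
    m_tests = len(out)
    if m_tests == 0:
        raise ValueError("empty contrast family")
    out["p_bonf"] = np.minimum(1.0, out["p"] * m_tests)
    return out


def pairwise_z_matrix(fit: ModelFit, factor: str, by: str) -> "dict[str, np.ndarray]":
    """For each level of ``by``: the antisymmetric matrix of pairwise
    contrast z-ratios between levels of ``factor`` (EMM differences on the
    asymptotic normal scale)."""
    levels = fit.info.factor_levels[factor]
    out = {}
    for b in fit.info.factor_levels[by]:
        k = len(levels)
        Z = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                x = (_grid_row(fit, {factor: levels[i], by: b})
                     - _grid_row(fit, {factor: levels[j], by: b}))
                est = float(x @ fit.beta)
                se = float(np.sqrt(max(x @ fit.cov_beta @ x, 0.0)))
                z, _ = _z_p(est, se)
                Z[i, j], Z[j, i] = z, -z
        out[b] = Z
    return out


def pairwise_group_contrasts(fit: ModelFit, group_factor: str, levels_pair,
                             within: "list[str]") -> pd.DataFrame:
    """Contrast ``levels_pair[1] - levels_pair[0]`` of ``group_factor``
    within every cell of the ``within`` factors; Bonferroni over the table."""
    grids = [fit.info.factor_levels[f] for f in within]
    rows = []
    for combo in itertools.product(*grids):
        assign = dict(zip(within, combo))
        x = (_grid_row(fit, {group_factor: levels_pair[1], **assign})
             - _grid_row(fit, {group_factor: levels_pair[0], **assign}))
        est = float(x @ fit.beta)
        se = float(np.sqrt(max(x @ fit.cov_beta @ x, 0.0)))
        z, p = _z_p(est, se)
        rows.append({**assign, "estimate": est, "se": se, "z_ratio": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_bonf"] = np.minimum(1.0, out["p"] * len(out))
    return out
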