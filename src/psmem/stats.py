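"""Group-level inference.

Random-intercept linear mixed models with type-III F tests and Satterthwaite
denominator degrees of freedom, split-plot (mixed) ANOVA on condition means,
Wilcoxon signed-rank tests, Holm multiplicity correction, and effect sizes
(Cohen's f-squared from marginal R-squared, partial eta-squared, Cohen's d).

The REML fit itself is delegated to :class:`statsmodels` MixedLM; this
module owns the model contract: sum-to-zero (type III) coding of factors,
the closed-form restricted likelihood of the random-intercept model used for
the Satterthwaite approximation, variance-inflation reporting, and the tidy
result layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm

__all__ = [
    "TestResult",
    "LmmSpec",
    "LmmResult",
    "fit_lmm",
    "mixed_anova",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "cohens_d",
    "f_squared",
    "partial_eta_squared",
    "variance_inflation",
]


@dataclass(frozen=True)
class TestResult:
    """One statistical effect in tidy form."""

    effect: str
    statistic: float
    stat_type: str  # "F" | "V" | "t" | "W"
    df1: float | None
    df2: float | None
    p: float
    p_holm: float | None = None
    effect_size: float | None = None
    effect_size_type: str | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "effect": self.effect, "statistic": self.statistic,
            "stat_type": self.stat_type, "df1": self.df1, "df2": self.df2,
            "p": self.p, "p_holm": self.p_holm, "effect_size": self.effect_size,
            "effect_size_type": self.effect_size_type, "note": self.note,
        }


@dataclass(frozen=True)
class LmmSpec:
    """Specification of a random-intercept mixed model.

    ``fixed`` holds main effects and interactions (``"a:b"``); ``covariates``
    are appended as additional main effects (e.g. the cortisol/placebo
    group); ``groups`` names the random-intercept grouping column.
    """

    outcome: str
    fixed: tuple[str, ...]
    groups: str = "participant_id"
    covariates: tuple[str, ...] = ()

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.fixed) + tuple(c for c in self.covariates
                                         if c not in self.fixed)


@dataclass(frozen=True)
class LmmResult:
    tests: tuple[TestResult, ...]
    coefficients: pd.DataFrame
    sigma2_re: float
    sigma2_resid: float
    vif: dict[str, float]
    converged: bool
    singular: bool
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_dict() for t in self.tests])


# ---------------------------------------------------------------------------
# design construction (sum-to-zero coding -> type III contrasts)

def _encode_variable(s: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    if s.dtype == bool:
        return np.where(s.to_numpy(), 1.0, -1.0)[:, None], [name]
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(pd.unique(s.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has fewer than two levels")
    cols = []
    names = []
    vals = s.astype(str).to_numpy()
    for lev in levels[:-1]:
        col = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
        cols.append(col)
        names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def build_design(table: pd.DataFrame, spec: LmmSpec
                 ) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Fixed-effects design matrix with intercept and per-term column slices."""
    encoded: dict[str, tuple[np.ndarray, list[str]]] = {}

    def enc(var: str):
        if var not in encoded:
            if var not in table.columns:
                raise ValueError(f"column {var!r} not in table")
            encoded[var] = _encode_variable(table[var], var)
        return encoded[var]

    blocks = [np.ones((len(table), 1))]
    names = ["intercept"]
    slices: dict[str, slice] = {}
    for term in spec.terms:
        parts = term.split(":")
        mats = [enc(p)[0] for p in parts]
        labs = [enc(p)[1] for p in parts]
        cols = mats[0]
        cn = labs[0]
        for m, l in zip(mats[1:], labs[1:]):
            cols = np.concatenate(
                [cols[:, [i]] * m for i in range(cols.shape[1])], axis=1)
            cn = [f"{a}:{b}" for a in cn for b in l]
        start = sum(b.shape[1] for b in blocks)
        slices[term] = slice(start, start + cols.shape[1])
        blocks.append(cols)
        names.extend(cn)
    X = np.concatenate(blocks, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"fixed-effects design is rank deficient (columns {names})")
    return X, names, slices


def variance_inflation(X: np.ndarray, names: list[str]) -> dict[str, float]:
    """VIF per non-intercept column (R-squared of that column on the rest)."""
    out: dict[str, float] = {}
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tot = X[:, j] - X[:, j].mean()
        r2 = 1.0 - (resid**2).sum() / max((tot**2).sum(), 1e-300)
        out[names[j]] = 1.0 / max(1.0 - r2, 1e-12)
    return out


# ---------------------------------------------------------------------------
# closed-form REML machinery for the random-intercept model

class _RandomInterceptREML:
    """Sufficient statistics and restricted likelihood for sigma^2 profiling.

    V = sigma2_e I + sigma2_u Z Z' with Z the group indicator; all GLS
    quantities use the Woodbury identity per group, so evaluations are O(n)
    once the per-group sums are cached.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        codes, _ = pd.factorize(groups)
        self.n, self.p = X.shape
        self.n_groups = codes.max() + 1
        self.group_sizes = np.bincount(codes)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of rows of X and of y
        self.sX = np.zeros((self.n_groups, self.p))
        np.add.at(self.sX, codes, X)
        self.sy = np.bincount(codes, weights=y)

    def gls(self, lam: float, e: float):
        c = lam / (e + self.group_sizes * lam)  # (G,)
        xvx = (self.XtX - (self.sX * c[:, None]).T @ self.sX) / e
        xvy = (self.Xty - self.sX.T @ (c * self.sy)) / e
        yvy = (self.yty - float(c @ self.sy**2)) / e
        C = np.linalg.inv(xvx)
        beta = C @ xvy
        return beta, C, xvx, xvy, yvy

    def reml_loglik(self, lam: float, e: float) -> float:
        beta, _, xvx, xvy, yvy = self.gls(lam, e)
        logdet_v = float(np.sum((self.group_sizes - 1) * np.log(e)
                                + np.log(e + self.group_sizes * lam)))
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        rss = yvy - float(beta @ xvy)
        return -0.5 * (logdet_v + logdet_xvx + rss)

    def cov_beta(self, lam: float, e: float) -> np.ndarray:
        return self.gls(lam, e)[1]

    def theta_cov(self, lam: float, e: float) -> np.ndarray:
        """Asymptotic covariance of (sigma2_u, sigma2_e) from the REML Hessian."""
        h = np.zeros((2, 2))
        steps = [max(1e-6, 1e-4 * max(lam, e)), max(1e-6, 1e-4 * e)]

        def f(t):
            return self.reml_loglik(max(t[0], 0.0), max(t[1], 1e-12))

        t0 = np.array([lam, e])
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * steps[i]
                ej = np.eye(2)[j] * steps[j]
                h[i, j] = h[j, i] = (
                    f(t0 + ei + ej) - f(t0 + ei - ej) - f(t0 - ei + ej)
                    + f(t0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
        try:
            return np.linalg.inv(-h)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)


def _satterthwaite_df(reml: _RandomInterceptREML, lam: float, e: float,
                      ell: np.ndarray, theta_cov: np.ndarray) -> float:
    """Satterthwaite df for the one-dimensional contrast ``ell``."""
    def phi(t):
        return float(ell @ reml.cov_beta(max(t[0], 0.0), max(t[1], 1e-12)) @ ell)

    t0 = np.array([lam, e])
    steps = [max(1e-6, 1e-4 * max(lam, e)), max(1e-6, 1e-4 * e)]
    grad = np.array([
        (phi(t0 + np.eye(2)[i] * steps[i]) - phi(t0 - np.eye(2)[i] * steps[i]))
        / (2 * steps[i])
        for i in range(2)
    ])
    denom = float(grad @ theta_cov @ grad)
    if not np.isfinite(denom) or denom <= 0:
        return float(reml.n - reml.p)
    return 2.0 * phi(t0) ** 2 / denom


def fit_lmm(table: pd.DataFrame, spec: LmmSpec,
            compute_effect_sizes: bool = True) -> LmmResult:
    """Random-intercept mixed model with type-III tests.

    Factors enter with sum-to-zero coding so that each term's F test is the
    type-III test of its coefficients while controlling for the others.
    F statistics use Satterthwaite denominator degrees of freedom, combined
    over multi-column terms the way lmerTest does (eigen-decomposition of
    the contrast covariance, then moment matching of the scaled chi-square).
    Cohen's f-squared is computed from the marginal R-squared of the full
    versus the term-deleted model. A singular fit (random-intercept variance
    estimated at zero) is reported on the result, not raised.
    """
    data = table.dropna(subset=[spec.outcome]).reset_index(drop=True)
    y = data[spec.outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    X, names, slices = build_design(data, spec)
    groups = data[spec.groups].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValueError("grouping column must have at least two levels")

    reml = _RandomInterceptREML(y, X, groups)
    lam, e, beta, converged = _fit_reml(y, X, groups, reml)
    singular = lam <= 1e-10 * np.var(y)

    C = reml.cov_beta(lam, e)
    theta_cov = reml.theta_cov(lam, e)

    vif = variance_inflation(X, names)
    r2_full = _marginal_r2(X, beta, lam, e)

    tests = []
    for term, sl in slices.items():
        idx = np.arange(sl.start, sl.stop)
        q = len(idx)
        Lc = C[np.ix_(idx, idx)]
        Lb = beta[idx]
        F = float(Lb @ np.linalg.inv(Lc) @ Lb) / q
        # per-eigencontrast Satterthwaite df, moment-matched into one F df
        vals, vecs = np.linalg.eigh(Lc)
        nus = []
        for k in range(q):
            ell = np.zeros(reml.p)
            ell[idx] = vecs[:, k]
            nus.append(_satterthwaite_df(reml, lam, e, ell, theta_cov))
        nus = [nu for nu in nus if np.isfinite(nu)]
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        df2 = 2.0 * E / (E - q) if E > q else float(reml.n - reml.p)
        p = float(sps.f.sf(F, q, df2))
        f2 = None
        if compute_effect_sizes:
            f2 = _term_f2(data, spec, term, y, groups, r2_full)
        tests.append(TestResult(effect=term, statistic=F, stat_type="F",
                                df1=float(q), df2=df2, p=p, effect_size=f2,
                                effect_size_type="f2" if f2 is not None else None,
                                note="singular fit" if singular else ""))

    coef = pd.DataFrame({"term": names, "estimate": beta,
                         "se": np.sqrt(np.diag(C))})
    return LmmResult(tests=tuple(tests), coefficients=coef, sigma2_re=lam,
                     sigma2_resid=e, vif=vif, converged=converged,
                     singular=singular, n_obs=len(y))


def _fit_reml(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
              reml: "_RandomInterceptREML | None" = None
              ) -> tuple[float, float, np.ndarray, bool]:
    """REML point estimates: statsmodels MixedLM, polished on the closed form.

    The statsmodels optimizer can spuriously stop at the sigma2_u = 0
    boundary; its estimate is therefore refined by direct maximization of
    the closed-form restricted likelihood (cheap: O(1) per evaluation after
    the sufficient statistics are cached) and the better optimum wins.
    """
    from scipy.optimize import minimize

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    lam0 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    e0 = float(res.scale)
    converged = bool(res.converged)
    reml = reml if reml is not None else _RandomInterceptREML(y, X, groups)

    vy = max(float(np.var(y)), 1e-12)

    def nll(t):
        return -reml.reml_loglik(float(np.exp(t[0])), float(np.exp(t[1])))

    best = (lam0, e0, reml.reml_loglik(lam0, e0))
    for start in ((max(lam0, 1e-4 * vy), e0), (0.1 * vy, 0.9 * vy)):
        opt = minimize(nll, np.log(start), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        lam1, e1 = np.exp(opt.x)
        ll1 = -opt.fun
        if ll1 > best[2] + 1e-9:
            best = (float(lam1), float(e1), ll1)
    lam, e, _ = best
    if lam < 1e-10 * vy:
        lam = 0.0
    beta = reml.gls(lam, e)[0]
    return lam, e, beta, converged


def _marginal_r2(X: np.ndarray, beta: np.ndarray, lam: float, e: float) -> float:
    """Marginal (fixed-effects) R-squared of a random-intercept model."""
    var_fix = float(np.var(X @ beta))
    return var_fix / (var_fix + lam + e)


def _term_f2(data: pd.DataFrame, spec: LmmSpec, term: str, y: np.ndarray,
             groups: np.ndarray, r2_full: float) -> float | None:
    reduced_terms = tuple(t for t in spec.terms if t != term)
    red = LmmSpec(outcome=spec.outcome, fixed=reduced_terms, groups=spec.groups)
    try:
        Xr, _, _ = build_design(data, red)
        lam_r, e_r, beta_r, _ = _fit_reml(y, Xr, groups)
        r2_red = _marginal_r2(Xr, beta_r, lam_r, e_r)
    except Exception:
        return None
    if r2_full >= 1.0:
        return None
    return max((r2_full - r2_red), 0.0) / (1.0 - r2_full)


# ---------------------------------------------------------------------------
# split-plot ANOVA on condition means

def mixed_anova(table: pd.DataFrame, dv: str, within: str, between: str,
                subject: str = "participant_id") -> tuple[TestResult, ...]:
    """Mixed (split-plot) ANOVA: one within factor, one between factor.

    One value per participant per within level; participants with a missing
    cell are dropped. F computation is delegated to pingouin; partial
    eta-squared is reported per effect.
    """
    import pingouin as pg

    wide = table.pivot_table(index=[subject, between], columns=within, values=dv)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    data = complete.stack().rename(dv).reset_index()
    counts = data.groupby(between)[subject].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need at least two participants per between-group level")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                             subject=subject)
    out = []
    for _, row in aov.iterrows():
        out.append(TestResult(
            effect=str(row["Source"]), statistic=float(row["F"]), stat_type="F",
            df1=float(row["DF1"]), df2=float(row["DF2"]), p=float(row["p_unc"]),
            effect_size=float(row["np2"]), effect_size_type="partial_eta2",
            note=f"dropped {dropped} participants with missing cells" if dropped else "",
        ))
    return tuple(out)


# ---------------------------------------------------------------------------
# nonparametric tests, multiplicity, effect sizes

def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray,
                         alternative: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test.

    V is the sum of ranks of positive differences (zero differences are
    dropped). The p-value is exact for n <= 25 without ties in the absolute
    differences, otherwise a normal approximation with tie correction. All
    differences zero yields a missing result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = (x - y)[~np.isnan(x - y)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(effect="wilcoxon", statistic=np.nan, stat_type="V",
                          df1=None, df2=None, p=np.nan,
                          note="all differences zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if n <= 25 and not has_ties:
        p = float(sps.wilcoxon(d, alternative=alternative, method="exact").pvalue)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts) / 48.0
        z = (v - mean) / np.sqrt(var)
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
    z_eq = sps.norm.isf(p / 2) if 0 < p <= 1 else np.nan
    r = float(abs(z_eq) / np.sqrt(n)) if np.isfinite(z_eq) else None
    return TestResult(effect="wilcoxon", statistic=v, stat_type="V", df1=None,
                      df2=None, p=min(p, 1.0), effect_size=r,
                      effect_size_type="r" if r is not None else None)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment (order-restoring, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Cohen's d with pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def f_squared(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f-squared from full and reduced model R-squared."""
    if r2_full >= 1.0:
        raise ValueError("f-squared undefined when the full model is saturated")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    return ss_effect / (ss_effect + ss_error)
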