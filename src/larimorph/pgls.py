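"""Phylogenetic generalized least squares under four models of evolution.

The response (here mantle darkness on the Kodak grey scale) is modelled as
y ~ MVN(X beta, sigma2 * C0(theta)) where C0 is one of

* NP      — identity (a non-phylogenetic model: ordinary least squares),
* BM      — shared branch lengths (Brownian-motion random walk),
* OU      — fixed-root Ornstein-Uhlenbeck with selection strength alpha,
* LAMBDA  — Pagel's lambda shrinking off-diagonal shared branch lengths.

All fits are maximum likelihood (not REML) so that likelihood-ratio tests
between models with the same fixed effects are valid.  For OU and LAMBDA the
scalar structure parameter is profiled: beta and sigma2 have closed-form
conditional MLEs, leaving a 1-d concentrated log-likelihood that is searched
on a grid and refined by bounded scalar optimization.

The phylogenetic half-life ln(2)/alpha converts OU selection strength into
the time for the expected trait to move halfway to its optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import CholeskyError, DegenerateInputError
from .phylo import Phylogeny, cholesky_or_raise, lambda_transform, ou_cov

__all__ = [
    "PGLSFit",
    "LRTResult",
    "gls_fit",
    "fit_model",
    "lrt",
    "half_life",
    "lambda_profile_ci",
    "ols_fit",
    "pearson",
]

MODELS = ("NP", "BM", "OU", "LAMBDA")

#: relative floor/ceiling of the OU selection-strength search, in units of
#: 1/tree-height.  The lower bound makes BM effectively nested in the OU
#: search space: at alpha*height = 1e-8 the OU structure differs from BM by
#: a relative O(1e-8), so loglik_OU >= loglik_BM - 1e-6 always holds.
ALPHA_REL_BOUNDS = (1e-8, 1e3)


@dataclass
class GLSResult:
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sigma2: float          # ML estimate r' C0^-1 r / n
    loglik: float
    n: int
    p: int
    degenerate: bool = False


@dataclass
class PGLSFit:
    """One fitted evolutionary regression model.

    ``param`` holds alpha (OU) or lambda (LAMBDA), ``param_ci`` a profile
    95% CI for lambda.  ``aic = 2k - 2 loglik`` with k = fixed effects +
    sigma2 + (1 if a structure parameter was estimated).
    """

    model: str
    coef_names: list
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    n: int
    k: int
    param: float | None = None
    param_name: str | None = None
    param_ci: tuple | None = None
    boundary: bool = False
    degenerate: bool = False
    _profile: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coef": {n: float(b) for n, b in zip(self.coef_names, self.beta)},
            "se": {n: float(s) for n, s in zip(self.coef_names, self.se)},
            "p_value": {n: float(p) for n, p in zip(self.coef_names, self.p_value)},
            "sigma2": float(self.sigma2),
            "param_name": self.param_name,
            "param": None if self.param is None else float(self.param),
            "param_ci": None if self.param_ci is None else [float(v) for v in self.param_ci],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n": self.n,
            "k": self.k,
            "boundary": self.boundary,
        }


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


_DEGENERATE_TOL = 1e-12


def gls_fit(X: np.ndarray, y: np.ndarray, C0: np.ndarray) -> GLSResult:
    """Closed-form ML generalized least squares for y ~ MVN(X beta, sigma2 C0).

    beta_hat = (X' C0^-1 X)^-1 X' C0^-1 y; sigma2_hat (ML) = r' C0^-1 r / n.
    Reported SEs use the bias-adjusted denominator n - p and t-distributed
    p-values with n - p degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size or C0.shape != (n, n):
        raise ValueError("X, y and C0 dimensions disagree")
    L = cholesky_or_raise(C0, "GLS covariance structure C0")
    logdetC = 2.0 * np.log(np.diag(L)).sum()
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p})")
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2_ml = rss / n
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    scale = np.mean(np.diag(C0))
    degenerate = sigma2_ml <= _DEGENERATE_TOL * max(scale * float(y @ y) / n, 1e-300)
    if degenerate:
        loglik = math.inf
        se = np.zeros(p)
        t = np.full(p, np.inf)
        pv = np.zeros(p)
    else:
        loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2_ml) + logdetC + n)
        sigma2_adj = rss / (n - p) if n > p else math.nan
        se = np.sqrt(sigma2_adj * np.diag(XtX_inv))
        t = beta / se
        pv = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    return GLSResult(beta, se, t, pv, sigma2_ml, loglik, n, p, degenerate)


def _bm_structure(tree: Phylogeny) -> np.ndarray:
    return tree.mrca_depth_matrix()


def _concentrated(X, y, structure_fn):
    """Profile log-likelihood of the scalar structure parameter."""

    def f(theta):
        try:
            return gls_fit(X, y, structure_fn(theta)).loglik
        except CholeskyError:
            return -math.inf

    return f


def _profile_maximize(f, grid):
    vals = np.array([f(g) for g in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return grid[i], vals[i]
    res = optimize.minimize_scalar(
        lambda t: -f(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def fit_model(
    tree: Phylogeny,
    y: np.ndarray,
    X: np.ndarray,
    model: str,
    coef_names: list | None = None,
) -> PGLSFit:
    """Fit one of the four evolutionary regression models by ML.

    ``y`` and rows of ``X`` must be aligned to ``tree.tip_labels`` order.
    OU profiles alpha on a log scale over [1e-6/height, 1e3/height] with a
    61-point grid plus bounded refinement; LAMBDA profiles lambda on [0, 1].
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if coef_names is None:
        coef_names = [f"b{i}" for i in range(p)]
    height = tree.height()

    param = None
    param_name = None
    param_ci = None
    boundary = False
    profile = None

    if model == "NP":
        res = gls_fit(X, y, np.eye(n))
        k = p + 1
    elif model == "BM":
        res = gls_fit(X, y, _bm_structure(tree))
        k = p + 1
    elif model == "OU":
        lo, hi = (b / height for b in ALPHA_REL_BOUNDS)
        f = _concentrated(X, y, lambda la: ou_cov(tree, math.exp(la)))
        grid = np.log(np.geomspace(lo, hi, 61))
        la_hat, _ = _profile_maximize(f, grid)
        param = math.exp(la_hat)
        param_name = "alpha"
        boundary = la_hat <= math.log(lo) + 1e-6 or la_hat >= math.log(hi) - 1e-6
        res = gls_fit(X, y, ou_cov(tree, param))
        profile = f
        k = p + 2
    else:  # LAMBDA
        C = _bm_structure(tree)
        f = _concentrated(X, y, lambda lam: lambda_transform(C, lam))
        grid = np.linspace(0.0, 1.0, 41)
        lam_hat, _ = _profile_maximize(f, grid)
        param = lam_hat
        param_name = "lambda"
        boundary = lam_hat <= 1e-8 or lam_hat >= 1.0 - 1e-8
        res = gls_fit(X, y, lambda_transform(C, lam_hat))
        profile = f
        k = p + 2

    fit = PGLSFit(
        model=model,
        coef_names=list(coef_names),
        beta=res.beta,
        se=res.se,
        t_stat=res.t_stat,
        p_value=res.p_value,
        sigma2=res.sigma2,
        loglik=res.loglik,
        aic=2.0 * k - 2.0 * res.loglik,
        n=n,
        k=k,
        param=param,
        param_name=param_name,
        param_ci=param_ci,
        boundary=boundary,
        degenerate=res.degenerate,
        _profile=profile,
    )
    if model == "LAMBDA":
        fit.param_ci = lambda_profile_ci(fit)
    return fit


def lrt(restricted: PGLSFit, general: PGLSFit) -> LRTResult:
    """Likelihood-ratio test of a restricted model against one extra parameter.

    statistic = 2 (loglik_general - loglik_restricted), clipped at 0;
    p from the chi-square upper tail with df = difference in k.  At a
    boundary MLE (alpha -> 0, lambda at 0 or 1) the plain chi-square is
    conservative; no boundary mixture correction is applied.
    """
    if restricted.n != general.n:
        raise ValueError("fits are on different sample sizes")
    if restricted.k >= general.k:
        raise ValueError("restricted model must have fewer parameters")
    df = general.k - restricted.k
    stat = max(0.0, 2.0 * (general.loglik - restricted.loglik))
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)))


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha in tree-time units."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return math.log(2.0) / alpha


_CHI2_1_HALF_95 = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207...


def lambda_profile_ci(fit: PGLSFit, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for lambda: where the profile drops chi2_1(level)/2.

    Endpoints are clipped to [0, 1] and always contain the MLE.  A profile
    flat to within the drop over the whole interval yields (0, 1) with a
    warning.
    """
    if fit.model != "LAMBDA" or fit._profile is None:
        raise ValueError("profile CI requires a LAMBDA fit with a stored profile")
    f = fit._profile
    drop = stats.chi2.ppf(level, 1) / 2.0
    lmax = f(fit.param)
    target = lmax - drop
    grid = np.linspace(0.0, 1.0, 201)
    vals = np.array([f(g) for g in grid])
    if vals.min() > target:
        import warnings

        warnings.warn("flat lambda profile: CI spans the whole [0, 1] interval")
        return (0.0, 1.0)

    def cut(a, b):
        # f(a) and f(b) straddle target; bisect for the crossing
        return optimize.brentq(lambda t: f(t) - target, a, b, xtol=1e-8)

    lam = fit.param
    lo = 0.0
    if f(0.0) < target:
        below = grid[(grid < lam) & (vals < target)]
        if below.size:
            lo = cut(below[-1], lam)
    hi = 1.0
    if f(1.0) < target:
        above = grid[(grid > lam) & (vals < target)]
        if above.size:
            hi = cut(lam, above[0])
    return (float(lo), float(hi))


@dataclass
class OLSResult:
    slope: float
    intercept: float
    se: float
    r2: float
    p_value: float


def ols_fit(x, y) -> OLSResult:
    """Simple least-squares regression of y on x (slope, SE, R^2, t p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor")
    res = stats.linregress(x, y)
    return OLSResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=float(res.stderr),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input to correlation")
    return float(np.corrcoef(x, y)[0, 1])
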