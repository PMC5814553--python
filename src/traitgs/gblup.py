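"""Univariate and bivariate GBLUP with REML variance components.

Stage 2 of the pipeline.  The single-trait model is

    y_i = mu + g_i + e_i,   g ~ N(0, A sigma2_g),   e ~ N(0, I sigma2_e),

with A the realized additive relationship matrix; genomic heritability is
h2_g = sigma2_g / (sigma2_g + sigma2_e).  The two-trait model stacks
records by trait,

    Y_i = mu + g_i + e_i,   g ~ N(0, G (x) A),   e ~ N(0, I (x) R),

with unstructured 2x2 genetic (G) and residual (R) covariance matrices and
records allowed to be missing per trait: a genotype may contribute a
secondary-trait record while its focal record is missing, which is exactly
how trait-assisted prediction recovers information on the validation set.

Variance components are estimated by REML.  Univariate fits use a single
eigendecomposition of the observed submatrix of A and a one-dimensional
heritability profile.  Bivariate fits maximize the observed-data REML
log-likelihood with guarded average-information (AI) updates: each AI step
is damped and step-halved until the log-likelihood increases, so the
iteration is monotone by construction (heavily damped early iterations
behave like small EM steps); iterates that leave the PSD cone are bent back
by eigenvalue clipping.  When both traits are observed on the same
genotypes, an equivalent canonical-transformation likelihood (one
eigendecomposition, O(n) per evaluation) is used instead for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genotypes import RelationshipMatrix

__all__ = [
    "RIDGE",
    "UnivariateFit",
    "Vcov2",
    "BivariateFit",
    "reml_univariate",
    "predict_unobserved",
    "reml_bivariate",
    "blup_given_components",
    "correlation_se",
]

#: ridge added to the diagonal of A at solve time (never stored in A)
RIDGE = 1e-6

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = list(trace or [])


class IdentifiabilityError(ValueError):
    pass


class ConditioningError(ValueError):
    pass


# ----------------------------------------------------------------------
# univariate GBLUP
# ----------------------------------------------------------------------

@dataclass
class UnivariateFit:
    mu: float
    sigma2_g: float
    sigma2_e: float
    h2_g: float
    gebv: pd.Series
    reml_loglik: float
    observed_ids: list = field(repr=False, default_factory=list)
    converged: bool = True


def _align_series(y, a: RelationshipMatrix) -> pd.Series:
    s = pd.Series(y, dtype=float)
    extra = set(map(str, s.index)) - set(a.genotype_ids)
    if extra:
        raise KeyError(f"phenotype ids not in relationship matrix: {sorted(extra)[:5]}")
    return s.reindex(a.genotype_ids)


def reml_univariate(y, a: RelationshipMatrix, *, ridge: float = RIDGE,
                    min_records: int = 30) -> UnivariateFit:
    """Single-trait GBLUP by REML on the eigenbasis of A.

    ``y`` is a Series indexed by genotype id (a subset of A's ids); missing
    records are NaN.  BLUP breeding values are returned for *all* genotypes
    in A — unobserved genotypes are predicted through their relationship to
    observed ones.

    Genomic heritability is the ratio of additive to phenotypic variance
    *as expressed in the phenotypes*: the additive variance of individual i
    under the model is A_ii sigma2_g, so h2_g = abar sigma2_g /
    (abar sigma2_g + sigma2_e) with abar the mean observed diagonal of A.
    (On an inbred panel the VanRaden GRM has abar ~ 2; for a kernel
    standardized to unit mean diagonal this reduces to the familiar
    sigma2_g / (sigma2_g + sigma2_e).)
    """
    y = _align_series(y, a)
    obs = y.notna().to_numpy()
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all records missing")
    if n_obs < min_records:
        raise ValueError(f"need >= {min_records} non-missing records, got {n_obs}")
    yo = y.to_numpy()[obs]
    a_r = a.values + ridge * np.eye(len(a.genotype_ids))
    aoo = a_r[np.ix_(obs, obs)]

    if np.var(yo) == 0.0:
        # nothing to explain: additive variance pinned at the lower bound
        gebv = pd.Series(0.0, index=a.genotype_ids)
        return UnivariateFit(mu=float(yo[0]), sigma2_g=0.0,
                             sigma2_e=float(np.var(yo, ddof=0)) or 1e-12,
                             h2_g=0.0, gebv=gebv, reml_loglik=np.nan,
                             observed_ids=list(np.array(a.genotype_ids)[obs]))

    d, u = np.linalg.eigh(aoo)
    yt = u.T @ yo
    xt = u.T @ np.ones(n_obs)

    def reml_ll(h: float) -> float:
        v = h * d + (1.0 - h)
        xv = xt / v
        sxx = float(xv @ xt)
        mu = float(xv @ yt) / sxx
        r = yt - mu * xt
        quad = float(r @ (r / v))
        s2 = quad / (n_obs - 1)
        return -0.5 * (np.log(v).sum() + np.log(sxx)
                       + (n_obs - 1) * (np.log(s2) + 1.0 + _LOG2PI))

    lo, hi = 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, 64)
    vals = np.array([reml_ll(h) for h in grid])
    i = int(vals.argmax())
    bl = grid[max(i - 1, 0)]
    bu = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda h: -reml_ll(h), bounds=(bl, bu),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    h = float(res.x)
    v = h * d + (1.0 - h)
    xv = xt / v
    sxx = float(xv @ xt)
    mu = float(xv @ yt) / sxx
    r = yt - mu * xt
    s2 = float(r @ (r / v)) / (n_obs - 1)
    sigma2_g, sigma2_e = h * s2, (1.0 - h) * s2
    abar = float(np.mean(np.diag(aoo)))
    h2_g = abar * sigma2_g / (abar * sigma2_g + sigma2_e)

    vinv_r = u @ (r / (v * s2))
    gebv_all = sigma2_g * (a_r[:, obs] @ vinv_r)
    gebv = pd.Series(gebv_all, index=a.genotype_ids)
    return UnivariateFit(mu=mu, sigma2_g=sigma2_g, sigma2_e=sigma2_e, h2_g=h2_g,
                         gebv=gebv, reml_loglik=float(reml_ll(h)),
                         observed_ids=list(np.array(a.genotype_ids)[obs]))


def predict_unobserved(fit: UnivariateFit, a: RelationshipMatrix,
                       observed_ids, query_ids, *,
                       ridge: float = RIDGE) -> pd.Series:
    """Conditional-expectation prediction A_qo (A_oo + ridge I)^-1 g_o.

    Identical (to solver precision) to the joint missing-record BLUP: both
    routes propagate the observed genotypes' breeding values through their
    genomic relationships.
    """
    oi = a.index_of(observed_ids)
    qi = a.index_of(query_ids)
    if set(oi) & set(qi):
        raise ValueError("query_ids must be disjoint from observed_ids")
    a_r = a.values + ridge * np.eye(len(a.genotype_ids))
    g_o = fit.gebv.iloc[oi].to_numpy()
    pred = a_r[np.ix_(qi, oi)] @ np.linalg.solve(a_r[np.ix_(oi, oi)], g_o)
    return pd.Series(pred, index=[a.genotype_ids[i] for i in qi])


# ----------------------------------------------------------------------
# bivariate GBLUP
# ----------------------------------------------------------------------

@dataclass
class Vcov2:
    """2x2 genetic or residual covariance matrix with derived correlation."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(2, 2)

    @property
    def correlation(self) -> float:
        den = np.sqrt(self.values[0, 0] * self.values[1, 1])
        return float(self.values[0, 1] / den) if den > 0 else np.nan


@dataclass
class BivariateFit:
    mu: np.ndarray
    G: Vcov2
    R: Vcov2
    gebv: pd.DataFrame
    cor_g: float
    cor_r: float
    reml_loglik: float
    converged: bool
    n_iter: int
    trace: list = field(repr=False, default_factory=list)
    se_cor_g: float = np.nan
    se_cor_r: float = np.nan
    # handles for post-fit standard-error computation
    _y: pd.DataFrame = field(repr=False, default=None)
    _a: RelationshipMatrix = field(repr=False, default=None)
    _ridge: float = field(repr=False, default=RIDGE)
    _free: np.ndarray = field(repr=False, default=None)


def _bend(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric 2x2 matrix to the PSD cone (eigenvalue clipping)."""
    w, v = np.linalg.eigh(m)
    lo = max(floor, 1e-6 * max(w.max(), floor))
    if w.min() >= lo:
        return m
    w = np.maximum(w, lo)
    return (v * w) @ v.T


def _theta_to_gr(theta):
    g = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    r = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return g, r


def _gr_to_theta(g, r):
    return np.array([g[0, 0], g[0, 1], g[1, 1], r[0, 0], r[0, 1], r[1, 1]])


class _ObsPattern:
    """Index bookkeeping for a bivariate missing-record layout."""

    def __init__(self, y: pd.DataFrame, a_r: np.ndarray):
        self.a_r = a_r
        m = y.notna().to_numpy()
        self.o1 = np.flatnonzero(m[:, 0])
        self.o2 = np.flatnonzero(m[:, 1])
        self.n1, self.n2 = len(self.o1), len(self.o2)
        self.m = self.n1 + self.n2
        self.y = np.concatenate([y.to_numpy()[self.o1, 0], y.to_numpy()[self.o2, 1]])
        # trait-intercept design (drop the column of a record-free trait)
        x = np.zeros((self.m, 2))
        x[:self.n1, 0] = 1.0
        x[self.n1:, 1] = 1.0
        self.active = [t for t, n in ((0, self.n1), (1, self.n2)) if n > 0]
        self.x = x[:, self.active]
        # overlap: positions of genotypes observed for both traits
        common = np.intersect1d(self.o1, self.o2)
        look1 = {g: i for i, g in enumerate(self.o1)}
        look2 = {g: i for i, g in enumerate(self.o2)}
        self.ov1 = np.array([look1[g] for g in common], dtype=int)
        self.ov2 = np.array([look2[g] for g in common], dtype=int)
        self.a11 = a_r[np.ix_(self.o1, self.o1)]
        self.a12 = a_r[np.ix_(self.o1, self.o2)]
        self.a22 = a_r[np.ix_(self.o2, self.o2)]

    def build_v(self, g, r) -> np.ndarray:
        v = np.empty((self.m, self.m))
        n1 = self.n1
        v[:n1, :n1] = g[0, 0] * self.a11
        v[:n1, :n1][np.diag_indices(n1)] += r[0, 0]
        v[n1:, n1:] = g[1, 1] * self.a22
        v[n1:, n1:][np.diag_indices(self.n2)] += r[1, 1]
        v12 = g[0, 1] * self.a12
        if self.ov1.size:
            v12[self.ov1, self.ov2] += r[0, 1]
        v[:n1, n1:] = v12
        v[n1:, :n1] = v12.T
        return v


def _reml_ll(pat: _ObsPattern, theta) -> float:
    g, r = _theta_to_gr(theta)
    v = pat.build_v(g, r)
    try:
        c = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(c[0])).sum()
    vix = linalg.cho_solve(c, pat.x, check_finite=False)
    xtvix = pat.x.T @ vix
    viy = linalg.cho_solve(c, pat.y, check_finite=False)
    xtviy = pat.x.T @ viy
    try:
        beta = np.linalg.solve(xtvix, xtviy)
    except np.linalg.LinAlgError:
        return -np.inf
    ypy = float(pat.y @ viy - xtviy @ beta)
    sign, ld2 = np.linalg.slogdet(xtvix)
    df = pat.m - pat.x.shape[1]
    return -0.5 * (logdet + ld2 + ypy + df * _LOG2PI)


def _reml_eval(pat: _ObsPattern, theta, free: np.ndarray):
    """Log-likelihood, score, and average-information matrix at theta."""
    g, r = _theta_to_gr(theta)
    v = pat.build_v(g, r)
    c = linalg.cho_factor(v, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c[0])).sum()
    vinv = linalg.cho_solve(c, np.eye(pat.m), check_finite=False)
    vix = vinv @ pat.x
    xtvix = pat.x.T @ vix
    xtvix_inv = np.linalg.inv(xtvix)
    p = vinv - vix @ xtvix_inv @ vix.T
    py = p @ pat.y
    n1 = pat.n1

    w1, w2 = py[:n1], py[n1:]
    # dV/dtheta_k applied to Py, for theta = (G11,G12,G22,R11,R12,R22)
    vk_py = np.zeros((6, pat.m))
    vk_py[0, :n1] = pat.a11 @ w1
    vk_py[1, :n1] = pat.a12 @ w2
    vk_py[1, n1:] = pat.a12.T @ w1
    vk_py[2, n1:] = pat.a22 @ w2
    vk_py[3, :n1] = w1
    if pat.ov1.size:
        vk_py[4, pat.ov1] = w2[pat.ov2]
        vk_py[4, n1 + pat.ov2] = w1[pat.ov1]
    vk_py[5, n1:] = w2

    tr = np.zeros(6)
    p11 = p[:n1, :n1]
    p12 = p[:n1, n1:]
    p22 = p[n1:, n1:]
    tr[0] = np.sum(p11 * pat.a11)
    tr[1] = 2.0 * np.sum(p12 * pat.a12)
    tr[2] = np.sum(p22 * pat.a22)
    tr[3] = np.trace(p11)
    if pat.ov1.size:
        tr[4] = 2.0 * np.sum(p12[pat.ov1, pat.ov2])
    tr[5] = np.trace(p22)

    score = -0.5 * (tr - vk_py @ py)
    pu = p @ vk_py.T
    ai = 0.5 * (vk_py @ pu)

    sign, ld2 = np.linalg.slogdet(xtvix)
    beta = xtvix_inv @ (pat.x.T @ (vinv @ pat.y))
    ypy = float(pat.y @ (vinv @ pat.y) - (pat.x.T @ (vinv @ pat.y)) @ beta)
    df = pat.m - pat.x.shape[1]
    ll = -0.5 * (logdet + ld2 + ypy + df * _LOG2PI)
    f = np.flatnonzero(free)
    return ll, score[f], ai[np.ix_(f, f)]


def _init_components(y: pd.DataFrame):
    yv = y.to_numpy()
    with warnings.catch_warnings():
        # a record-free trait yields an all-NaN column; handled just below
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(yv, axis=0, ddof=1)
    var = np.where(np.isfinite(var) & (var > 0), var, 1.0)
    both = np.all(~np.isnan(yv), axis=1)
    if both.sum() >= 3:
        cov = np.cov(yv[both, 0], yv[both, 1])[0, 1]
        cap = 0.9 * np.sqrt(var[0] * var[1])
        cov = float(np.clip(cov, -cap, cap))
    else:
        cov = 0.0
    s = np.array([[var[0], cov], [cov, var[1]]])
    return 0.5 * s, 0.5 * s


def _bend_theta(theta, frozen_value, free):
    g, r = _theta_to_gr(theta)
    out = _gr_to_theta(_bend(g), _bend(r))
    out[~free] = frozen_value[~free]
    return out


def reml_bivariate(y: pd.DataFrame, a: RelationshipMatrix, *,
                   ridge: float = RIDGE, max_iter: int = 1000,
                   ll_tol: float = 1e-8, par_tol: float = 1e-6,
                   min_records: int = 30, method: str = "auto",
                   init=None) -> BivariateFit:
    """Two-trait GBLUP REML with per-trait missing records.

    ``y`` has one column per trait, indexed by genotype id; NaN marks a
    missing record.  Returns intercepts, unstructured G and R, GEBVs for
    every genotype in A on both traits, and the genetic/residual
    correlations.  ``init`` optionally supplies starting ``(G, R)``
    matrices (e.g. the previous fold's estimates).

    A trait with *zero* records is tolerated as a degenerate case: its
    variance parameters stay at their starting values, cross-covariances
    are fixed at zero, and the observed trait's components are estimated —
    this makes the fit collapse exactly onto the univariate model.
    """
    if y.shape[1] != 2:
        raise ValueError("y must have exactly 2 trait columns")
    y = y.apply(pd.to_numeric).reindex(a.genotype_ids)
    counts = y.notna().sum().to_numpy()
    for t in range(2):
        if 0 < counts[t] < min_records:
            raise ValueError(
                f"trait {y.columns[t]!r} has {counts[t]} records; need >= {min_records}")
    if counts.min() == 0 and counts.max() == 0:
        raise ValueError("all records missing")
    both = y.notna().all(axis=1)
    if counts.min() > 0 and not both.any():
        raise IdentifiabilityError(
            "no genotype observed for both traits: cor_g is unidentifiable")

    n_all = len(a.genotype_ids)
    a_r = a.values + ridge * np.eye(n_all)
    pat = _ObsPattern(y, a_r)

    g0, r0 = _init_components(y) if init is None else (np.array(init[0], float),
                                                       np.array(init[1], float))
    free = np.ones(6, dtype=bool)
    if counts[0] == 0:
        free[[0, 1, 3, 4]] = False
        g0[0, 1] = r0[0, 1] = 0.0
    if counts[1] == 0:
        free[[1, 2, 4, 5]] = False
        g0[0, 1] = r0[0, 1] = 0.0
    theta0 = _gr_to_theta(_bend(g0), _bend(r0))

    complete = (counts.min() > 0 and pat.n1 == pat.n2
                and np.array_equal(pat.o1, pat.o2))
    if method == "auto":
        method = "canonical" if complete else "ai"
    if method == "canonical" and not complete:
        raise ValueError("canonical path requires complete records on both traits")

    if method == "canonical":
        theta, ll, n_iter, trace, converged = _fit_canonical(y, pat, theta0, max_iter)
    else:
        theta, ll, n_iter, trace, converged = _fit_ai(
            pat, theta0, free, max_iter, ll_tol, par_tol)

    g, r = _theta_to_gr(theta)
    mu, gebv = _blup(pat, y, a_r, g, r, a.genotype_ids, list(y.columns))
    fit = BivariateFit(mu=mu, G=Vcov2(g), R=Vcov2(r), gebv=gebv,
                       cor_g=Vcov2(g).correlation, cor_r=Vcov2(r).correlation,
                       reml_loglik=float(ll), converged=converged,
                       n_iter=n_iter, trace=trace,
                       _y=y, _a=a, _ridge=ridge, _free=free)
    return fit


def _fit_ai(pat, theta0, free, max_iter, ll_tol, par_tol):
    """Guarded average-information REML: monotone damped-Newton iteration."""
    theta = theta0.copy()
    ll, score, ai = _reml_eval(pat, theta, free)
    trace = [ll]
    lam = 1.0  # heavy early damping: EM-like short steps while far from optimum
    fidx = np.flatnonzero(free)
    converged = False
    slow = 0  # consecutive near-flat accepted steps (boundary crawl detector)
    for it in range(1, max_iter + 1):
        d = np.diag(ai).copy()
        d[d <= 0] = 1.0
        step = np.linalg.solve(ai + lam * np.diag(d) + 1e-12 * np.eye(len(d)), score)
        alpha, accepted = 1.0, False
        for _ in range(20):
            cand = theta.copy()
            cand[fidx] += alpha * step
            cand = _bend_theta(cand, theta0, free)
            ll_new = _reml_ll(pat, cand)
            if ll_new >= ll - 1e-12:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # Levenberg-style retry: heavier damping shortens and rotates the
            # step toward the gradient, which can slide along a bent boundary
            lam *= 100.0
            if lam > 1e8:
                converged = True
                break
            continue
        d_ll = ll_new - ll
        d_par = np.max(np.abs(cand - theta))
        if ll_new < ll - 1e-9:  # monotonicity guard
            raise ConvergenceError("REML log-likelihood decreased", trace)
        theta, ll = cand, ll_new
        trace.append(ll)
        lam = max(lam * 0.3, 1e-4)
        slow = slow + 1 if d_ll < 50.0 * ll_tol * (1.0 + abs(ll)) else 0
        if (d_ll < ll_tol * (1.0 + abs(ll)) and d_ll >= 0) or d_par < par_tol:
            converged = True
            break
        if slow >= 5:
            # crawling along the PSD boundary: likelihood gains are negligible
            converged = True
            break
        ll, score, ai = _reml_eval(pat, theta, free)
        ll = trace[-1]
    else:
        raise ConvergenceError(
            f"bivariate REML did not converge in {max_iter} iterations", trace)
    return theta, ll, len(trace) - 1, trace, converged


def _fit_canonical(y, pat, theta0, max_iter):
    """Complete-record fast path: canonical transformation of the eigenbasis."""
    d, u = np.linalg.eigh(pat.a11)
    yo = y.to_numpy()[pat.o1]
    yt = u.T @ yo                      # n x 2
    ut = u.T @ np.ones(pat.n1)

    def negll(x):
        g, r = _chol_to_gr(x)
        s11 = d * g[0, 0] + r[0, 0]
        s12 = d * g[0, 1] + r[0, 1]
        s22 = d * g[1, 1] + r[1, 1]
        det = s11 * s22 - s12 ** 2
        if (not np.all(np.isfinite(det))) or np.any(det <= 0) or np.any(s11 <= 0):
            return 1e12
        i11, i12, i22 = s22 / det, -s12 / det, s11 / det
        u2 = ut ** 2
        m = np.array([[np.sum(u2 * i11), np.sum(u2 * i12)],
                      [np.sum(u2 * i12), np.sum(u2 * i22)]])
        b = np.array([np.sum(ut * (i11 * yt[:, 0] + i12 * yt[:, 1])),
                      np.sum(ut * (i12 * yt[:, 0] + i22 * yt[:, 1]))])
        try:
            mu = np.linalg.solve(m, b)
        except np.linalg.LinAlgError:
            return 1e12
        r1 = yt[:, 0] - ut * mu[0]
        r2 = yt[:, 1] - ut * mu[1]
        quad = np.sum(i11 * r1 ** 2 + 2 * i12 * r1 * r2 + i22 * r2 ** 2)
        sign, ldm = np.linalg.slogdet(m)
        ll = -0.5 * (np.log(det).sum() + ldm + quad
                     + (2 * pat.n1 - 2) * _LOG2PI)
        return -ll

    x0 = _gr_to_chol(*_theta_to_gr(theta0))
    res = optimize.minimize(negll, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-13,
                                     "gtol": 1e-10})
    # derivative-free polish: evaluations are O(n), terminal accuracy matters
    res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                             options={"maxiter": 2000, "fatol": 1e-11,
                                      "xatol": 1e-9})
    best = res2 if res2.fun <= res.fun else res
    g, r = _chol_to_gr(best.x)
    ll = -float(best.fun)
    return (_gr_to_theta(g, r), ll, int(res.nit + res2.nit),
            [-float(negll(x0)), ll], True)


def _gr_to_chol(g, r):
    def enc(m):
        lam = np.linalg.cholesky(m + 1e-10 * np.eye(2))
        return [np.log(lam[0, 0]), lam[1, 0], np.log(lam[1, 1])]
    return np.array(enc(g) + enc(r))


def _chol_to_gr(x):
    def dec(a, b, c):
        # clip to keep exp/products finite; the likelihood is flat out here
        a, c = np.clip(a, -40.0, 40.0), np.clip(c, -40.0, 40.0)
        b = np.clip(b, -1e12, 1e12)
        lam = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        return lam @ lam.T
    return dec(*x[:3]), dec(*x[3:])


def _blup(pat: _ObsPattern, y, a_r, g, r, ids, traits):
    """GLS intercepts and joint BLUP breeding values for all genotypes."""
    v = pat.build_v(g, r)
    c = linalg.cho_factor(v, lower=True, check_finite=False)
    vix = linalg.cho_solve(c, pat.x, check_finite=False)
    xtvix = pat.x.T @ vix
    beta = np.linalg.solve(xtvix, pat.x.T @ linalg.cho_solve(c, pat.y,
                                                             check_finite=False))
    mu = np.full(2, np.nan)
    mu[pat.active] = beta
    resid = pat.y - pat.x @ beta
    w = linalg.cho_solve(c, resid, check_finite=False)
    w1, w2 = w[:pat.n1], w[pat.n1:]
    b1 = a_r[:, pat.o1] @ w1
    b2 = a_r[:, pat.o2] @ w2
    gebv = np.column_stack([g[0, 0] * b1 + g[0, 1] * b2,
                            g[1, 0] * b1 + g[1, 1] * b2])
    return mu, pd.DataFrame(gebv, index=ids, columns=traits)


def blup_given_components(y: pd.DataFrame, a: RelationshipMatrix,
                          g_cov, r_cov, *, ridge: float = RIDGE) -> pd.DataFrame:
    """Multi-trait BLUP at fixed G and R (the trait-assisted solve).

    Focal-trait GEBVs of genotypes whose focal record is missing draw on
    their own secondary-trait records: information flows through both the
    genetic and the residual trait covariances.
    """
    g = np.asarray(g_cov.values if isinstance(g_cov, Vcov2) else g_cov, float)
    r = np.asarray(r_cov.values if isinstance(r_cov, Vcov2) else r_cov, float)
    for name, m in (("G", g), ("R", r)):
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ConditioningError(f"{name} is not positive semi-definite")
    y = y.apply(pd.to_numeric).reindex(a.genotype_ids)
    a_r = a.values + ridge * np.eye(len(a.genotype_ids))
    pat = _ObsPattern(y, a_r)
    if pat.ov1.size and np.linalg.det(r) <= 0:
        raise ConditioningError(
            "R is singular for genotypes observing both traits")
    _, gebv = _blup(pat, y, a_r, g, r, a.genotype_ids, list(y.columns))
    return gebv


def correlation_se(fit: BivariateFit, *, rel_step: float = 1e-4):
    """Delta-method standard errors for (cor_g, cor_r).

    Approximates the observed information by central finite differences of
    the analytic REML score over the free covariance parameters, then
    propagates to the correlations.  Documented as an approximation: it is
    not the expected information of any particular REML software.
    """
    if fit._y is None:
        raise ValueError("fit does not carry its inputs; cannot compute SEs")
    a_r = fit._a.values + fit._ridge * np.eye(len(fit._a.genotype_ids))
    pat = _ObsPattern(fit._y, a_r)
    free = fit._free if fit._free is not None else np.ones(6, bool)
    fidx = np.flatnonzero(free)
    theta = _gr_to_theta(fit.G.values, fit.R.values)
    k = len(fidx)
    h = rel_step * (1.0 + np.abs(theta[fidx]))
    def score_at(t):
        _, s, _ = _reml_eval(pat, t, free)
        return s

    hess = np.zeros((k, k))
    for j, (pj, hj) in enumerate(zip(fidx, h)):
        col = None
        for _ in range(4):  # shrink the step if it crosses the PSD boundary
            tp, tm = theta.copy(), theta.copy()
            tp[pj] += hj
            tm[pj] -= hj
            try:
                col = (score_at(tp) - score_at(tm)) / (2.0 * hj)
                break
            except (linalg.LinAlgError, np.linalg.LinAlgError):
                hj /= 10.0
        if col is None:
            warnings.warn("observed information not computable; "
                          "correlation SEs undefined", stacklevel=2)
            fit.se_cor_g = fit.se_cor_r = np.nan
            return np.nan, np.nan
        hess[:, j] = col
    info = -0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; correlation SEs undefined",
                      stacklevel=2)
        fit.se_cor_g = fit.se_cor_r = np.nan
        return np.nan, np.nan

    cov_full = np.zeros((6, 6))
    cov_full[np.ix_(fidx, fidx)] = cov

    def delta(idx, m):
        v11, v12, v22 = m[0, 0], m[0, 1], m[1, 1]
        den = np.sqrt(v11 * v22)
        if den <= 0:
            return np.nan
        cor = v12 / den
        grad = np.zeros(6)
        grad[idx[0]] = -cor / (2.0 * v11)
        grad[idx[1]] = 1.0 / den
        grad[idx[2]] = -cor / (2.0 * v22)
        var = float(grad @ cov_full @ grad)
        return float(np.sqrt(max(var, 0.0)))

    fit.se_cor_g = delta((0, 1, 2), fit.G.values)
    fit.se_cor_r = delta((3, 4, 5), fit.R.values)
    return fit.se_cor_g, fit.se_cor_r
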