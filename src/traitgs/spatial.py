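"""Stage-1 spatial adjustment of field trials.

Per trait and trial the model is

    y_ij = mu + G_i + B_j + e_ij,

with the genotype effect G_i fixed, the block effect B_j ~ N(0, sigma2_b I)
random, and the plot residual field e either iid or separable first-order
autoregressive over the trial grid, e ~ N(0, sigma2_e AR1(rho_row) (x)
AR1(rho_col)).  Variance parameters are estimated by REML on orthonormal
error contrasts; candidate residual structures are compared by AIC
(penalising variance parameters only, so REML likelihoods are comparable:
all candidates share the same fixed effects).  Genotype BLUEs (adjusted
means) are generalized-least-squares estimates at the converged variance
components; multi-year adjusted means are per-year (optionally scaled)
BLUEs averaged over the years a genotype appears in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "Stage1Model",
    "Stage1Fit",
    "AdjustedMeans",
    "ar1_correlation",
    "stage1_loglik",
    "fit_stage1",
    "select_model",
    "combine_years",
]

_LOG2PI = np.log(2.0 * np.pi)


class PlotTableError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


class ScalingError(ValueError):
    pass


def ar1_correlation(rho: float, size: int) -> np.ndarray:
    """AR(1) correlation matrix: entry (i, j) = rho^|i-j|."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if size < 1:
        raise ValueError("size must be >= 1")
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class Stage1Model:
    """Fixed effects are always intercept + genotype; the rest is configurable."""

    include_block: bool = True
    residual_structure: str = "ar1xar1"

    def __post_init__(self):
        if self.residual_structure not in ("iid", "ar1xar1"):
            raise ValueError("residual_structure must be 'iid' or 'ar1xar1'")

    @property
    def n_variance_params(self) -> int:
        # sigma2_e always; sigma2_b if blocks; rho_row + rho_col if spatial
        return 1 + int(self.include_block) + 2 * (self.residual_structure == "ar1xar1")


@dataclass
class Stage1Fit:
    model: Stage1Model
    sigma2_b: float
    sigma2_e: float
    rho_row: float
    rho_col: float
    genotype_blues: pd.DataFrame   # columns: value, se
    reml_loglik: float
    aic: float
    n_params: int
    converged: bool = True
    trace: list = field(default_factory=list, repr=False)


@dataclass
class AdjustedMeans:
    """Per-genotype, per-trait combined means (the x-bar of stage 2)."""

    values: pd.DataFrame    # genotype x trait
    n_years: pd.DataFrame   # genotype x trait, contributing-year counts

    @classmethod
    def from_traits(cls, per_trait: dict) -> "AdjustedMeans":
        vals = pd.DataFrame({t: v for t, (v, _) in per_trait.items()})
        ny = pd.DataFrame({t: c for t, (_, c) in per_trait.items()})
        return cls(values=vals, n_years=ny.reindex(vals.index))


def _validate_plots(plots: pd.DataFrame, need_block: bool) -> pd.DataFrame:
    required = {"genotype", "row", "col", "value"}
    if need_block:
        required.add("block")
    missing = required - set(plots.columns)
    if missing:
        raise PlotTableError(f"plot table lacks columns {sorted(missing)}")
    for col in ("year", "trait"):
        if col in plots.columns and plots[col].nunique() > 1:
            raise PlotTableError(f"fit_stage1 expects a single {col}")
    if plots["genotype"].astype(str).str.len().eq(0).any():
        raise PlotTableError("empty genotype ids in plot table")
    if plots.duplicated(subset=["row", "col"]).any():
        raise PlotTableError("(row, col) positions must be unique within a trial")
    return plots.reset_index(drop=True)


def _spatial_corr(rows: np.ndarray, cols: np.ndarray, rho_row: float,
                  rho_col: float) -> np.ndarray:
    """Separable AR(1)xAR(1) correlation restricted to the observed plots.

    For a fully observed grid in row-major order this equals
    kron(AR1(rho_row), AR1(rho_col)); missing plots simply subset it.
    """
    nr, nc = rows.max(), cols.max()
    n = len(rows)
    if n == nr * nc:
        order = (rows - 1) * nc + (cols - 1)
        if np.array_equal(np.sort(order), np.arange(n)):
            full = np.kron(ar1_correlation(rho_row, nr), ar1_correlation(rho_col, nc))
            return full[np.ix_(order, order)]
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    pr = rho_row ** np.arange(dr.max() + 1)
    pc = rho_col ** np.arange(dc.max() + 1)
    return pr[dr] * pc[dc]


def _design(plots: pd.DataFrame, include_block: bool):
    geno = pd.Categorical(plots["genotype"].astype(str))
    levels = list(geno.categories)
    n = len(plots)
    x = np.zeros((n, len(levels)))
    x[np.arange(n), geno.codes] = 1.0
    x[:, 0] = 1.0  # treatment coding: intercept absorbs the reference genotype
    zb = None
    if include_block:
        blk = pd.Categorical(plots["block"].astype(str))
        if len(blk.categories) >= 2:
            zb = np.zeros((n, len(blk.categories)))
            zb[np.arange(n), blk.codes] = 1.0
    return x, zb, levels


def stage1_loglik(plots: pd.DataFrame, model: Stage1Model, sigma2_b: float,
                  sigma2_e: float, rho_row: float = 0.0,
                  rho_col: float = 0.0) -> float:
    """REML log-likelihood (orthonormal error contrasts) at given components."""
    plots = _validate_plots(plots, model.include_block)
    x, zb, _ = _design(plots, model.include_block)
    rows = plots["row"].to_numpy(int)
    cols = plots["col"].to_numpy(int)
    if model.residual_structure == "ar1xar1":
        r = _spatial_corr(rows, cols, rho_row, rho_col)
    else:
        r = np.eye(len(plots))
    sigma = sigma2_e * r
    if zb is not None and sigma2_b > 0:
        sigma = sigma + sigma2_b * (zb @ zb.T)
    q, _ = np.linalg.qr(x, mode="complete")
    b = q[:, np.linalg.matrix_rank(x):]
    s = b.T @ sigma @ b
    yb = b.T @ plots["value"].to_numpy(float)
    sign, logdet = np.linalg.slogdet(s)
    quad = yb @ np.linalg.solve(s, yb)
    df = b.shape[1]
    return -0.5 * (logdet + quad + df * _LOG2PI)


def fit_stage1(plots: pd.DataFrame, model: Stage1Model, *,
               max_iter: int = 4000, ll_tol: float = 1e-8,
               rho_starts=(0.0, 0.5, -0.5)) -> Stage1Fit:
    """REML fit of the stage-1 model on one trial and one trait.

    The residual variance is profiled out analytically; the remaining free
    parameters (block-to-residual variance ratio on a log scale, AR(1)
    correlations on an atanh scale) are optimized by Nelder--Mead from
    multiple starts for each correlation.
    """
    plots = _validate_plots(plots, model.include_block)
    y = plots["value"].to_numpy(float)
    rows = plots["row"].to_numpy(int)
    cols = plots["col"].to_numpy(int)
    x, zb, levels = _design(plots, model.include_block)
    n, p = x.shape

    r_diag = np.abs(np.diag(linalg.qr(x, mode="r", pivoting=True)[0]))
    if (r_diag < 1e-8 * r_diag.max()).any():
        raise PlotTableError("singular fixed-effects design (aliased genotypes)")
    if n - p < 2:
        raise PlotTableError(
            f"only {n - p} error contrasts: too few plots ({n}) for {p} fixed effects"
        )

    q, _ = np.linalg.qr(x, mode="complete")
    b = q[:, p:]
    yb = b.T @ y
    df = n - p
    bz = b.T @ zb if zb is not None else None
    has_block = bz is not None
    spatial = model.residual_structure == "ar1xar1"
    # two algebraically equivalent REML routes (likelihoods differ by the
    # theta-independent constant 0.5 log|X'X|): project onto error contrasts
    # when few remain, otherwise profile through the fixed-effects solve
    use_contrasts = df <= p

    def unpack(theta):
        i = 0
        gamma = 0.0
        rr = rc = 0.0
        if has_block:
            gamma = np.exp(theta[i]); i += 1
        if spatial:
            rr = np.tanh(theta[i]); rc = np.tanh(theta[i + 1])
        return gamma, rr, rc

    def profiled_negll(theta):
        gamma, rr, rc = unpack(theta)
        corr = _spatial_corr(rows, cols, rr, rc) if spatial else np.eye(n)
        if use_contrasts:
            s = b.T @ corr @ b
            if has_block:
                s = s + gamma * (bz @ bz.T)
            try:
                c = linalg.cho_factor(s, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return 1e12
            logdet = 2.0 * np.log(np.diag(c[0])).sum()
            quad = yb @ linalg.cho_solve(c, yb, check_finite=False)
        else:
            k = corr
            if has_block:
                k = k + gamma * (zb @ zb.T)
            try:
                ck = linalg.cho_factor(k, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return 1e12
            kix = linalg.cho_solve(ck, x, check_finite=False)
            kiy = linalg.cho_solve(ck, y, check_finite=False)
            xtkix = x.T @ kix
            try:
                cf = linalg.cho_factor(xtkix, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return 1e12
            xtkiy = x.T @ kiy
            quad = float(y @ kiy - xtkiy @ linalg.cho_solve(cf, xtkiy,
                                                            check_finite=False))
            logdet = (2.0 * np.log(np.diag(ck[0])).sum()
                      + 2.0 * np.log(np.diag(cf[0])).sum())
        if quad <= 0:
            return 1e12
        s2 = quad / df
        return 0.5 * (logdet + df * np.log(s2) + df * (1.0 + _LOG2PI))

    n_free = int(has_block) + 2 * int(spatial)
    trace: list = []
    if n_free == 0:
        theta_hat = np.array([])
        converged = True
    else:
        starts = []
        g0 = np.log(0.2)
        if spatial:
            for r1 in rho_starts:
                for r2 in rho_starts:
                    t = ([g0] if has_block else []) + [np.arctanh(r1), np.arctanh(r2)]
                    starts.append(np.array(t))
        else:
            starts.append(np.array([g0]))
        starts.sort(key=profiled_negll)
        best = None
        for s0 in starts[:2]:
            res = optimize.minimize(profiled_negll, s0, method="Nelder-Mead",
                                    options={"fatol": ll_tol, "xatol": 1e-6,
                                             "maxiter": max_iter,
                                             "maxfev": 2 * max_iter})
            trace.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        if not best.success:
            raise ConvergenceError(
                f"stage-1 REML did not converge: {best.message}", trace)
        theta_hat = best.x
        converged = bool(best.success)

    gamma, rr, rc = unpack(theta_hat)
    corr = _spatial_corr(rows, cols, rr, rc) if spatial else np.eye(n)
    s = b.T @ corr @ b
    if has_block:
        s = s + gamma * (bz @ bz.T)
    c = linalg.cho_factor(s, lower=True, check_finite=False)
    sigma2_e = float(yb @ linalg.cho_solve(c, yb) / df)
    sigma2_b = float(gamma * sigma2_e) if has_block else 0.0

    # GLS genotype BLUEs at the converged components
    v = sigma2_e * corr
    if has_block:
        v = v + sigma2_b * (zb @ zb.T)
    cv = linalg.cho_factor(v, lower=True, check_finite=False)
    vix = linalg.cho_solve(cv, x, check_finite=False)
    xtvix = x.T @ vix
    beta_cov = np.linalg.inv(xtvix)
    beta = beta_cov @ (vix.T @ y)
    mu = beta[0]
    effects = np.concatenate([[0.0], beta[1:]])
    blues = mu + effects
    var = np.empty(p)
    var[0] = beta_cov[0, 0]
    var[1:] = beta_cov[0, 0] + np.diag(beta_cov)[1:] + 2.0 * beta_cov[0, 1:]
    blues_df = pd.DataFrame({"value": blues, "se": np.sqrt(np.maximum(var, 0))},
                            index=pd.Index(levels, name="genotype"))

    ll = stage1_loglik(plots, model, sigma2_b, sigma2_e, rr, rc)
    n_params = model.n_variance_params
    return Stage1Fit(model=model, sigma2_b=sigma2_b, sigma2_e=sigma2_e,
                     rho_row=float(rr), rho_col=float(rc),
                     genotype_blues=blues_df, reml_loglik=float(ll),
                     aic=float(-2.0 * ll + 2.0 * n_params), n_params=n_params,
                     converged=converged, trace=trace)


def select_model(plots: pd.DataFrame, candidates) -> Stage1Fit:
    """Fit all candidate models; return the minimum-AIC fit.

    Ties break toward fewer variance parameters, then earlier position in
    the candidate list.  Candidates that fail to converge are skipped with
    a warning; if all fail an error is raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits = []
    for pos, m in enumerate(candidates):
        try:
            fits.append((pos, fit_stage1(plots, m)))
        except (ConvergenceError, np.linalg.LinAlgError) as e:
            warnings.warn(f"candidate {pos} ({m.residual_structure}) failed: {e}",
                          stacklevel=2)
    if not fits:
        raise ConvergenceError("all stage-1 candidate models failed")
    return min(fits, key=lambda pf: (round(pf[1].aic, 10), pf[1].n_params, pf[0]))[1]


def combine_years(per_year_blues: dict, scaling: str = "standardize"):
    """Combine per-year genotype BLUEs into adjusted means x-bar.

    ``per_year_blues`` maps year label -> Stage1Fit (or a plain Series of
    BLUEs).  Per year the BLUEs are transformed according to ``scaling``
    ('none', 'center', or 'standardize' = center and divide by that year's
    standard deviation of BLUEs); x-bar is the mean of a genotype's
    transformed values over the years it appears in.

    Returns ``(xbar, n_years)`` as aligned Series.
    """
    if scaling not in ("none", "center", "standardize"):
        raise ValueError("scaling must be one of none|center|standardize")
    if not per_year_blues:
        raise ValueError("need at least one year of BLUEs")
    cols = {}
    for year, fit in per_year_blues.items():
        s = fit.genotype_blues["value"] if isinstance(fit, Stage1Fit) else pd.Series(fit)
        if scaling in ("center", "standardize"):
            s = s - s.mean()
        if scaling == "standardize":
            sd = s.std(ddof=1)
            if not sd > 0:
                raise ScalingError(f"zero within-year variance in year {year!r}")
            s = s / sd
        cols[str(year)] = s
    wide = pd.DataFrame(cols)
    return wide.mean(axis=1), wide.notna().sum(axis=1)
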