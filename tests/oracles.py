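"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available
(dense matrices, explicit mixed-model equations, elementwise covariance
construction) and stays independent of the library code paths it checks.
"""

import numpy as np
import pandas as pd
from scipy.linalg import null_space

_LOG2PI = np.log(2.0 * np.pi)


def vanraden_brute(dosages: np.ndarray) -> np.ndarray:
    """Elementwise VanRaden method-1 GRM: sum_k (x_ik-2p_k)(x_jk-2p_k) / (2 sum p q)."""
    n, m = dosages.shape
    p = dosages.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    scale = 2.0 * sum(p[k] * (1 - p[k]) for k in range(m) if poly[k])
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = sum((dosages[i, k] - 2 * p[k]) * (dosages[j, k] - 2 * p[k])
                          for k in range(m)) / scale
    return a


def univariate_mme(y_obs, obs_idx, a_ridged, sigma2_g, sigma2_e):
    """Dense single-trait mixed-model equations: returns (mu, g for all genotypes)."""
    n = a_ridged.shape[0]
    m = len(obs_idx)
    z = np.zeros((m, n))
    z[np.arange(m), obs_idx] = 1.0
    x = np.ones((m, 1))
    ainv = np.linalg.inv(a_ridged)
    c = np.block([
        [x.T @ x / sigma2_e, x.T @ z / sigma2_e],
        [z.T @ x / sigma2_e, z.T @ z / sigma2_e + ainv / sigma2_g],
    ])
    rhs = np.concatenate([x.T @ y_obs, z.T @ y_obs]) / sigma2_e
    sol = np.linalg.solve(c, rhs)
    return sol[0], sol[1:]


def bivariate_mme(y: pd.DataFrame, a_ridged, g_cov, r_cov):
    """Dense two-trait MME with per-genotype residual blocks.

    Records are stacked trait-major; genotype effects g = (g_trait1,
    g_trait2) have covariance G (x) A.  Returns (mu, gebv n x 2).
    """
    n = a_ridged.shape[0]
    yv = y.to_numpy()
    obs = [(t, i) for t in range(2) for i in range(n) if not np.isnan(yv[i, t])]
    m = len(obs)
    x = np.zeros((m, 2))
    z = np.zeros((m, 2 * n))
    yo = np.zeros(m)
    for r, (t, i) in enumerate(obs):
        x[r, t] = 1.0
        z[r, t * n + i] = 1.0
        yo[r] = yv[i, t]
    active = [t for t in range(2) if any(o[0] == t for o in obs)]
    x = x[:, active]
    # residual precision: per genotype, invert R restricted to observed traits
    rinv = np.zeros((m, m))
    rows_of = {}
    for r, (t, i) in enumerate(obs):
        rows_of.setdefault(i, []).append((t, r))
    for i, entries in rows_of.items():
        ts = [t for t, _ in entries]
        rs = [r for _, r in entries]
        block = np.linalg.inv(np.asarray(r_cov)[np.ix_(ts, ts)])
        for a_, ra in enumerate(rs):
            for b_, rb in enumerate(rs):
                rinv[ra, rb] = block[a_, b_]
    ginv_kron = np.kron(np.linalg.inv(g_cov), np.linalg.inv(a_ridged))
    c = np.block([
        [x.T @ rinv @ x, x.T @ rinv @ z],
        [z.T @ rinv @ x, z.T @ rinv @ z + ginv_kron],
    ])
    rhs = np.concatenate([x.T @ rinv @ yo, z.T @ rinv @ yo])
    sol = np.linalg.solve(c, rhs)
    mu = np.full(2, np.nan)
    mu[active] = sol[: len(active)]
    g = sol[len(active):]
    return mu, np.column_stack([g[:n], g[n:]])


def stage1_dense_loglik(plots: pd.DataFrame, sigma2_b, sigma2_e, rho_row,
                        rho_col, *, iid=False, include_block=True):
    """REML log-likelihood from a dense, elementwise covariance construction."""
    plots = plots.reset_index(drop=True)
    y = plots["value"].to_numpy(float)
    rows = plots["row"].to_numpy(int)
    cols = plots["col"].to_numpy(int)
    n = len(plots)
    geno = sorted(plots["genotype"].astype(str).unique())
    x = np.zeros((n, len(geno)))
    for r in range(n):
        x[r, geno.index(str(plots.loc[r, "genotype"]))] = 1.0
    sigma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if iid:
                corr = 1.0 if i == j else 0.0
            else:
                corr = (rho_row ** abs(rows[i] - rows[j])
                        * rho_col ** abs(cols[i] - cols[j]))
            sigma[i, j] = sigma2_e * corr
            if include_block and plots.loc[i, "block"] == plots.loc[j, "block"]:
                sigma[i, j] += sigma2_b
    b = null_space(x.T)
    s = b.T @ sigma @ b
    yb = b.T @ y
    _, logdet = np.linalg.slogdet(s)
    quad = yb @ np.linalg.solve(s, yb)
    return -0.5 * (logdet + quad + b.shape[1] * _LOG2PI)
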