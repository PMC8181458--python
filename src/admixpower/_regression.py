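"""Batched per-locus regression solvers.

A genome scan is thousands of tiny regressions that share the response
and the covariates and differ only in the genotype column.  These
solvers exploit that structure:

- linear: Frisch–Waugh–Lovell — residualize the response and every
  genotype column against the shared covariates once, then the per-locus
  slope, standard error, and t-test come from columnwise inner products.
  This is exact OLS, not an approximation.
- logistic: Newton–Raphson iterations run simultaneously across loci;
  each locus has its own small coefficient vector and 3x3 (at most)
  Hessian, solved as a batched linear system.

Both return NaN statistics with ``tested=False`` for loci whose genotype
column is constant (monomorphic) or collinear with the covariates, and
the logistic solver additionally flags loci that fail to converge within
the iteration cap or whose fitted effect diverges (separation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

MAX_LOGISTIC_ITER = 100
LOGISTIC_TOL = 1e-8
#: |beta| beyond this on the log-odds scale is treated as (quasi-)separation.
SEPARATION_BOUND = 50.0


@dataclass
class ScanStats:
    beta: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    tested: np.ndarray


def _shared_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    return np.column_stack(cols)


def linear_scan_stats(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    tested_mask: np.ndarray | None = None,
) -> ScanStats:
    """Exact per-locus OLS of y on [1, covariates, g] via FWL residualization."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_loci = g.shape
    x = _shared_design(n, covariates)
    k = x.shape[1] + 1  # + genotype column
    if n <= k:
        raise ValueError("need more observations than parameters")

    # residualize against the shared design
    q, _ = np.linalg.qr(x)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    gy = y_r @ g_r
    # collinear/monomorphic columns have ~zero residual variance
    ok = gg > n * np.finfo(float).eps * max(1.0, float(np.max(gg, initial=0.0)))
    if tested_mask is not None:
        ok &= np.asarray(tested_mask, dtype=bool)

    beta = np.full(n_loci, np.nan)
    se = np.full(n_loci, np.nan)
    p = np.full(n_loci, np.nan)
    df = n - k
    beta[ok] = gy[ok] / gg[ok]
    rss = np.maximum(y_r @ y_r - beta[ok] ** 2 * gg[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / gg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    # a perfect fit gives se = 0: report p = 0-adjacent rather than NaN
    p[ok & (se == 0.0)] = 0.0
    return ScanStats(beta=beta, se=se, p_value=p, tested=ok)


def logistic_scan_stats(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    tested_mask: np.ndarray | None = None,
    max_iter: int = MAX_LOGISTIC_ITER,
    tol: float = LOGISTIC_TOL,
) -> ScanStats:
    """Per-locus logistic regression (batched Newton–Raphson), Wald p-values."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_loci = g.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic scan requires a 0/1 response")
    x = _shared_design(n, covariates)  # (n, k0)
    k0 = x.shape[1]
    k = k0 + 1

    ok = np.ptp(g, axis=0) > 0
    if tested_mask is not None:
        ok &= np.asarray(tested_mask, dtype=bool)
    idx = np.flatnonzero(ok)
    beta_out = np.full(n_loci, np.nan)
    se_out = np.full(n_loci, np.nan)
    p_out = np.full(n_loci, np.nan)
    tested = np.zeros(n_loci, dtype=bool)
    if idx.size == 0:
        return ScanStats(beta_out, se_out, p_out, tested)

    gs = g[:, idx]  # (n, L)
    L = idx.size
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    coef = np.zeros((L, k))
    coef[:, 0] = np.log(ybar / (1.0 - ybar))

    active = np.ones(L, dtype=bool)
    failed = np.zeros(L, dtype=bool)
    hess = np.empty((L, k, k))
    score = np.empty((L, k))

    for _ in range(max_iter):
        a = np.flatnonzero(active)
        if a.size == 0:
            break
        ga = gs[:, a]  # (n, La)
        ca = coef[a]  # (La, k)
        eta = x @ ca[:, :k0].T + ga * ca[:, k0]  # (n, La)
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu

        sc = score[a]
        sc[:, :k0] = resid.T @ x
        sc[:, k0] = np.einsum("nl,nl->l", resid, ga)

        h = hess[a]
        # shared-design block: x^T diag(w_l) x for each locus l
        h[:, :k0, :k0] = np.einsum("ni,nl,nj->lij", x, w, x, optimize=True)
        wg = w * ga
        h[:, :k0, k0] = wg.T @ x
        h[:, k0, :k0] = h[:, :k0, k0]
        h[:, k0, k0] = np.einsum("nl,nl->l", wg, ga)

        det = np.linalg.det(h)
        bad = ~np.isfinite(det) | (np.abs(det) < 1e-300)
        if np.any(bad):
            failed[a[bad]] = True
            active[a[bad]] = False
            good = ~bad
            a, sc, h = a[good], sc[good], h[good]
            if a.size == 0:
                continue
        step = np.linalg.solve(h, sc[..., None])[..., 0]
        coef[a] += step
        moved = np.max(np.abs(step), axis=1)
        diverged = np.abs(coef[a, k0]) > SEPARATION_BOUND
        failed[a[diverged]] = True
        active[a[diverged]] = False
        active[a[(moved < tol) & ~diverged]] = False
    else:
        never = active.copy()
        failed |= never
        if np.any(never):
            logger.warning(
                "logistic scan: %d loci failed to converge in %d iterations "
                "(likely separation); marked untested",
                int(never.sum()),
                max_iter,
            )
    if np.any(failed):
        logger.info(
            "logistic scan: %d of %d loci flagged untested (singular or "
            "separated fits)",
            int(failed.sum()),
            L,
        )

    conv = np.flatnonzero(~failed)
    if conv.size:
        ga = gs[:, conv]
        ca = coef[conv]
        eta = x @ ca[:, :k0].T + ga * ca[:, k0]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        h = np.empty((conv.size, k, k))
        h[:, :k0, :k0] = np.einsum("ni,nl,nj->lij", x, w, x, optimize=True)
        wg = w * ga
        h[:, :k0, k0] = wg.T @ x
        h[:, k0, :k0] = h[:, :k0, k0]
        h[:, k0, k0] = np.einsum("nl,nl->l", wg, ga)
        det = np.linalg.det(h)
        solvable = np.isfinite(det) & (np.abs(det) > 1e-300)
        var_g = np.full(conv.size, np.nan)
        if np.any(solvable):
            cov = np.linalg.inv(h[solvable])
            var_g[solvable] = cov[:, k0, k0]
        good_var = np.isfinite(var_g) & (var_g > 0)
        conv = conv[good_var]
        if conv.size:
            b = coef[conv, k0]
            s = np.sqrt(var_g[good_var])
            z = b / s
            loci = idx[conv]
            beta_out[loci] = b
            se_out[loci] = s
            p_out[loci] = 2.0 * stats.norm.sf(np.abs(z))
            tested[loci] = True
    return ScanStats(beta_out, se_out, p_out, tested)
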