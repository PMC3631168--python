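"""Numba kernels shared by the statistic, comparator and harness modules.

Everything here operates on raw (unstandardized) dosage blocks.  The key
observation making bootstrap/permutation loops cheap is that the two-block
PLS path fit depends on the data only through the within- and cross-block
correlation matrices: after per-stratum standardization the outer estimate is
``xi = X w_a / sd(X w_a)``, the centroid inner sign is ``sign(w_a' C w_b)``
and the mode-A weight update is proportional to ``C w_b`` / ``C' w_a``.  Each
resampled fit therefore reduces to one cross-product of an (n x m) block
followed by a handful of operations on (p x q) matrices.

All randomness is drawn from numba's internal np.random state, seeded
explicitly at the top of every kernel, so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# statistic kinds understood by the generic resampling kernels
STAT_PLSPM = 0
STAT_CC1 = 1

_SD_EPS = 1e-12


@njit(cache=True)
def corr_from_raw(Z):
    """Correlation matrix (divisor n-1) of the columns of Z.

    Returns ``(R, sd, mu, ok)``; ``ok`` is False when a column is constant.
    """
    n, m = Z.shape
    mu = np.empty(m)
    for j in range(m):
        mu[j] = Z[:, j].mean()
    Zc = Z - mu
    S = Zc.T @ Zc / (n - 1)
    sd = np.empty(m)
    ok = True
    for j in range(m):
        v = S[j, j]
        if v < _SD_EPS:
            ok = False
            sd[j] = 0.0
        else:
            sd[j] = np.sqrt(v)
    R = np.empty((m, m))
    if ok:
        for j in range(m):
            for k in range(m):
                R[j, k] = S[j, k] / (sd[j] * sd[k])
    return R, sd, mu, ok


@njit(cache=True)
def plspm_weights(Rxx, Ryy, C, tol, max_iter, init_a, init_b):
    """Mode-A / centroid two-block PLS fit in correlation space.

    Alternates the outer estimation (latent scores as weighted block sums,
    rescaled to unit variance), the centroid inner estimation (sign ``e`` of
    the score correlation) and the mode-A weight update (correlation of each
    indicator with the inner estimate, weight vector rescaled to unit norm)
    until the largest absolute weight change drops below ``tol``.

    After convergence each weight vector is flipped, if needed, so that its
    largest-magnitude component is positive: two-block PLS is otherwise
    sign-indeterminate, and the co-association statistic subtracts path
    coefficients across strata, so a deterministic orientation is required.

    Returns ``(w_a, w_b, beta, s_a, s_b, n_iter, converged, e)`` where
    ``s_a, s_b`` are the standard deviations of the unscaled scores
    ``X w_a`` / ``Y w_b`` and ``beta`` is the score correlation.
    """
    p = C.shape[0]
    q = C.shape[1]
    wa = init_a.copy()
    wb = init_b.copy()
    e = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = wa @ C @ wb
        if num > 0.0:
            e = 1.0
        elif num < 0.0:
            e = -1.0
        else:
            e = 1.0  # exact zero correlation: centroid sign defaults to +1
        wa_new = e * (C @ wb)
        na = np.sqrt((wa_new * wa_new).sum())
        if na < 1e-300:
            wa_new = wa.copy()
        else:
            wa_new = wa_new / na
        wb_new = e * (C.T @ wa)
        nb = np.sqrt((wb_new * wb_new).sum())
        if nb < 1e-300:
            wb_new = wb.copy()
        else:
            wb_new = wb_new / nb
        d = 0.0
        for j in range(p):
            dj = abs(wa_new[j] - wa[j])
            if dj > d:
                d = dj
        for k in range(q):
            dk = abs(wb_new[k] - wb[k])
            if dk > d:
                d = dk
        wa = wa_new
        wb = wb_new
        if d < tol:
            converged = True
            break
    # deterministic orientation: largest-|w| component positive per block
    ia = 0
    for j in range(1, p):
        if abs(wa[j]) > abs(wa[ia]):
            ia = j
    if wa[ia] < 0.0:
        wa = -wa
    ib = 0
    for k in range(1, q):
        if abs(wb[k]) > abs(wb[ib]):
            ib = k
    if wb[ib] < 0.0:
        wb = -wb
    sa = np.sqrt(wa @ Rxx @ wa)
    sb = np.sqrt(wb @ Ryy @ wb)
    beta = (wa @ C @ wb) / (sa * sb)
    if beta > 1.0:
        beta = 1.0
    elif beta < -1.0:
        beta = -1.0
    return wa, wb, beta, sa, sb, it, converged, e


@njit(cache=True)
def cc1_from_corr(Rxx, Ryy, C, ridge):
    """First canonical correlation from correlation matrices.

    Computed as the largest singular value of ``Lx^-1 C Ly^-T`` with
    ``Lx Lx' = Rxx``; when a within-block matrix is numerically singular a
    ridge is added to its diagonal (returned flag reports it).
    """
    p = Rxx.shape[0]
    q = Ryy.shape[0]
    ridged = False
    ex = np.linalg.eigvalsh(Rxx)
    Rx = Rxx.copy()
    if ex[0] < 1e-8:
        for j in range(p):
            Rx[j, j] += ridge
        ridged = True
    ey = np.linalg.eigvalsh(Ryy)
    Ry = Ryy.copy()
    if ey[0] < 1e-8:
        for k in range(q):
            Ry[k, k] += ridge
        ridged = True
    Lx = np.linalg.cholesky(Rx)
    Ly = np.linalg.cholesky(Ry)
    M = np.linalg.solve(Lx, C)          # Lx^-1 C
    K = np.linalg.solve(Ly, M.T).T      # (Lx^-1 C) Ly^-T
    s = np.linalg.svd(K)[1]
    cc1 = s[0]
    if cc1 > 1.0:
        cc1 = 1.0
    return cc1, ridged


@njit(cache=True)
def stratum_stat(Z, p, kind, tol, max_iter):
    """Statistic (path coefficient or cc1) plus loadings for one stratum.

    Returns ``(stat, loadings, ok)``.  Loadings are the correlations of every
    column with its own latent score (PLSPM kind only; zeros for cc1).
    """
    m = Z.shape[1]
    q = m - p
    loadings = np.zeros(m)
    R, sd, mu, ok = corr_from_raw(Z)
    if not ok:
        return 0.0, loadings, False
    Rxx = np.ascontiguousarray(R[:p, :p])
    Ryy = np.ascontiguousarray(R[p:, p:])
    C = np.ascontiguousarray(R[:p, p:])
    if kind == STAT_CC1:
        cc1, _ = cc1_from_corr(Rxx, Ryy, C, 1e-8)
        return cc1, loadings, True
    init_a = np.full(p, 1.0 / np.sqrt(p))
    init_b = np.full(q, 1.0 / np.sqrt(q))
    wa, wb, beta, sa, sb, it, conv, e = plspm_weights(Rxx, Ryy, C, tol, max_iter, init_a, init_b)
    la = Rxx @ wa / sa
    lb = Ryy @ wb / sb
    for j in range(p):
        loadings[j] = la[j]
    for k in range(q):
        loadings[p + k] = lb[k]
    return beta, loadings, True


@njit(cache=True)
def bootstrap_stats(Z, p, kind, n_boot, seed, tol, max_iter, max_fail):
    """Bootstrap the stratum statistic: resample rows with replacement.

    Replicates whose resample makes a column constant are redrawn; the redraw
    count is returned.  Gives the replicate statistics and, for the PLSPM
    kind, the replicate loadings (n_boot x m).
    """
    np.random.seed(seed)
    n = Z.shape[0]
    m = Z.shape[1]
    stats = np.empty(n_boot)
    loadings = np.empty((n_boot, m))
    fails = 0
    b = 0
    while b < n_boot:
        idx = np.random.randint(0, n, n)
        Zb = Z[idx]
        s, lo, ok = stratum_stat(Zb, p, kind, tol, max_iter)
        if not ok:
            fails += 1
            if fails > max_fail:
                return stats, loadings, fails, False
            continue
        stats[b] = s
        loadings[b] = lo
        b += 1
    return stats, loadings, fails, True


@njit(cache=True)
def perm_stat_diffs(Zall, p, n_case, kind, n_perm, seed, tol, max_iter):
    """Label-permutation differences of the per-stratum statistic.

    For each permutation the pooled rows are split into a pseudo-case group
    of size ``n_case`` and a pseudo-control remainder, and the statistic
    difference (case minus control) is recorded.  Permutations where either
    pseudo-stratum has a constant column are redrawn (up to 100 times each,
    after which NaN is stored).
    """
    np.random.seed(seed)
    N = Zall.shape[0]
    out = np.empty(n_perm)
    redraws = 0
    for t in range(n_perm):
        val = np.nan
        for _attempt in range(100):
            idx = np.random.permutation(N)
            Zc = Zall[idx[:n_case]]
            Zk = Zall[idx[n_case:]]
            sc, _, ok1 = stratum_stat(Zc, p, kind, tol, max_iter)
            if not ok1:
                redraws += 1
                continue
            sk, _, ok2 = stratum_stat(Zk, p, kind, tol, max_iter)
            if not ok2:
                redraws += 1
                continue
            val = sc - sk
            break
        out[t] = val
    return out, redraws


@njit(cache=True)
def perm_full_U(Zall, p, n_case, kind, n_perm, n_boot_inner, seed, tol, max_iter):
    """Label-permutation U* with the denominator re-bootstrapped per permutation."""
    np.random.seed(seed)
    N = Zall.shape[0]
    out = np.empty(n_perm)
    for t in range(n_perm):
        val = np.nan
        for _attempt in range(100):
            idx = np.random.permutation(N)
            Zc = Zall[idx[:n_case]]
            Zk = Zall[idx[n_case:]]
            sc, _, ok1 = stratum_stat(Zc, p, kind, tol, max_iter)
            sk, _, ok2 = stratum_stat(Zk, p, kind, tol, max_iter)
            if not (ok1 and ok2):
                continue
            bseed_c = np.random.randint(0, 2**31 - 1)
            bseed_k = np.random.randint(0, 2**31 - 1)
            bc, _, _, okb1 = bootstrap_stats(Zc, p, kind, n_boot_inner, bseed_c, tol, max_iter, n_boot_inner)
            bk, _, _, okb2 = bootstrap_stats(Zk, p, kind, n_boot_inner, bseed_k, tol, max_iter, n_boot_inner)
            if not (okb1 and okb2):
                continue
            vc = bc.var()
            vk = bk.var()
            # unbiased variance
            vc = vc * n_boot_inner / (n_boot_inner - 1)
            vk = vk * n_boot_inner / (n_boot_inner - 1)
            denom = np.sqrt(vc + vk)
            if denom < 1e-15:
                val = 0.0 if sc == sk else np.inf
            else:
                val = (sc - sk) / denom
            break
        out[t] = val
    return out


# ---------------------------------------------------------------------------
# covariance-difference comparator
# ---------------------------------------------------------------------------


@njit(cache=True)
def cross_cov(Z, p):
    """Cross-gene covariance block (first p columns vs the rest), divisor n-1."""
    n, m = Z.shape
    q = m - p
    mu = np.empty(m)
    for j in range(m):
        mu[j] = Z[:, j].mean()
    Zc = Z - mu
    X = np.ascontiguousarray(Zc[:, :p])
    Y = np.ascontiguousarray(Zc[:, p:])
    return X.T @ Y / (n - 1)


@njit(cache=True)
def bootstrap_cov_d(Zc, Zk, p, n_boot, seed):
    """Bootstrap replicates of d = vec(cross-cov(cases) - cross-cov(controls)).

    Stratified: cases and controls are resampled independently.
    """
    np.random.seed(seed)
    nc = Zc.shape[0]
    nk = Zk.shape[0]
    m = Zc.shape[1]
    q = m - p
    out = np.empty((n_boot, p * q))
    for b in range(n_boot):
        ic = np.random.randint(0, nc, nc)
        ik = np.random.randint(0, nk, nk)
        dc = cross_cov(Zc[ic], p)
        dk = cross_cov(Zk[ik], p)
        out[b] = (dc - dk).ravel()
    return out


@njit(cache=True)
def perm_cov_d(Zall, p, n_case, n_perm, seed):
    """Label-permutation replicates of the cross-covariance difference vector."""
    np.random.seed(seed)
    N = Zall.shape[0]
    m = Zall.shape[1]
    q = m - p
    out = np.empty((n_perm, p * q))
    for t in range(n_perm):
        idx = np.random.permutation(N)
        dc = cross_cov(Zall[idx[:n_case]], p)
        dk = cross_cov(Zall[idx[n_case:]], p)
        out[t] = (dc - dk).ravel()
    return out


# ---------------------------------------------------------------------------
# single-SNP logistic with min-p permutation adjustment
# ---------------------------------------------------------------------------


@njit(cache=True)
def irls_interaction_z(g1, g2, y, max_iter, tol):
    """Wald z of the product term in logit(y) ~ g1 + g2 + g1*g2.

    Plain Newton/IRLS with a tiny diagonal ridge for numerical safety.
    Returns ``(z, converged)``; separation or non-convergence yields
    ``converged = False``.
    """
    n = g1.shape[0]
    X = np.empty((n, 4))
    for i in range(n):
        X[i, 0] = 1.0
        X[i, 1] = g1[i]
        X[i, 2] = g2[i]
        X[i, 3] = g1[i] * g2[i]
    beta = np.zeros(4)
    H = np.eye(4)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.empty(n)
        for i in range(n):
            v = eta[i]
            if v > 35.0:
                mu[i] = 1.0 - 1e-15
            elif v < -35.0:
                mu[i] = 1e-15
            else:
                mu[i] = 1.0 / (1.0 + np.exp(-v))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        Xw = X * w.reshape(n, 1)
        H = X.T @ Xw
        for d in range(4):
            H[d, d] += 1e-10
        delta = np.linalg.solve(H, grad)
        beta = beta + delta
        db = np.abs(delta).max()
        if db < tol:
            converged = True
            break
    if not converged or np.abs(beta).max() > 30.0:
        return 0.0, False
    Hinv = np.linalg.inv(H)
    se = np.sqrt(Hinv[3, 3])
    if se <= 0.0:
        return 0.0, False
    return beta[3] / se, True


@njit(cache=True)
def minp_observed(Ga, Gb, y, max_iter, tol):
    """|Wald z| of the interaction term for every SNP pair (NaN where the fit fails)."""
    pa = Ga.shape[1]
    pb = Gb.shape[1]
    zabs = np.full((pa, pb), np.nan)
    for j in range(pa):
        g1 = np.ascontiguousarray(Ga[:, j])
        for k in range(pb):
            g2 = np.ascontiguousarray(Gb[:, k])
            z, ok = irls_interaction_z(g1, g2, y, max_iter, tol)
            if ok:
                zabs[j, k] = abs(z)
    return zabs


@njit(cache=True)
def minp_perm_count(Ga, Gb, y, obs_max, n_perm, seed, max_iter, tol):
    """Count permutations whose max-|z| over pairs reaches the observed max.

    This is the max-T form of the min-p multiplicity adjustment: minimizing
    the Wald p over pairs is equivalent to maximizing |z|.
    """
    np.random.seed(seed)
    n = y.shape[0]
    pa = Ga.shape[1]
    pb = Gb.shape[1]
    count = 0
    for _t in range(n_perm):
        yp = y[np.random.permutation(n)]
        mx = -1.0
        for j in range(pa):
            g1 = np.ascontiguousarray(Ga[:, j])
            for k in range(pb):
                g2 = np.ascontiguousarray(Gb[:, k])
                z, ok = irls_interaction_z(g1, g2, yp, max_iter, tol)
                if ok and abs(z) > mx:
                    mx = abs(z)
        if mx >= obs_max:
            count += 1
    return count
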