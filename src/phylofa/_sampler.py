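"""Adaptive Metropolis-within-Gibbs kernel for the phylogenetic regression.

One compiled function runs a single MCMC chain for either family:

* beta family — y_i ~ Beta(mu_i*phi, (1-mu_i)*phi), logit(mu_i) = x_i'b + u_i;
* Gaussian family — y_i ~ N(x_i'b + u_i, sigma_e^2);

with u ~ MVN(0, sigma_p^2 * C) the phylogenetic species effect (C is the
normalized Brownian-motion correlation matrix, passed via its precision
Q0 = C^-1), flat priors on b, half-Student-t priors on the standard
deviations and a Gamma prior on phi.

Update blocks per iteration:

* b: exact conjugate Gibbs draw in the Gaussian family (flat prior); in the
  beta family coordinate-wise random-walk Metropolis plus a joint
  random-walk step whose proposal covariance is proportional to (X'X)^-1,
  which keeps mixing efficient when design columns are correlated.
* u: sequential single-site updates — exact Gibbs in the Gaussian family,
  random-walk Metropolis with per-site adapted scales in the beta family
  (two sweeps per iteration; each site touches one observation, and the
  conditional prior is read off the maintained vector s = Q0 u) — followed by
  a whitened sweep in the coordinates w = L^-1 u / sigma_p (L the Cholesky
  factor of C), whose prior is iid standard normal: each whitened coordinate
  moves a correlated block of species coherently, which is what single-site
  moves cannot do for tight clades whose effects the prior almost equates.
* translation moves: for each design column j, a joint proposal
  (b_j, u) -> (b_j + d, u - d*X[:, j]) that leaves the linear predictor (and
  hence the likelihood) unchanged and is driven purely by the Gaussian prior
  on u — this decouples the fixed effects from the species effects, whose
  posterior trade-off otherwise dominates the autocorrelation of b; a joint
  variant with (X'X)^-1-shaped increments handles correlated columns.
* sigma_p: a centered log-scale random-walk step followed by a non-centered
  (ancillarity-sufficiency interweaving) step that rescales u jointly with
  sigma_p — the interweave breaks the strong posterior coupling between u and
  sigma_p that makes the centered parameterization alone mix slowly.
* phi or sigma_e: log-scale random-walk Metropolis.

Proposal scales adapt by Robbins-Monro toward 0.44 acceptance during burn-in
only, so the post-burn-in kernel is a fixed Markov kernel satisfying detailed
balance.  All randomness comes from numba's RNG seeded once per chain.
"""

import math

import numpy as np
from numba import njit

_TARGET = 0.44  # optimal scalar random-walk acceptance rate


@njit(cache=True)
def _beta_ll_one(eta_i, phi, logy_i, log1my_i):
    mu = 1.0 / (1.0 + math.exp(-eta_i))
    if mu < 1e-12:
        mu = 1e-12
    elif mu > 1.0 - 1e-12:
        mu = 1.0 - 1e-12
    a = mu * phi
    b = (1.0 - mu) * phi
    return (math.lgamma(phi) - math.lgamma(a) - math.lgamma(b)
            + (a - 1.0) * logy_i + (b - 1.0) * log1my_i)


@njit(cache=True)
def _ll_total(is_beta, y, eta, disp, logy, log1my):
    # additive constants independent of the parameters are dropped
    n = y.shape[0]
    if is_beta:
        tot = 0.0
        for i in range(n):
            tot += _beta_ll_one(eta[i], disp, logy[i], log1my[i])
        return tot
    ssr = 0.0
    for i in range(n):
        d = y[i] - eta[i]
        ssr += d * d
    return -n * math.log(disp) - 0.5 * ssr / (disp * disp)


@njit(cache=True)
def _half_t_lp(x, df, scale):
    # half-Student-t(df, 0, scale) log-density kernel on x > 0
    return -0.5 * (df + 1.0) * math.log(1.0 + x * x / (df * scale * scale))


@njit(cache=True)
def run_chain(is_beta, use_phylo, y, X, Q0, Lc, XtXinv, XtXinv_chol,
              logy, log1my, n_iter, burn, thin, seed,
              sp_df, sp_scale, se_df, se_scale, phi_a, phi_b,
              beta0, u0, sp0, disp0):
    np.random.seed(seed)
    n, p = X.shape
    beta = beta0.copy()
    u = u0.copy()
    sp = sp0
    disp = disp0
    eta = X @ beta + u

    nkeep = (n_iter - burn) // thin
    beta_dr = np.empty((nkeep, p))
    u_dr = np.empty((nkeep, n))
    sp_dr = np.empty(nkeep)
    disp_dr = np.empty(nkeep)

    ls_beta = np.full(p, math.log(0.1))
    ls_u = np.full(n, math.log(0.5))
    ls_tr = np.full(p, math.log(0.3))
    ls_sp = math.log(0.3)
    ls_sp_nc = math.log(0.3)
    ls_disp = math.log(0.3)

    QX = np.ascontiguousarray((Q0 @ X).T) if use_phylo else np.zeros((p, 1))
    Xt = np.ascontiguousarray(X.T)
    xQx = np.empty(p)
    for j in range(p):
        xQx[j] = Xt[j] @ QX[j] if use_phylo else 0.0
    XQX = (X.T @ Q0 @ X) if use_phylo else np.zeros((p, p))
    ls_bj = math.log(0.5)   # joint beta proposal scale (x (X'X)^-1 chol)
    ls_trj = math.log(0.5)  # joint translation scale
    ls_w = np.full(n, math.log(0.5))  # whitened-coordinate scales

    k = 0
    for it in range(n_iter):
        adapt = it < burn
        step = 1.0 / (1.0 + it) ** 0.6
        cur = _ll_total(is_beta, y, eta, disp, logy, log1my)

        # ---- fixed effects
        if is_beta:
            for j in range(p):
                d = math.exp(ls_beta[j]) * np.random.normal()
                eta_prop = eta + X[:, j] * d
                prop = _ll_total(True, y, eta_prop, disp, logy, log1my)
                alpha = math.exp(min(0.0, prop - cur))
                if np.random.random() < alpha:
                    beta[j] += d
                    eta = eta_prop
                    cur = prop
                if adapt:
                    ls_beta[j] += step * (alpha - _TARGET)
            # joint step along the correlation structure of the design
            z = np.empty(p)
            for j in range(p):
                z[j] = np.random.normal()
            dvec = math.exp(ls_bj) * (XtXinv_chol @ z)
            eta_prop = eta + X @ dvec
            prop = _ll_total(True, y, eta_prop, disp, logy, log1my)
            alpha = math.exp(min(0.0, prop - cur))
            if np.random.random() < alpha:
                beta = beta + dvec
                eta = eta_prop
                cur = prop
            if adapt:
                ls_bj += step * (alpha - _TARGET)
        else:
            r = y - u
            bmean = XtXinv @ (X.T @ r)
            z = np.empty(p)
            for j in range(p):
                z[j] = np.random.normal()
            beta = bmean + disp * (XtXinv_chol @ z)
            eta = X @ beta + u
            cur = _ll_total(False, y, eta, disp, logy, log1my)

        # ---- species effects and phylogenetic scale
        if use_phylo:
            sp2 = sp * sp
            s = Q0 @ u  # recomputed each iteration to kill incremental drift
            if is_beta:
                for sweep in range(2):
                    for i in range(n):
                        d = math.exp(ls_u[i]) * np.random.normal()
                        dll = (_beta_ll_one(eta[i] + d, disp, logy[i], log1my[i])
                               - _beta_ll_one(eta[i], disp, logy[i], log1my[i]))
                        dquad = 2.0 * d * s[i] + d * d * Q0[i, i]
                        alpha = math.exp(min(0.0, dll - 0.5 * dquad / sp2))
                        if np.random.random() < alpha:
                            u[i] += d
                            eta[i] += d
                            s += Q0[i] * d
                            cur += dll
                        if adapt:
                            ls_u[i] += step * (alpha - _TARGET)
                # whitened sweep: w = L^-1 u / sp has iid N(0, 1) prior;
                # coordinate k moves all tips in column k's support together
                w = np.zeros(n)
                for i in range(n):  # forward substitution for L w = u / sp
                    acc_ = u[i] / sp
                    for kk in range(i):
                        acc_ -= Lc[i, kk] * w[kk]
                    w[i] = acc_ / Lc[i, i]
                for kk in range(n):
                    dw = math.exp(ls_w[kk]) * np.random.normal()
                    dll = 0.0
                    for i in range(kk, n):
                        lik = Lc[i, kk]
                        if lik != 0.0:
                            du_i = sp * lik * dw
                            dll += (_beta_ll_one(eta[i] + du_i, disp,
                                                 logy[i], log1my[i])
                                    - _beta_ll_one(eta[i], disp,
                                                   logy[i], log1my[i]))
                    dpr = -0.5 * ((w[kk] + dw) ** 2 - w[kk] ** 2)
                    alpha = math.exp(min(0.0, dll + dpr))
                    if np.random.random() < alpha:
                        w[kk] += dw
                        for i in range(kk, n):
                            lik = Lc[i, kk]
                            if lik != 0.0:
                                du_i = sp * lik * dw
                                u[i] += du_i
                                eta[i] += du_i
                        cur += dll
                    if adapt:
                        ls_w[kk] += step * (alpha - _TARGET)
                s = Q0 @ u  # refresh after the correlated moves
            else:
                # exact joint Gibbs draw: u | rest ~ N(A^-1 b, A^-1) with
                # A = Q0/sp^2 + I/de^2 and b = (y - X beta)/de^2
                de2 = disp * disp
                A = Q0 / sp2
                for i in range(n):
                    A[i, i] += 1.0 / de2
                b = (y - (eta - u)) / de2
                La = np.linalg.cholesky(A)
                m = np.linalg.solve(A, b)
                z = np.empty(n)
                for i in range(n):
                    z[i] = np.random.normal()
                v = np.empty(n)  # solve La' v = z (back substitution)
                for i in range(n - 1, -1, -1):
                    acc_ = z[i]
                    for k2 in range(i + 1, n):
                        acc_ -= La[k2, i] * v[k2]
                    v[i] = acc_ / La[i, i]
                unew = m + v
                eta += unew - u
                u = unew
                s = Q0 @ u
                cur = _ll_total(False, y, eta, disp, logy, log1my)

            # likelihood-invariant translations along each design column
            for j in range(p):
                d = math.exp(ls_tr[j]) * np.random.normal()
                dquad = -2.0 * d * (Xt[j] @ s) + d * d * xQx[j]
                alpha = math.exp(min(0.0, -0.5 * dquad / sp2))
                if np.random.random() < alpha:
                    beta[j] += d
                    u -= d * Xt[j]
                    s -= d * QX[j]
                if adapt:
                    ls_tr[j] += step * (alpha - _TARGET)

            # joint translation with (X'X)^-1-shaped increment
            z = np.empty(p)
            for j in range(p):
                z[j] = np.random.normal()
            dvec = math.exp(ls_trj) * (XtXinv_chol @ z)
            su = QX.T @ dvec          # Q0 X d, length n
            dquad = -2.0 * (dvec @ (QX @ u)) + dvec @ (XQX @ dvec)
            alpha = math.exp(min(0.0, -0.5 * dquad / sp2))
            if np.random.random() < alpha:
                beta = beta + dvec
                u -= X @ dvec
                s -= su
            if adapt:
                ls_trj += step * (alpha - _TARGET)

            # centered step: u fixed, MVN(u; 0, sp^2 C) term informs sp
            q = 0.0
            for i in range(n):
                q += u[i] * s[i]
            d = math.exp(ls_sp) * np.random.normal()
            prop_sp = sp * math.exp(d)
            lp_cur = (-n * math.log(sp) - 0.5 * q / sp2
                      + _half_t_lp(sp, sp_df, sp_scale) + math.log(sp))
            lp_prop = (-n * math.log(prop_sp) - 0.5 * q / (prop_sp * prop_sp)
                       + _half_t_lp(prop_sp, sp_df, sp_scale) + math.log(prop_sp))
            alpha = math.exp(min(0.0, lp_prop - lp_cur))
            if np.random.random() < alpha:
                sp = prop_sp
                sp2 = sp * sp
            if adapt:
                ls_sp += step * (alpha - _TARGET)

            # interweaved non-centered step: v = u/sp fixed, likelihood informs sp
            d = math.exp(ls_sp_nc) * np.random.normal()
            c = math.exp(d)
            prop_sp = sp * c
            eta_prop = eta + (c - 1.0) * u
            prop = _ll_total(is_beta, y, eta_prop, disp, logy, log1my)
            lr = (prop - cur
                  + _half_t_lp(prop_sp, sp_df, sp_scale) - _half_t_lp(sp, sp_df, sp_scale)
                  + math.log(prop_sp) - math.log(sp))
            alpha = math.exp(min(0.0, lr))
            if np.random.random() < alpha:
                u = u * c
                eta = eta_prop
                sp = prop_sp
                cur = prop
            if adapt:
                ls_sp_nc += step * (alpha - _TARGET)

        # ---- dispersion (phi or sigma_e)
        d = math.exp(ls_disp) * np.random.normal()
        prop_disp = disp * math.exp(d)
        prop = _ll_total(is_beta, y, eta, prop_disp, logy, log1my)
        if is_beta:
            # Gamma(a, b) prior on phi plus log-scale Jacobian
            prior_diff = (phi_a * (math.log(prop_disp) - math.log(disp))
                          - phi_b * (prop_disp - disp))
        else:
            prior_diff = (_half_t_lp(prop_disp, se_df, se_scale)
                          - _half_t_lp(disp, se_df, se_scale)
                          + math.log(prop_disp) - math.log(disp))
        alpha = math.exp(min(0.0, prop - cur + prior_diff))
        if np.random.random() < alpha:
            disp = prop_disp
            cur = prop
        if adapt:
            ls_disp += step * (alpha - _TARGET)

        # ---- store
        if it >= burn and (it - burn) % thin == 0 and k < nkeep:
            beta_dr[k] = beta
            u_dr[k] = u
            sp_dr[k] = sp
            disp_dr[k] = disp
            k += 1

    return beta_dr, u_dr, sp_dr, disp_dr
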