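"""Numba kernel for the spike-and-slab gamma-GLM sampler.

One chain = one call to :func:`run_chain`.  The linear predictor eta and the
derived weights w_i = y_i * exp(-eta_i) are maintained incrementally; term
columns are visited through a CSC-like sparse structure so a proposal only
touches the samples its column loads on.  Indicator flips are add/delete
moves with the Laplace prior as proposal density (the prior density then
cancels in the acceptance ratio, leaving the likelihood ratio times the
prior inclusion odds).  Random-walk scales adapt toward a 0.4 acceptance
rate during burn-in only, so the retained draws target the exact posterior.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _laplace(scale):
    u = np.random.random() - 0.5
    if u >= 0.0:
        return -scale * math.log(1.0 - 2.0 * u)
    return scale * math.log(1.0 + 2.0 * u)


_LOG_HALF = math.log(0.5)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _log_prior_beta(b, scale):
    return -math.log(2.0 * scale) - abs(b) / scale


@njit(cache=True)
def _log_q_beta(b, scale, mu, sd):
    """Add-move proposal density: 0.5 Laplace(0, scale) + 0.5 N(mu, sd)."""
    lp = _log_prior_beta(b, scale)
    z = (b - mu) / sd
    ln = -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI
    hi = lp if lp > ln else ln
    return _LOG_HALF + hi + math.log(math.exp(lp - hi) + math.exp(ln - hi))


@njit(cache=True)
def _draw_q_beta(scale, mu, sd):
    if np.random.random() < 0.5:
        return _laplace(scale)
    return mu + sd * np.random.standard_normal()


@njit(cache=True)
def _tau_loglik(tau, n, s_logy, s_eta, s_w):
    return n * (tau * math.log(tau) - math.lgamma(tau)) + (tau - 1.0) * s_logy \
        - tau * s_eta - tau * s_w


@njit(cache=True)
def run_chain(
    y,
    Xc,                      # dense covariate block (n, m)
    col_ptr, row_idx, val,   # sparse term columns (p of them)
    grp_ptr,                 # (G+1,) column offsets per indicator group
    prop_mean, prop_sd,      # (p,) data-informed add-proposal centre/scale
    col_mean,                # (p,) term-column means for intercept-centred jumps
    rel_a, rel_b,            # related-group pairs eligible for swap moves
    n_iter, n_burn, thin,
    seed,
    tau_mu2, tau_alpha2, b_lap, lam, kap, a_pi, b_pi,
    c0, alpha0, beta0, inc0, pi0, tau0,
    likelihood_on,
):
    np.random.seed(seed)
    n = y.shape[0]
    m = Xc.shape[1]
    p = col_ptr.shape[0] - 1
    G = grp_ptr.shape[0] - 1
    like = 1.0 if likelihood_on else 0.0

    c = c0
    alpha = alpha0.copy()
    beta = beta0.copy()
    inc = inc0.copy()
    pi = pi0
    tau = tau0

    s_logy = 0.0
    for i in range(n):
        s_logy += math.log(y[i])

    eta = np.empty(n)
    for i in range(n):
        e = c
        for j in range(m):
            e += Xc[i, j] * alpha[j]
        eta[i] = e
    for j in range(p):
        if beta[j] != 0.0:
            for k in range(col_ptr[j], col_ptr[j + 1]):
                eta[row_idx[k]] += val[k] * beta[j]
    w = np.empty(n)
    s_eta = 0.0
    s_w = 0.0
    for i in range(n):
        w[i] = y[i] * math.exp(-eta[i])
        s_eta += eta[i]
        s_w += w[i]

    n_inc = 0
    for g in range(G):
        n_inc += inc[g]

    # adaptive RW scales
    step_c = 0.1
    step_alpha = np.full(m, 0.1)
    step_beta = np.full(p, 0.2)
    step_tau = 0.3
    step_pi = 0.25 * (b_pi - a_pi)
    acc_c = 0.0; att_c = 0.0
    acc_alpha = np.zeros(m); att_alpha = np.zeros(m)
    acc_beta = np.zeros(p); att_beta = np.zeros(p)
    acc_tau = 0.0; att_tau = 0.0
    acc_pi = 0.0; att_pi = 0.0

    n_keep = (n_iter - n_burn) // thin
    c_draws = np.empty(n_keep)
    alpha_draws = np.empty((n_keep, m))
    beta_draws = np.empty((n_keep, p))
    inc_draws = np.empty((n_keep, G), dtype=np.int8)
    pi_draws = np.empty(n_keep)
    tau_draws = np.empty(n_keep)

    d_eta = np.zeros(n)
    touched = np.empty(n, dtype=np.int64)
    new_beta = np.empty(p)

    kept = 0
    for t in range(n_iter):
        adapting = t < n_burn

        # ---- intercept: constant shift of eta
        delta = step_c * np.random.standard_normal()
        c_new = c + delta
        dll = (-tau * n * delta - tau * (math.exp(-delta) - 1.0) * s_w) * like
        dlp = -(c_new * c_new - c * c) / (2.0 * tau_mu2)
        att_c += 1.0
        if math.log(np.random.random()) < dll + dlp:
            acc_c += 1.0
            c = c_new
            f = math.exp(-delta)
            for i in range(n):
                eta[i] += delta
                w[i] *= f
            s_eta += n * delta
            s_w *= f

        # ---- covariate effects: dense column updates
        for j in range(m):
            delta = step_alpha[j] * np.random.standard_normal()
            a_new = alpha[j] + delta
            dll = 0.0
            if likelihood_on:
                for i in range(n):
                    d = delta * Xc[i, j]
                    dll += -tau * d - tau * w[i] * (math.exp(-d) - 1.0)
            dlp = -(a_new * a_new - alpha[j] * alpha[j]) / (2.0 * tau_alpha2)
            att_alpha[j] += 1.0
            if math.log(np.random.random()) < dll + dlp:
                acc_alpha[j] += 1.0
                alpha[j] = a_new
                for i in range(n):
                    d = delta * Xc[i, j]
                    eta[i] += d
                    w[i] *= math.exp(-d)
                    s_eta += d
                s_w = 0.0
                for i in range(n):
                    s_w += w[i]

        # ---- gamma shape tau: RW on log scale
        z = step_tau * np.random.standard_normal()
        tau_new = tau * math.exp(z)
        dll = (_tau_loglik(tau_new, n, s_logy, s_eta, s_w)
               - _tau_loglik(tau, n, s_logy, s_eta, s_w)) * like
        dlp = (lam - 1.0) * (math.log(tau_new) - math.log(tau)) - kap * (tau_new - tau)
        dlp += z  # Jacobian of the log transform
        att_tau += 1.0
        if math.log(np.random.random()) < dll + dlp:
            acc_tau += 1.0
            tau = tau_new

        # ---- inclusion probability pi: RW within [a, b], binomial target
        if G > 0 and b_pi > a_pi:
            pi_new = pi + step_pi * np.random.standard_normal()
            att_pi += 1.0
            if a_pi < pi_new < b_pi:
                dlp = n_inc * (math.log(pi_new) - math.log(pi)) \
                    + (G - n_inc) * (math.log(1.0 - pi_new) - math.log(1.0 - pi))
                if math.log(np.random.random()) < dlp:
                    acc_pi += 1.0
                    pi = pi_new

        # ---- term groups: add/delete + within-model refinement
        log_odds_in = math.log(pi) - math.log(1.0 - pi)
        for g in range(G):
            j0 = grp_ptr[g]
            j1 = grp_ptr[g + 1]
            # -- add/delete move, betas proposed from (or returned to) the prior
            n_t = 0
            if inc[g] == 0:
                dlp = log_odds_in
                for j in range(j0, j1):
                    b = _draw_q_beta(b_lap, prop_mean[j], prop_sd[j])
                    new_beta[j] = b
                    dlp += _log_prior_beta(b, b_lap) \
                        - _log_q_beta(b, b_lap, prop_mean[j], prop_sd[j])
                sign = 1.0
            else:
                dlp = -log_odds_in
                for j in range(j0, j1):
                    b = beta[j]
                    new_beta[j] = b
                    dlp += _log_q_beta(b, b_lap, prop_mean[j], prop_sd[j]) \
                        - _log_prior_beta(b, b_lap)
                sign = -1.0
            dc = 0.0
            for j in range(j0, j1):
                bj = new_beta[j] * sign
                dc -= bj * col_mean[j]
                if bj != 0.0:
                    for k in range(col_ptr[j], col_ptr[j + 1]):
                        i = row_idx[k]
                        if d_eta[i] == 0.0:
                            touched[n_t] = i
                            n_t += 1
                        d_eta[i] += val[k] * bj
            # the intercept absorbs the group's mean contribution (shear map,
            # |Jacobian| = 1), so jumps move along the level ridge
            dlp += -((c + dc) ** 2 - c * c) / (2.0 * tau_mu2)
            dll = 0.0
            if likelihood_on:
                sw_t = 0.0
                for u in range(n_t):
                    i = touched[u]
                    d = d_eta[i] + dc
                    dll += -tau * d - tau * w[i] * (math.exp(-d) - 1.0)
                    sw_t += w[i]
                dll += -tau * dc * (n - n_t) \
                    - tau * (math.exp(-dc) - 1.0) * (s_w - sw_t)
            if math.log(np.random.random()) < dll + dlp:
                c += dc
                f = math.exp(-dc)
                for i in range(n):
                    eta[i] += dc
                    w[i] *= f
                for u in range(n_t):
                    i = touched[u]
                    eta[i] += d_eta[i]
                    w[i] = y[i] * math.exp(-eta[i])
                s_eta = 0.0
                s_w = 0.0
                for i in range(n):
                    s_eta += eta[i]
                    s_w += w[i]
                if inc[g] == 0:
                    inc[g] = 1
                    n_inc += 1
                    for j in range(j0, j1):
                        beta[j] = new_beta[j]
                else:
                    inc[g] = 0
                    n_inc -= 1
                    for j in range(j0, j1):
                        beta[j] = 0.0
            for u in range(n_t):
                d_eta[touched[u]] = 0.0
            # -- random-walk refinement of included betas
            if inc[g] == 1:
                for j in range(j0, j1):
                    delta = step_beta[j] * np.random.standard_normal()
                    b_new = beta[j] + delta
                    dll = 0.0
                    if likelihood_on:
                        for k in range(col_ptr[j], col_ptr[j + 1]):
                            i = row_idx[k]
                            d = delta * val[k]
                            dll += -tau * d - tau * w[i] * (math.exp(-d) - 1.0)
                    dlp = (abs(beta[j]) - abs(b_new)) / b_lap
                    att_beta[j] += 1.0
                    if math.log(np.random.random()) < dll + dlp:
                        acc_beta[j] += 1.0
                        for k in range(col_ptr[j], col_ptr[j + 1]):
                            i = row_idx[k]
                            d = delta * val[k]
                            eta[i] += d
                            nw = y[i] * math.exp(-eta[i])
                            s_w += nw - w[i]
                            w[i] = nw
                            s_eta += d
                        beta[j] = b_new

        # ---- swap moves between groups sharing a variant: delete one, add
        # the other in a single step so chains can hop between the
        # near-equivalent explanations that defeat one-at-a-time flips
        for r_i in range(rel_a.shape[0]):
            ga = rel_a[r_i]
            gb = rel_b[r_i]
            if inc[ga] + inc[gb] != 1:
                continue
            if inc[ga] == 1:
                gin = ga
                gout = gb
            else:
                gin = gb
                gout = ga
            dlp = 0.0
            dc = 0.0
            n_t = 0
            for j in range(grp_ptr[gout], grp_ptr[gout + 1]):
                b = _draw_q_beta(b_lap, prop_mean[j], prop_sd[j])
                new_beta[j] = b
                dc -= b * col_mean[j]
                dlp += _log_prior_beta(b, b_lap) \
                    - _log_q_beta(b, b_lap, prop_mean[j], prop_sd[j])
                if b != 0.0:
                    for k in range(col_ptr[j], col_ptr[j + 1]):
                        i = row_idx[k]
                        if d_eta[i] == 0.0:
                            touched[n_t] = i
                            n_t += 1
                        d_eta[i] += val[k] * b
            for j in range(grp_ptr[gin], grp_ptr[gin + 1]):
                b = beta[j]
                dc += b * col_mean[j]
                dlp += _log_q_beta(b, b_lap, prop_mean[j], prop_sd[j]) \
                    - _log_prior_beta(b, b_lap)
                if b != 0.0:
                    for k in range(col_ptr[j], col_ptr[j + 1]):
                        i = row_idx[k]
                        if d_eta[i] == 0.0:
                            touched[n_t] = i
                            n_t += 1
                        d_eta[i] -= val[k] * b
            dlp += -((c + dc) ** 2 - c * c) / (2.0 * tau_mu2)
            dll = 0.0
            if likelihood_on:
                sw_t = 0.0
                for u in range(n_t):
                    i = touched[u]
                    d = d_eta[i] + dc
                    dll += -tau * d - tau * w[i] * (math.exp(-d) - 1.0)
                    sw_t += w[i]
                dll += -tau * dc * (n - n_t) \
                    - tau * (math.exp(-dc) - 1.0) * (s_w - sw_t)
            if math.log(np.random.random()) < dll + dlp:
                c += dc
                f = math.exp(-dc)
                for i in range(n):
                    eta[i] += dc
                    w[i] *= f
                for u in range(n_t):
                    i = touched[u]
                    eta[i] += d_eta[i]
                    w[i] = y[i] * math.exp(-eta[i])
                s_eta = 0.0
                s_w = 0.0
                for i in range(n):
                    s_eta += eta[i]
                    s_w += w[i]
                inc[gin] = 0
                inc[gout] = 1
                for j in range(grp_ptr[gin], grp_ptr[gin + 1]):
                    beta[j] = 0.0
                for j in range(grp_ptr[gout], grp_ptr[gout + 1]):
                    beta[j] = new_beta[j]
            for u in range(n_t):
                d_eta[touched[u]] = 0.0

        # ---- adapt scales in batches of 100 during burn-in only
        if adapting and (t + 1) % 100 == 0:
            if att_c > 0:
                step_c *= math.exp(min(0.5, max(-0.5, acc_c / att_c - 0.4)))
            for j in range(m):
                if att_alpha[j] > 0:
                    step_alpha[j] *= math.exp(min(0.5, max(-0.5, acc_alpha[j] / att_alpha[j] - 0.4)))
            for j in range(p):
                if att_beta[j] > 0:
                    step_beta[j] *= math.exp(min(0.5, max(-0.5, acc_beta[j] / att_beta[j] - 0.4)))
            if att_tau > 0:
                step_tau *= math.exp(min(0.5, max(-0.5, acc_tau / att_tau - 0.4)))
            if att_pi > 0:
                step_pi *= math.exp(min(0.5, max(-0.5, acc_pi / att_pi - 0.4)))
                step_pi = min(step_pi, b_pi - a_pi)
            acc_c = 0.0; att_c = 0.0
            acc_tau = 0.0; att_tau = 0.0
            acc_pi = 0.0; att_pi = 0.0
            for j in range(m):
                acc_alpha[j] = 0.0; att_alpha[j] = 0.0
            for j in range(p):
                acc_beta[j] = 0.0; att_beta[j] = 0.0

        # ---- periodic exact refresh against incremental drift
        if (t + 1) % 2000 == 0:
            for i in range(n):
                e = c
                for j in range(m):
                    e += Xc[i, j] * alpha[j]
                eta[i] = e
            for j in range(p):
                if beta[j] != 0.0:
                    for k in range(col_ptr[j], col_ptr[j + 1]):
                        eta[row_idx[k]] += val[k] * beta[j]
            s_eta = 0.0
            s_w = 0.0
            for i in range(n):
                w[i] = y[i] * math.exp(-eta[i])
                s_eta += eta[i]
                s_w += w[i]

        # ---- record
        if t >= n_burn and (t - n_burn) % thin == 0 and kept < n_keep:
            c_draws[kept] = c
            for j in range(m):
                alpha_draws[kept, j] = alpha[j]
            for j in range(p):
                beta_draws[kept, j] = beta[j]
            for g in range(G):
                inc_draws[kept, g] = inc[g]
            pi_draws[kept] = pi
            tau_draws[kept] = tau
            kept += 1

    return c_draws, alpha_draws, beta_draws, inc_draws, pi_draws, tau_draws
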