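"""Compiled inner loops for the MH-RM fitter."""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def mstep_kernel(P, y, th_act, S_act, grad, info, compute_info):
    """Complete-data score and Fisher information per item.

    Parameters of item i are (slopes on its L loading dimensions, free
    intercepts 1..K); features of category k are the slope-scaled scoring
    weights ``S_act[i, l, k] * th_act[n, i, l]`` plus category indicators.
    ``grad`` (I, L+K) and ``info`` (I, L+K, L+K) are overwritten.
    """
    N, I, K1 = P.shape
    L = S_act.shape[1]
    n_par = L + K1 - 1
    grad[:] = 0.0
    if compute_info:
        info[:] = 0.0
    x = np.empty((L, K1))
    mx = np.empty(L)
    for n in range(N):
        for i in range(I):
            for l in range(L):
                tv = th_act[n, i, l]
                for k in range(K1):
                    x[l, k] = tv * S_act[i, l, k]
            for l in range(L):
                s = 0.0
                for k in range(K1):
                    s += P[n, i, k] * x[l, k]
                mx[l] = s
            yk = y[n, i]
            for l in range(L):
                grad[i, l] += x[l, yk] - mx[l]
            for k in range(1, K1):
                ind = 1.0 if yk == k else 0.0
                grad[i, L + k - 1] += ind - P[n, i, k]
            if compute_info:
                for l in range(L):
                    for m in range(l, L):
                        s = 0.0
                        for k in range(K1):
                            s += P[n, i, k] * x[l, k] * x[m, k]
                        info[i, l, m] += s - mx[l] * mx[m]
                for l in range(L):
                    for k in range(1, K1):
                        info[i, l, L + k - 1] += P[n, i, k] * (x[l, k] - mx[l])
                for k in range(1, K1):
                    pk = P[n, i, k]
                    info[i, L + k - 1, L + k - 1] += pk * (1.0 - pk)
                    for m in range(k + 1, K1):
                        info[i, L + k - 1, L + m - 1] -= pk * P[n, i, m]
    if compute_info:
        for i in range(I):
            for a in range(n_par):
                for b in range(a):
                    info[i, a, b] = info[i, b, a]


@njit(cache=True, fastmath=True)
def sweep_kernel(theta, logits, lse, theta_prec, Wt, WtY, prec,
                 item_idx, item_off, deltas, logu, accept_out):
    """One component-wise random-walk Metropolis sweep over all persons.

    Proposals on dimension d touch only the items listed in
    ``item_idx[item_off[d]:item_off[d+1]]`` (an item's logits depend on d
    only if it loads on d), so ``logits`` and the per-item log-normalizers
    ``lse`` are updated incrementally in place.  ``WtY[n, i, d]`` holds the
    slope-scaled weight of person n's observed category, and
    ``theta_prec = theta @ prec`` tracks the Gaussian prior term.
    """
    N, D = theta.shape
    K1 = logits.shape[2]
    I = logits.shape[1]
    scratch = np.empty(I)
    for d in range(D):
        start, end = item_off[d], item_off[d + 1]
        acc = 0
        for n in range(N):
            delta = deltas[n, d]
            dll = -delta * theta_prec[n, d] - 0.5 * delta * delta * prec[d, d]
            for jj in range(start, end):
                i = item_idx[jj]
                mx = -1e300
                for k in range(K1):
                    v = logits[n, i, k] + delta * Wt[i, d, k]
                    if v > mx:
                        mx = v
                s = 0.0
                for k in range(K1):
                    s += np.exp(logits[n, i, k] + delta * Wt[i, d, k] - mx)
                lse_new = mx + np.log(s)
                scratch[i] = lse_new
                dll += delta * WtY[n, i, d] - (lse_new - lse[n, i])
            if logu[n, d] < dll:
                acc += 1
                theta[n, d] += delta
                for jj in range(start, end):
                    i = item_idx[jj]
                    for k in range(K1):
                        logits[n, i, k] += delta * Wt[i, d, k]
                    lse[n, i] = scratch[i]
                for e in range(D):
                    theta_prec[n, e] += delta * prec[d, e]
        accept_out[d] = acc / N
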