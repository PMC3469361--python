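"""Compiled micro-step chain for the co-evolution simulator.

The event loop consumes pre-drawn randomness (event sides, focal actors and
one choice uniform per event), so all stochasticity lives in the caller's
numpy Generator and results are reproducible bit-for-bit.  Effects are
dispatched on small integer codes; covariate payloads are per-effect value
vectors plus centering scalars, so memory stays O(K n) even for the largest
schools.

Network effect codes: 0 density, 1 reciprocity, 2 transitive triplets,
3 three-cycles, 4 in-degree popularity, 5 out-degree popularity,
6 out-degree activity, 7 ego, 8 alter, 9 similarity, 10 same.
Behavior effect codes: 0 linear, 1 quadratic, 2 average-alter,
3 average-similarity, 4 covariate.
Effect kind 1 marks "the behavior variable used as covariate".
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    x, z, outdeg, indeg,
    net_code, net_param, net_kind, net_vec, net_c1, net_c2,
    beh_code, beh_param, beh_vec,
    zbar, zrange, znsim,
    sides, actors, u_choice,
    cap, want_score, score, zmin, zmax,
):
    n = x.shape[0]
    kn = net_code.size
    kb = beh_code.size
    util = np.empty(n)
    mat = np.empty((kn, n))
    avec = np.empty(n)
    bvec = np.empty(n)
    cvec = np.empty(n)
    w = np.empty(n)
    bstat = np.empty((kb, 3))
    bu = np.empty(3)
    bw = np.empty(3)
    need_tt = False
    need_3c = False
    for k in range(kn):
        if net_code[k] == 2:
            need_tt = True
        if net_code[k] == 3:
            need_3c = True
    n_net = 0
    n_beh = 0

    for ev in range(sides.size):
        i = actors[ev]
        if sides[ev]:
            n_net += 1
            if need_tt:
                for j in range(n):
                    avec[j] = 0.0
                    bvec[j] = 0.0
                for h in range(n):
                    if x[i, h] == 1.0:
                        for j in range(n):
                            avec[j] += x[j, h]
                            bvec[j] += x[h, j]
            if need_3c:
                for j in range(n):
                    cvec[j] = 0.0
                for h in range(n):
                    if x[h, i] == 1.0:
                        for j in range(n):
                            cvec[j] += x[j, h]
            for k in range(kn):
                code = net_code[k]
                kind = net_kind[k]
                if code == 7:  # ego: constant across alters
                    vi = (z[i] - zbar) if kind == 1 else (net_vec[k, i] - net_c1[k])
                    for j in range(n):
                        mat[k, j] = (1.0 - 2.0 * x[i, j]) * vi
                elif code == 6:
                    oi = outdeg[i]
                    for j in range(n):
                        d = 1.0 - 2.0 * x[i, j]
                        mat[k, j] = 2.0 * oi * d + 1.0
                else:
                    for j in range(n):
                        d = 1.0 - 2.0 * x[i, j]
                        if code == 0:
                            mk = d
                        elif code == 1:
                            mk = d * x[j, i]
                        elif code == 2:
                            mk = d * (avec[j] + bvec[j])
                        elif code == 3:
                            mk = d * cvec[j]
                        elif code == 4:
                            mk = d * indeg[j] + (d + 1.0) * 0.5
                        elif code == 5:
                            mk = d * outdeg[j]
                        elif code == 8:
                            va = (z[j] - zbar) if kind == 1 else (net_vec[k, j] - net_c1[k])
                            mk = d * va
                        elif code == 9:
                            if kind == 1:
                                s = 1.0 - abs(z[j] - z[i]) / zrange - znsim
                            else:
                                s = (
                                    1.0
                                    - abs(net_vec[k, j] - net_vec[k, i]) / net_c2[k]
                                    - net_c1[k]
                                )
                            mk = d * s
                        else:  # code == 10, same
                            if kind == 1:
                                same = 1.0 if z[j] == z[i] else 0.0
                            else:
                                same = 1.0 if net_vec[k, j] == net_vec[k, i] else 0.0
                            mk = d * same
                        mat[k, j] = mk
                mat[k, i] = 0.0
            for j in range(n):
                u = 0.0
                for k in range(kn):
                    u += net_param[k] * mat[k, j]
                util[j] = u
            util[i] = 0.0
            if cap > 0 and outdeg[i] >= cap:
                for j in range(n):
                    if j != i and x[i, j] == 0.0:
                        util[j] = -1.0e30
            umax = util[0]
            for j in range(1, n):
                if util[j] > umax:
                    umax = util[j]
            tot = 0.0
            for j in range(n):
                w[j] = np.exp(util[j] - umax)
                tot += w[j]
            r = u_choice[ev] * tot
            acc = 0.0
            jsel = n - 1
            for j in range(n):
                acc += w[j]
                if r < acc:
                    jsel = j
                    break
            if want_score:
                for k in range(kn):
                    ex = 0.0
                    for j in range(n):
                        ex += w[j] * mat[k, j]
                    score[k] += mat[k, jsel] - ex / tot
            if jsel != i:
                newv = 1.0 - x[i, jsel]
                x[i, jsel] = newv
                dd = 2.0 * newv - 1.0
                outdeg[i] += dd
                indeg[jsel] += dd
        else:
            n_beh += 1
            zi = z[i]
            lo = zi - 1 if zi - 1 >= zmin else zmin
            hi = zi + 1 if zi + 1 <= zmax else zmax
            nopts = hi - lo + 1
            od = outdeg[i]
            alt_sum = 0.0
            if od > 0:
                for j in range(n):
                    if x[i, j] == 1.0:
                        alt_sum += z[j] - zbar
            for k in range(kb):
                code = beh_code[k]
                for c in range(nopts):
                    zc = lo + c
                    zcen = zc - zbar
                    if code == 0:
                        s = zcen
                    elif code == 1:
                        s = zcen * zcen
                    elif code == 2:
                        s = zcen * alt_sum / od if od > 0 else 0.0
                    elif code == 3:
                        if od > 0:
                            tot_s = 0.0
                            for j in range(n):
                                if x[i, j] == 1.0:
                                    tot_s += 1.0 - abs(z[j] - zc) / zrange - znsim
                            s = tot_s / od
                        else:
                            s = 0.0
                    else:  # covariate effect; beh_vec pre-centered
                        s = zcen * beh_vec[k, i]
                    bstat[k, c] = s
            for c in range(nopts):
                u = 0.0
                for k in range(kb):
                    u += beh_param[k] * bstat[k, c]
                bu[c] = u
            umax = bu[0]
            for c in range(1, nopts):
                if bu[c] > umax:
                    umax = bu[c]
            tot = 0.0
            for c in range(nopts):
                bw[c] = np.exp(bu[c] - umax)
                tot += bw[c]
            r = u_choice[ev] * tot
            acc = 0.0
            csel = nopts - 1
            for c in range(nopts):
                acc += bw[c]
                if r < acc:
                    csel = c
                    break
            if want_score:
                for k in range(kb):
                    ex = 0.0
                    for c in range(nopts):
                        ex += bw[c] * bstat[k, c]
                    score[kn + k] += bstat[k, csel] - ex / tot
            z[i] = lo + csel
    return n_net, n_beh
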