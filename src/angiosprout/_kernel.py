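"""Compiled inner loop of the copy dynamics.

Mirrors the pure-Python reference path in :mod:`angiosprout.cpm` /
:mod:`angiosprout.motility` operation for operation (same formulas, same
evaluation order, same random-stream layout), so both paths produce
identical trajectories from identical uniform deviates.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

FROZEN = -1

# offsets (dx1, dx2); order must match cpm.OFF20 and cpm.RING8
_OFF20 = np.array([(1, 0), (-1, 0), (0, 1), (0, -1),
                   (1, 1), (1, -1), (-1, 1), (-1, -1),
                   (2, 0), (-2, 0), (0, 2), (0, -2),
                   (1, 2), (1, -2), (-1, 2), (-1, -2),
                   (2, 1), (2, -1), (-2, 1), (-2, -1)], dtype=np.int64)
_RING8 = np.array([(1, 0), (1, 1), (0, 1), (-1, 1),
                   (-1, 0), (-1, -1), (0, -1), (1, -1)], dtype=np.int64)


@njit(cache=True, inline="always")
def _bond(a, b, J_CC, J_CM, J_border):
    if a == b:
        return 0.0
    if a > 0 and b > 0:
        return J_CC
    if a > 0 or b > 0:
        other = b if a > 0 else a
        if other == FROZEN:
            return J_border
        return J_CM
    return 0.0


@njit(cache=True, inline="always")
def _length(area, s1, s2, s11, s22, s12):
    if area <= 0:
        return 0.0
    if area == 1:
        return 1.0
    a = float(area)
    i11 = s22 - s2 * s2 / a
    i22 = s11 - s1 * s1 / a
    i12 = -(s12 - s1 * s2 / a)
    lam = 0.5 * ((i11 + i22) + math.sqrt((i11 - i22) ** 2 + 4.0 * i12 * i12))
    return math.sqrt(12.0 * lam / a)


@njit(cache=True)
def run_attempts(sigma, area, At, Lt, sx1, sx2, sx11, sx22, sx12,
                 cV, cE, rand,
                 J_CC, J_CM, J_border, lam_A, lam_L, M,
                 chi, Gamma, s_sat, eta, mu, rho,
                 hapto_at_source, chemo_retraction, n_adh):
    Y, X = sigma.shape
    n_sites = X * Y
    gauss_norm = 1.0 / (rho * math.sqrt(2.0 * math.pi))
    accepted = 0
    for k in range(rand.shape[0]):
        flat = int(rand[k, 0] * n_sites)
        t2 = flat // X
        t1 = flat - t2 * X
        st = sigma[t2, t1]
        if st == FROZEN:
            continue
        ni = int(rand[k, 1] * 20)
        s1 = t1 + _OFF20[ni, 0]
        s2 = t2 + _OFF20[ni, 1]
        if s1 < 0 or s1 >= X or s2 < 0 or s2 >= Y:
            continue
        ss = sigma[s2, s1]
        if ss == FROZEN or ss == st:
            continue
        # local connectivity ring test for the losing cell
        if st > 0:
            if area[st] == 1:
                continue
            transitions = 0
            p1 = t1 + _RING8[0, 0]
            p2 = t2 + _RING8[0, 1]
            first = (0 <= p1 < X and 0 <= p2 < Y and sigma[p2, p1] == st)
            prev = first
            for r in range(1, 8):
                p1 = t1 + _RING8[r, 0]
                p2 = t2 + _RING8[r, 1]
                member = (0 <= p1 < X and 0 <= p2 < Y
                          and sigma[p2, p1] == st)
                if member != prev:
                    transitions += 1
                prev = member
            if prev != first:
                transitions += 1
            if transitions != 2:
                continue
        # gained site must touch the gaining cell (sources can be 2 away)
        if ss > 0:
            attached = False
            for r in range(8):
                p1 = t1 + _RING8[r, 0]
                p2 = t2 + _RING8[r, 1]
                if (0 <= p1 < X and 0 <= p2 < Y
                        and sigma[p2, p1] == ss):
                    attached = True
                    break
            if not attached:
                continue
        # --- adhesion bonds around the target ---
        dE = 0.0
        for n in range(n_adh):
            p1 = t1 + _OFF20[n, 0]
            p2 = t2 + _OFF20[n, 1]
            if p1 < 0 or p1 >= X or p2 < 0 or p2 >= Y:
                continue
            sn = sigma[p2, p1]
            dE += (_bond(ss, sn, J_CC, J_CM, J_border)
                   - _bond(st, sn, J_CC, J_CM, J_border))
        # --- area constraint ---
        if st > 0:
            a = float(area[st])
            at = At[st]
            dE += lam_A * ((a - 1.0 - at) ** 2 - (a - at) ** 2)
        if ss > 0:
            a = float(area[ss])
            at = At[ss]
            dE += lam_A * ((a + 1.0 - at) ** 2 - (a - at) ** 2)
        # --- length constraint ---
        if st > 0:
            lb = _length(area[st], float(sx1[st]), float(sx2[st]),
                         float(sx11[st]), float(sx22[st]), float(sx12[st]))
            la = _length(area[st] - 1, float(sx1[st] - t1),
                         float(sx2[st] - t2), float(sx11[st] - t1 * t1),
                         float(sx22[st] - t2 * t2),
                         float(sx12[st] - t1 * t2))
            lt = Lt[st]
            dE += lam_L * ((la - lt) ** 2 - (lb - lt) ** 2)
        if ss > 0:
            lb = _length(area[ss], float(sx1[ss]), float(sx2[ss]),
                         float(sx11[ss]), float(sx22[ss]), float(sx12[ss]))
            la = _length(area[ss] + 1, float(sx1[ss] + t1),
                         float(sx2[ss] + t2), float(sx11[ss] + t1 * t1),
                         float(sx22[ss] + t2 * t2),
                         float(sx12[ss] + t1 * t2))
            lt = Lt[ss]
            dE += lam_L * ((la - lt) ** 2 - (lb - lt) ** 2)
        # --- guidance terms: extensions into the medium only ---
        if st == 0:
            dE += -chi * (cV[t2, t1] - cV[s2, s1])
            ce_t = cE[t2, t1]
            ce_s = cE[s2, s1]
            dE += -Gamma * (ce_t / (1.0 + s_sat * ce_t)
                            - ce_s / (1.0 + s_sat * ce_s))
            ce_ref = ce_s if hapto_at_source else ce_t
            g = gauss_norm * math.exp(-(ce_ref - mu) ** 2 / (2.0 * rho * rho))
            dE += -eta * (-1.0 + g)
        elif chemo_retraction and ss == 0:
            dE += -chi * (cV[t2, t1] - cV[s2, s1])
        # --- Boltzmann acceptance ---
        if dE < 0:
            ok = True
        else:
            ok = rand[k, 2] < math.exp(-dE / M)
        if not ok:
            continue
        accepted += 1
        sigma[t2, t1] = ss
        if st > 0:
            area[st] -= 1
            sx1[st] -= t1
            sx2[st] -= t2
            sx11[st] -= t1 * t1
            sx22[st] -= t2 * t2
            sx12[st] -= t1 * t2
        if ss > 0:
            area[ss] += 1
            sx1[ss] += t1
            sx2[ss] += t2
            sx11[ss] += t1 * t1
            sx22[ss] += t2 * t2
            sx12[ss] += t1 * t2
    return accepted


@njit(cache=True)
def contact_counts(sigma, n_cells, n_adh):
    """Per-cell (cell-ECM boundary pairs, total heterotypic pairs).

    Pairs run over the same adjacency as adhesion bonds, directed from
    the cell's own sites.
    """
    Y, X = sigma.shape
    numer = np.zeros(n_cells + 1, dtype=np.int64)
    denom = np.zeros(n_cells + 1, dtype=np.int64)
    for y in range(Y):
        for x in range(X):
            s = sigma[y, x]
            if s <= 0:
                continue
            for n in range(n_adh):
                p1 = x + _OFF20[n, 0]
                p2 = y + _OFF20[n, 1]
                if p1 < 0 or p1 >= X or p2 < 0 or p2 >= Y:
                    continue
                sn = sigma[p2, p1]
                if sn != s:
                    denom[s] += 1
                    if sn == 0:
                        numer[s] += 1
    return numer, denom


@njit(cache=True)
def pde_substeps(sigma, cE, cM, cV, n_substeps, dt,
                 eps_EM, alpha_MV, eps_M, D_M, c_M_max):
    """n_substeps fused forward-Euler steps (sigma held fixed).

    Mirrors fields.pde_substep term for term and in the same floating-
    point evaluation order. cE is updated in place; the returned cM
    buffer alternates with a scratch buffer.
    """
    Y, X = sigma.shape
    scratch = np.zeros_like(cM)
    deg = dt * eps_EM
    for _ in range(n_substeps):
        for y in range(Y):
            for x in range(X):
                s = sigma[y, x]
                medium = s == 0
                if medium:
                    cE[y, x] = cE[y, x] - deg * cM[y, x] * cE[y, x]
                if y == 0 or y == Y - 1 or x == 0 or x == X - 1:
                    scratch[y, x] = 0.0
                    continue
                up = cM[y - 1, x]
                down = cM[y + 1, x]
                left = cM[y, x - 1]
                right = cM[y, x + 1]
                lap = up + down + left + right - 4.0 * cM[y, x]
                if s > 0 and cM[y, x] < c_M_max:
                    secr = alpha_MV * cV[y, x]
                else:
                    secr = 0.0
                decay = eps_M * cM[y, x] if medium else 0.0
                scratch[y, x] = cM[y, x] + dt * (secr - decay + D_M * lap)
        tmp = cM
        cM = scratch
        scratch = tmp
    return cM
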