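"""JIT-compiled fixed-step integrator for the delayed TX/TL system.

The delay enters only through the translation substrate RNA(t - tau_d), so
the step size is chosen to divide tau_d exactly: the lagged value at a grid
node is a previously stored node value, and the half-step stage times of the
classical Runge–Kutta scheme use cubic Hermite interpolation between stored
nodes (values + derivatives). History is RNA(s) = rna0 for s <= 0.

State vector: [RNA, TsR, TlR, P_dark, P_mat]; DNA is a constant input.
Variant codes: tx/tl 0=Michaelis–Menten 1=mass action; tsr 0=none
1=first-order; tlr 0=first-order 1=Michaelis–Menten.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_dde"]


@njit(cache=True)
def _rhs(y, lag_rna, dna, p, tx, tl, tsd, tld, out):
    # clamp to the state domain: intermediate Runge-Kutta stages may step
    # slightly outside it near the absorbing boundaries
    rna = y[0] if y[0] > 0.0 else 0.0
    tsr = y[1] if y[1] > 0.0 else 0.0
    tlr = y[2] if y[2] > 0.0 else 0.0
    pd = y[3] if y[3] > 0.0 else 0.0
    if tsr > 1.0:
        tsr = 1.0
    if tlr > 1.0:
        tlr = 1.0

    if tx == 0:
        den = p[1] + dna
        vtx = p[0] * tsr * dna / den if den > 0.0 else 0.0
    else:
        vtx = p[0] * tsr * dna

    if tl == 0:
        den = p[4] + lag_rna
        vtl = p[3] * tlr * lag_rna / den if den > 0.0 else 0.0
    else:
        vtl = p[3] * tlr * lag_rna

    out[0] = vtx - p[2] * rna
    out[1] = -p[9] * vtx
    if tsd == 1:
        out[1] -= p[6] * tsr
    if tld == 1:
        den = p[8] + tlr
        deg = p[7] * tlr / den if den > 0.0 else 0.0
    else:
        deg = p[7] * tlr
    out[2] = -p[10] * vtl - deg
    out[3] = vtl - p[5] * pd
    out[4] = p[5] * pd
    return vtx, vtl


@njit(cache=True, inline="always")
def _hermite_mid(y0, y1, d0, d1, h):
    # cubic Hermite at the interval midpoint
    return 0.5 * (y0 + y1) + 0.125 * h * (d0 - d1)


@njit(cache=True)
def integrate_dde(p, tx, tl, tsd, tld, dna0, rna0, t_end, h, m):
    """Integrate the delayed system with fixed-step RK4.

    Parameters: ``p`` the 13-vector of kinetic parameters (canonical order),
    variant codes, initial DNA/RNA (nM), end time (h), step ``h`` and the lag
    in steps ``m`` (``tau_d = m*h``; ``m=0`` means no delay). Returns
    ``(ts, Y, vtx, vtl, clip_conc, clip_res)`` with node times, states
    ``(n+1, 5)``, synthesis fluxes at nodes, and the largest domain clip
    applied to concentration states (nM) and to the resource states.
    Resource clips at the absorbing boundary TlR = 0 are expected whenever
    K_l is small (the decay rate stays finite as TlR -> 0).
    """
    n = int(np.ceil(t_end / h - 1e-9))
    if n < 1:
        n = 1
    ts = np.empty(n + 1)
    Y = np.empty((n + 1, 5))
    vtx_arr = np.empty(n + 1)
    vtl_arr = np.empty(n + 1)
    rna_hist = np.empty(n + 1)
    drna_hist = np.empty(n + 1)

    y = np.empty(5)
    y[0] = rna0
    y[1] = 1.0
    y[2] = 1.0
    y[3] = 0.0
    y[4] = 0.0

    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    ytmp = np.empty(5)

    clip_conc = 0.0
    clip_res = 0.0
    ts[0] = 0.0
    Y[0] = y
    rna_hist[0] = y[0]

    for i in range(n):
        t = i * h
        ts[i + 1] = (i + 1) * h

        # lagged RNA at the four stage times
        if m == 0:
            lag1 = y[0]
        else:
            j = i - m
            lag1 = rna0 if j < 0 else rna_hist[j]

        v1, w1 = _rhs(y, lag1, dna0, p, tx, tl, tsd, tld, k1)
        vtx_arr[i] = v1
        vtl_arr[i] = w1
        drna_hist[i] = k1[0]

        lag_half = 0.0
        lag_full = 0.0
        if m > 0:
            if i < m:
                lag_half = rna0
            else:
                j = i - m
                lag_half = _hermite_mid(
                    rna_hist[j], rna_hist[j + 1],
                    drna_hist[j], drna_hist[j + 1], h,
                )
                if lag_half < 0.0:  # Hermite overshoot near kinks
                    lag_half = 0.0
            if i + 1 <= m:
                lag_full = rna0
            else:
                lag_full = rna_hist[i - m + 1]

        for s in range(5):
            ytmp[s] = y[s] + 0.5 * h * k1[s]
        lh = ytmp[0] if m == 0 else lag_half
        _rhs(ytmp, lh, dna0, p, tx, tl, tsd, tld, k2)

        for s in range(5):
            ytmp[s] = y[s] + 0.5 * h * k2[s]
        lh = ytmp[0] if m == 0 else lag_half
        _rhs(ytmp, lh, dna0, p, tx, tl, tsd, tld, k3)

        for s in range(5):
            ytmp[s] = y[s] + h * k3[s]
        lh = ytmp[0] if m == 0 else lag_full
        _rhs(ytmp, lh, dna0, p, tx, tl, tsd, tld, k4)

        for s in range(5):
            y[s] = y[s] + (h / 6.0) * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])

        # enforce state domain: concentrations >= 0, resources in [0, 1]
        for s in (0, 3, 4):
            if y[s] < 0.0:
                if -y[s] > clip_conc:
                    clip_conc = -y[s]
                y[s] = 0.0
        for s in (1, 2):
            if y[s] < 0.0:
                if -y[s] > clip_res:
                    clip_res = -y[s]
                y[s] = 0.0
            elif y[s] > 1.0:
                if y[s] - 1.0 > clip_res:
                    clip_res = y[s] - 1.0
                y[s] = 1.0

        Y[i + 1] = y
        rna_hist[i + 1] = y[0]

    # fluxes at the final node
    if m == 0:
        lagn = y[0]
    else:
        j = n - m
        lagn = rna0 if j < 0 else rna_hist[j]
    vn, wn = _rhs(y, lagn, dna0, p, tx, tl, tsd, tld, k1)
    vtx_arr[n] = vn
    vtl_arr[n] = wn

    return ts, Y, vtx_arr, vtl_arr, clip_conc, clip_res
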