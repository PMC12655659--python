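"""Compiled fixed-step RK4 integrator for the disposition system.

The transit-chain forcing is smooth (the input rate of each dose starts
at zero for N > 0), so a classic fixed-step RK4 with h ~ 0.05-0.1 h
resolves the fastest time scale (1/ktr ~ 0.25 h) to ~1e-4 relative
accuracy; the adaptive scipy path in :mod:`radpk.engine` serves as the
reference.

A parameter vector ``p`` packs, in order:
  0 cl, 1 vc, 2 q, 3 vp, 4 ka, 5 f, 6 ktr, 7 n_transit, 8 lgamma(n+1),
  9 circ_amp, 10 circ_acrophase, 11 circ_period, 12 clock_offset

State layout: y[0:3] = forced solution (depot, central, peripheral);
optionally three further 3-blocks y[3+3j : 6+3j] carrying the columns of
the homogeneous fundamental matrix (used for the periodic steady state).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

P_CL, P_VC, P_Q, P_VP, P_KA, P_F, P_KTR, P_N, P_LGAM = 0, 1, 2, 3, 4, 5, 6, 7, 8
P_CAMP, P_CACRO, P_CPER, P_COFF = 9, 10, 11, 12
NP_PACK = 13


def pack_params(params, theta, clock_offset: float = 0.0) -> np.ndarray:
    """Pack an IndividualParams + ThetaSet circadian block into a vector."""
    ktr = (params.n_transit + 1.0) / params.mtt
    return np.array([
        params.cl, params.vc, params.q, params.vp, params.ka, params.f,
        ktr, params.n_transit, math.lgamma(params.n_transit + 1.0),
        theta.theta_circadian, theta.circadian_acrophase,
        theta.circadian_period, clock_offset,
    ])


@njit(cache=True)
def _transit_rate(t, dose_times, dose_amts, f, ktr, n, lgam):
    s = 0.0
    for i in range(dose_times.shape[0]):
        td = t - dose_times[i]
        if td <= 0.0:
            continue
        x = ktr * td
        if n == 0.0:
            lr = math.log(ktr) - x
        else:
            lr = math.log(ktr) + n * math.log(x) - x - lgam
        if lr > -45.0:
            s += f * dose_amts[i] * math.exp(lr)
    return s


@njit(cache=True)
def _rhs(t, y, out, p, dose_times, dose_amts, nblocks):
    inp = _transit_rate(t, dose_times, dose_amts, p[P_F], p[P_KTR], p[P_N], p[P_LGAM])
    circ = 1.0 + p[P_CAMP] * math.cos(
        2.0 * math.pi * (t + p[P_COFF] - p[P_CACRO]) / p[P_CPER])
    ke = p[P_CL] * circ / p[P_VC]
    k12 = p[P_Q] / p[P_VC]
    k21 = p[P_Q] / p[P_VP]
    ka = p[P_KA]
    out[0] = inp - ka * y[0]
    out[1] = ka * y[0] - (ke + k12) * y[1] + k21 * y[2]
    out[2] = k12 * y[1] - k21 * y[2]
    for j in range(1, nblocks):
        b = 3 * j
        out[b] = -ka * y[b]
        out[b + 1] = ka * y[b] - (ke + k12) * y[b + 1] + k21 * y[b + 2]
        out[b + 2] = k12 * y[b + 1] - k21 * y[b + 2]


@njit(cache=True)
def integrate(y0, t0, record_times, h, p, dose_times, dose_amts):
    """RK4 from ``t0`` through sorted ``record_times``; each inter-record
    interval is subdivided into equal steps no longer than ``h``.
    Returns the state at every record time, shape (n_rec, len(y0))."""
    ny = y0.shape[0]
    nblocks = ny // 3
    nrec = record_times.shape[0]
    out = np.empty((nrec, ny))
    y = y0.copy()
    k1 = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    yt = np.empty(ny)
    t = t0
    for r in range(nrec):
        tr = record_times[r]
        if tr > t + 1e-12:
            nst = int(math.ceil((tr - t) / h - 1e-9))
            if nst < 1:
                nst = 1
            hh = (tr - t) / nst
            for _ in range(nst):
                _rhs(t, y, k1, p, dose_times, dose_amts, nblocks)
                for i in range(ny):
                    yt[i] = y[i] + 0.5 * hh * k1[i]
                _rhs(t + 0.5 * hh, yt, k2, p, dose_times, dose_amts, nblocks)
                for i in range(ny):
                    yt[i] = y[i] + 0.5 * hh * k2[i]
                _rhs(t + 0.5 * hh, yt, k3, p, dose_times, dose_amts, nblocks)
                for i in range(ny):
                    yt[i] = y[i] + hh * k3[i]
                _rhs(t + hh, yt, k4, p, dose_times, dose_amts, nblocks)
                for i in range(ny):
                    y[i] += hh / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                t += hh
            t = tr
        out[r] = y
    return out


@njit(cache=True)
def integrate_forced(t0, record_times, h, p, dose_times, dose_amts):
    """Forced solution from a zero initial state; returns central amounts
    at the record times."""
    y0 = np.zeros(3)
    out = integrate(y0, t0, record_times, h, p, dose_times, dose_amts)
    return out[:, 1]


@njit(cache=True)
def periodic_window(record_times, period, h, p, dose_times, dose_amts):
    """Central amounts over one period of the periodic steady state.

    ``dose_times`` must contain the periodic dose pattern extended far
    enough into the past (t < 0) that older doses contribute nothing,
    and forward through ``period``.  ``record_times`` lie in [0, period].
    The state transition over one period is obtained from the fundamental
    matrix (integrated alongside the forced solution) and the fixed point
    x* = (I - Phi)^-1 b gives the steady-state window by superposition.
    """
    y0 = np.zeros(12)
    y0[3] = 1.0   # Phi column 1
    y0[7] = 1.0   # Phi column 2
    y0[11] = 1.0  # Phi column 3
    nrec = record_times.shape[0]
    rec = np.empty(nrec + 1)
    for i in range(nrec):
        rec[i] = record_times[i]
    rec[nrec] = period
    # record_times must be sorted and <= period
    out = integrate(y0, 0.0, rec, h, p, dose_times, dose_amts)
    phi_T = np.empty((3, 3))
    for j in range(3):
        for i in range(3):
            phi_T[i, j] = out[nrec, 3 + 3 * j + i]
    b = out[nrec, 0:3].copy()
    a = np.eye(3) - phi_T
    xstar = np.linalg.solve(a, b)
    central = np.empty(nrec)
    for r in range(nrec):
        c = out[r, 1]
        for j in range(3):
            c += out[r, 3 + 3 * j + 1] * xstar[j]
        central[r] = c
    return central
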