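"""Compiled hot-loop kernels for the coupled plant ODE.

The right-hand side of the 233-state plant system is evaluated tens of
thousands of times per simulation (implicit stepping plus finite-difference
Jacobian groups), so the ASM2d rates, the settler flux balance and the flow
routing are duplicated here as scalar-loop kernels that numba can compile.
`sludgeopt.plant` uses these by default and falls back to the vectorized
NumPy implementations when numba is unavailable; an equivalence test keeps
the two paths synchronized.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


# kinetic parameter packing order (matches asm2d._default_kinetics)
KIN_ORDER = (
    "K_H", "eta_NO3_hyd", "eta_fe", "K_O2_hyd", "K_NO3_hyd", "K_X",
    "mu_H", "q_fe", "b_H", "eta_NO3_H", "K_O2_H", "K_F", "K_fe", "K_A_H",
    "K_NO3_H", "K_NH4_H", "K_P_H", "K_ALK_H",
    "q_PHA", "q_PP", "mu_PAO", "eta_NO3_PAO", "b_PAO", "b_PP", "b_PHA",
    "K_O2_PAO", "K_NO3_PAO", "K_A_PAO", "K_NH4_PAO", "K_PS", "K_P_PAO",
    "K_ALK_PAO", "K_PP", "K_MAX", "K_IPP", "K_PHA",
    "mu_AUT", "b_AUT", "K_O2_AUT", "K_NH4_AUT", "K_ALK_AUT", "K_P_AUT",
)


def pack_kinetics(kvals: dict) -> np.ndarray:
    return np.array([kvals[name] for name in KIN_ORDER], dtype=np.float64)


@njit(cache=True)
def _rates_row(s, kin, out):  # pragma: no cover - compiled
    """ASM2d biological process rates for one tank (chemical P excluded)."""
    SO2, SF, SA, SNH4, SNO3, SPO4 = s[0], s[1], s[2], s[3], s[4], s[5]
    SALK = s[7]
    XS, XH, XPAO, XPP, XPHA, XAUT = s[10], s[11], s[12], s[13], s[14], s[15]

    (K_H, eta_hyd, eta_fe, K_O2h, K_NO3h, K_X,
     mu_H, q_fe, b_H, eta_H, K_O2H, K_F, K_fe, K_AH,
     K_NO3H, K_NH4H, K_PH, K_ALKH,
     q_PHA, q_PP, mu_PAO, eta_PAO, b_PAO, b_PP, b_PHA,
     K_O2P, K_NO3P, K_AP, K_NH4P, K_PS, K_PP_s, K_ALKP,
     K_PP_r, K_MAX, K_IPP, K_PHA_r,
     mu_A, b_A, K_O2A, K_NH4A, K_ALKA, K_PA) = (
        kin[0], kin[1], kin[2], kin[3], kin[4], kin[5],
        kin[6], kin[7], kin[8], kin[9], kin[10], kin[11], kin[12], kin[13],
        kin[14], kin[15], kin[16], kin[17],
        kin[18], kin[19], kin[20], kin[21], kin[22], kin[23], kin[24],
        kin[25], kin[26], kin[27], kin[28], kin[29], kin[30],
        kin[31], kin[32], kin[33], kin[34], kin[35],
        kin[36], kin[37], kin[38], kin[39], kin[40], kin[41],
    )

    den = K_X * XH + XS
    sat_XS = XS / den if den > 0.0 else 0.0
    o2_on = SO2 / (K_O2h + SO2)
    o2_off = K_O2h / (K_O2h + SO2)
    no3_on = SNO3 / (K_NO3h + SNO3)
    no3_off = K_NO3h / (K_NO3h + SNO3)
    out[0] = K_H * o2_on * sat_XS * XH
    out[1] = K_H * eta_hyd * o2_off * no3_on * sat_XS * XH
    out[2] = K_H * eta_fe * o2_off * no3_off * sat_XS * XH

    o2H = SO2 / (K_O2H + SO2)
    o2H_off = K_O2H / (K_O2H + SO2)
    no3H = SNO3 / (K_NO3H + SNO3)
    no3H_off = K_NO3H / (K_NO3H + SNO3)
    nut = (SNH4 / (K_NH4H + SNH4)) * (SPO4 / (K_PH + SPO4)) * (SALK / (K_ALKH + SALK))
    tot = SF + SA
    prefF = SF / tot if tot > 0.0 else 0.0
    prefA = SA / tot if tot > 0.0 else 0.0
    growF = (SF / (K_F + SF)) * prefF * nut * XH
    growA = (SA / (K_AH + SA)) * prefA * nut * XH
    out[3] = mu_H * o2H * growF
    out[4] = mu_H * o2H * growA
    out[5] = mu_H * eta_H * o2H_off * no3H * growF
    out[6] = mu_H * eta_H * o2H_off * no3H * growA
    out[7] = q_fe * o2H_off * no3H_off * (SF / (K_fe + SF)) * (SALK / (K_ALKH + SALK)) * XH
    out[8] = b_H * XH

    o2P = SO2 / (K_O2P + SO2)
    o2P_off = K_O2P / (K_O2P + SO2)
    no3P = SNO3 / (K_NO3P + SNO3)
    alkP = SALK / (K_ALKP + SALK)
    den = K_PP_r * XPAO + XPP
    sat_PP = XPP / den if den > 0.0 else 0.0
    den = K_PHA_r * XPAO + XPHA
    sat_PHA = XPHA / den if den > 0.0 else 0.0
    head = K_MAX * XPAO - XPP
    if head < 0.0:
        head = 0.0
    den = K_IPP * XPAO + head
    sat_head = head / den if den > 0.0 else 0.0
    out[9] = q_PHA * (SA / (K_AP + SA)) * alkP * sat_PP * XPAO
    stor = q_PP * (SPO4 / (K_PS + SPO4)) * alkP * sat_PHA * sat_head * XPAO
    out[10] = stor * o2P
    out[11] = stor * eta_PAO * o2P_off * no3P
    grow = mu_PAO * (SNH4 / (K_NH4P + SNH4)) * (SPO4 / (K_PA + SPO4)) * alkP * sat_PHA * XPAO
    out[12] = grow * o2P
    out[13] = grow * eta_PAO * o2P_off * no3P
    out[14] = b_PAO * XPAO * alkP
    out[15] = b_PP * XPP * alkP
    out[16] = b_PHA * XPHA * alkP

    out[17] = (
        mu_A * (SO2 / (K_O2A + SO2)) * (SNH4 / (K_NH4A + SNH4))
        * (SPO4 / (K_PA + SPO4)) * (SALK / (K_ALKA + SALK)) * XAUT
    )
    out[18] = b_A * XAUT
    out[19] = 0.0
    out[20] = 0.0


@njit(cache=True)
def plant_rhs_kernel(  # pragma: no cover - compiled
    y,
    Qin,
    c_in,
    kin,
    stoich,        # (21, 19)
    i_tss,         # (19,)
    volumes,       # (7,)
    klas,          # (7,)
    so_sat,
    ql_ratio,
    qs_ratio,
    qw_ratio,
    rec_from,
    rec_to,
    flow_mult,     # (7,)
    feed_mult,
    s_area,
    s_height,
    s_feed_layer,
    s_v0,
    s_v0max,
    s_rh,
    s_rp,
    s_fns,
    s_xt,
):
    n_comp = 19
    n_sol = 9
    dydt = np.zeros_like(y)

    tanks = np.empty((7, n_comp))
    for i in range(7):
        for j in range(n_comp):
            v = y[i * n_comp + j]
            tanks[i, j] = v if v > 0.0 else 0.0
    off = 7 * n_comp
    X = np.empty(10)
    for i in range(10):
        v = y[off + i]
        X[i] = v if v > 0.0 else 0.0
    Sol = np.empty((10, n_sol))
    for i in range(10):
        for j in range(n_sol):
            v = y[off + 10 + i * n_sol + j]
            Sol[i, j] = v if v > 0.0 else 0.0

    Ql = ql_ratio * Qin
    Qs = qs_ratio * Qin
    Qw = qw_ratio * Qin

    feed = tanks[6]
    feed_tss = 0.0
    for j in range(n_comp):
        feed_tss += feed[j] * i_tss[j]

    # return-sludge composition: bottom solubles + feed particulates scaled
    ras = np.zeros(n_comp)
    for j in range(n_sol):
        ras[j] = Sol[9, j]
    if feed_tss > 1e-9:
        scale = X[9] / feed_tss
        for j in range(9, n_comp):
            ras[j] = feed[j] * scale
    ras[16] = X[9]  # XTSS slot

    # inlet concentrations
    inlet = np.empty((7, n_comp))
    q0 = Qin + Qs
    for j in range(n_comp):
        inlet[0, j] = (Qin * c_in[j] + Qs * ras[j]) / q0
    for i in range(1, 7):
        q_up = flow_mult[i - 1] * Qin
        if i == rec_to:
            for j in range(n_comp):
                inlet[i, j] = (q_up * tanks[i - 1, j] + Ql * tanks[rec_from, j]) / (q_up + Ql)
        else:
            for j in range(n_comp):
                inlet[i, j] = tanks[i - 1, j]

    rates = np.empty(21)
    for i in range(7):
        _rates_row(tanks[i], kin, rates)
        qv = flow_mult[i] * Qin / volumes[i]
        for j in range(n_comp):
            acc = qv * (inlet[i, j] - tanks[i, j])
            for k in range(21):
                acc += rates[k] * stoich[k, j]
            dydt[i * n_comp + j] = acc
        dydt[i * n_comp + 0] += klas[i] * (so_sat - tanks[i, 0])

    # settler
    Q_feed = feed_mult * Qin
    Q_under = Qs + Qw
    Q_eff = Q_feed - Q_under
    A = s_area
    h = s_height / 10.0
    v_up = Q_eff / A
    v_dn = Q_under / A
    fl = s_feed_layer

    vs = np.empty(10)
    for i in range(10):
        xs = X[i] - s_fns * feed_tss
        if xs < 0.0:
            xs = 0.0
        v = s_v0 * (np.exp(-s_rh * xs) - np.exp(-s_rp * xs))
        if v < 0.0:
            v = 0.0
        elif v > s_v0max:
            v = s_v0max
        vs[i] = v
    Js = vs * X
    J = np.zeros(11)
    for i in range(1, 10):
        mn = Js[i - 1] if Js[i - 1] < Js[i] else Js[i]
        if i <= fl:
            J[i] = mn if X[i] > s_xt else Js[i - 1]
        else:
            J[i] = mn

    for i in range(10):
        acc = (J[i] - J[i + 1]) / h
        if i < fl:
            acc += (v_up / h) * (X[i + 1] - X[i])
        elif i == fl:
            acc += (Q_feed * feed_tss) / (A * h) - ((v_up + v_dn) / h) * X[i]
        else:
            acc += (v_dn / h) * (X[i - 1] - X[i])
        dydt[off + i] = acc

    for i in range(10):
        base = off + 10 + i * n_sol
        if i < fl:
            for j in range(n_sol):
                dydt[base + j] = (v_up / h) * (Sol[i + 1, j] - Sol[i, j])
        elif i == fl:
            for j in range(n_sol):
                dydt[base + j] = (Q_feed / (A * h)) * feed[j] - ((v_up + v_dn) / h) * Sol[i, j]
        else:
            for j in range(n_sol):
                dydt[base + j] = (v_dn / h) * (Sol[i - 1, j] - Sol[i, j])
    return dydt
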