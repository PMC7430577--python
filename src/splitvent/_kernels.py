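"""Compiled numerical core: loss laws, per-connection flow solves, ODE RHS.

Everything here works in SI units on flat float64 arrays so numba can compile
it once and the breath-cycle integration stays cheap enough for grid sweeps.
The public modules (`components`, `network`) wrap these kernels with typed,
clinical-unit interfaces; the kernels are the single implementation of the
physics, so the readable wrappers and the solver can never disagree.

Parameter-vector layout (``NP`` slots, see ``network.build_network``)::

    0 R_specific  1 T_ref  2 mu  3 p_atm
    4 mode (0 PC, 1 VC)  5 pip (Pa gauge)  6 peep  7 period  8 t_insp
    9 rise_time  10 q_plateau (m3/s, VC)
    11 R_src_fwd  12 R_src_rev (Pa.s/m3)  13 q_smooth (m3/s)
    14 L_shared  15 D_shared  16 V_node_shared
    17 energy_flag (0 isothermal, 1 adiabatic-wall energy balance)  18 cv
    19.. limb A block, 32.. limb B block (stride 13):
        +0 has_resistor  +1 lumen_d  +2 throat_L  +3 Cd  +4 Kc
        +5 L_limb  +6 D_limb  +7 V_node_limb
        +8 d_ett  +9 L_ett  +10 R_aw (Pa.s/m3)  +11 C (m3/Pa)  +12 spare
    45 has_B

State vector: [p_I, p_A, p_B, V_A, V_B, M_src, M_A, M_B] (+ [T_I, T_A, T_B]
in energy mode).  Pressures absolute Pa; lung volumes above relaxed, m3; the
M_* states are cumulative masses through the source and the two limb
connections, used for conservation audits.
"""

import numpy as np
from numba import njit

PI = np.pi

# --- parameter layout ---------------------------------------------------
P_RS, P_T, P_MU, P_PATM = 0, 1, 2, 3
P_MODE, P_PIP, P_PEEP, P_PERIOD, P_TINSP, P_RISE, P_QVC = 4, 5, 6, 7, 8, 9, 10
P_RFWD, P_RREV, P_QSM, P_LSH, P_DSH, P_VI = 11, 12, 13, 14, 15, 16
P_ENERGY, P_CV = 17, 18
LIMB_A, LIMB_B, LIMB_STRIDE = 19, 32, 13
(L_HASRES, L_DRES, L_LT, L_CD, L_KC, L_LTUBE, L_DTUBE, L_VNODE,
 L_DETT, L_LETT, L_RAW, L_C, L_SPARE) = range(13)
P_HASB = 45
NP = 46

NSTATE_ISO = 8
NSTATE_ENERGY = 11

_FTOL_BASE = 1e-9  # Pa, flow-solve pressure residual


@njit(cache=True)
def pipe_dp_kernel(mdot, length, diameter, rho, mu):
    """Friction pressure loss of a straight circular pipe, signed, odd in mdot.

    Darcy friction factor: 64/Re below Re 2000 (identical to
    Hagen-Poiseuille), Blasius 0.316 Re^-1/4 above 4000, linear blend in
    Re between (continuous at both ends).
    """
    if mdot == 0.0:
        return 0.0
    am = abs(mdot)
    area = 0.25 * PI * diameter * diameter
    re = 4.0 * am / (PI * diameter * mu)
    v = am / (rho * area)
    if re < 2000.0:
        dp = 32.0 * mu * length * v / (diameter * diameter)
    else:
        f_turb = 0.316 * re ** -0.25
        dyn = 0.5 * rho * v * v * length / diameter
        if re > 4000.0:
            dp = f_turb * dyn
        else:
            f_lam = 64.0 / re
            w = (re - 2000.0) / 2000.0
            dp = ((1.0 - w) * f_lam + w * f_turb) * dyn
    return dp if mdot > 0.0 else -dp


@njit(cache=True)
def resistor_dp_kernel(mdot, lumen_d, throat_l, cd, kc, d_up, rho, mu):
    """Composite loss of a reduced-lumen inline resistor, signed, odd.

    Sudden-contraction loss (coefficient tapered by (1 - area ratio) so it
    vanishes as the lumen approaches the tube bore) plus Borda-Carnot
    re-expansion loss, both divided by the discharge coefficient squared,
    plus ordinary pipe friction over the throat length.
    """
    if mdot == 0.0:
        return 0.0
    am = abs(mdot)
    a_throat = 0.25 * PI * lumen_d * lumen_d
    a_up = 0.25 * PI * d_up * d_up
    v_t = am / (rho * a_throat)
    v_u = am / (rho * a_up)
    sigma = a_throat / a_up
    minor = (kc * (1.0 - sigma) * 0.5 * rho * v_t * v_t
             + 0.5 * rho * (v_t - v_u) ** 2) / (cd * cd)
    dp = minor + pipe_dp_kernel(am, throat_l, lumen_d, rho, mu)
    return dp if mdot > 0.0 else -dp


@njit(cache=True)
def reynolds_kernel(mdot, diameter, mu):
    return 4.0 * abs(mdot) / (PI * diameter * mu)


# chain descriptor: ch[0] kind, ch[1] rho_up, ch[2] rho_dn, ch[3] mu, rest per kind
# kind 0 source: 4 R_fwd, 5 R_rev, 6 q_smooth, 7 L, 8 D
# kind 1 limb:   4 has_res, 5 d_res, 6 Lt, 7 Cd, 8 Kc, 9 L, 10 D, 11 D_up
# kind 2 lung:   4 d_ett, 5 L_ett, 6 R_aw
@njit(cache=True)
def _chain_dp(mdot, ch):
    kind = int(ch[0])
    rho_u = ch[1]
    rho_d = ch[2]
    mu = ch[3]
    rho = 0.5 * (rho_u + rho_d)
    if kind == 0:
        dp = pipe_dp_kernel(mdot, ch[7], ch[8], rho, mu)
        area = 0.25 * PI * ch[8] * ch[8]
        dp += (mdot / area) ** 2 * (1.0 / rho_u - 1.0 / rho_d)
        rfwd = ch[4]
        rrev = ch[5]
        if rfwd > 0.0 or rrev > 0.0:
            q = mdot / rho
            qs = ch[6]
            if rfwd == rrev or qs <= 0.0:
                dp += (rfwd if mdot >= 0.0 else rrev) * q
            else:
                w = 0.5 * (1.0 + np.tanh(q / qs))
                dp += (w * rfwd + (1.0 - w) * rrev) * q
        return dp
    elif kind == 1:
        dp = pipe_dp_kernel(mdot, ch[9], ch[10], rho, mu)
        if ch[4] > 0.0:
            dp += resistor_dp_kernel(mdot, ch[5], ch[6], ch[7], ch[8], ch[11], rho, mu)
        area = 0.25 * PI * ch[10] * ch[10]
        dp += (mdot / area) ** 2 * (1.0 / rho_u - 1.0 / rho_d)
        return dp
    else:
        dp = pipe_dp_kernel(mdot, ch[5], ch[4], rho, mu)
        dp += ch[6] * mdot / rho
        return dp


@njit(cache=True)
def _solve_chain(p_up, p_dn, ch):
    """Mass flow through a series connection given end pressures.

    The loss laws are monotone odd functions of the flow, so the residual
    F(m) = dp_chain(m) - (p_up - p_dn) brackets a unique root; solved by
    doubling bracket expansion + Illinois-damped regula falsi.
    """
    d_p = p_up - p_dn
    if d_p == 0.0:
        return 0.0
    ftol = _FTOL_BASE * (1.0 + abs(d_p))
    if d_p > 0.0:
        a = 0.0
        fa = -d_p
        b = 1e-5
        fb = _chain_dp(b, ch) - d_p
        n = 0
        while fb < 0.0 and n < 200:
            a = b
            fa = fb
            b *= 2.0
            fb = _chain_dp(b, ch) - d_p
            n += 1
    else:
        b = 0.0
        fb = -d_p
        a = -1e-5
        fa = _chain_dp(a, ch) - d_p
        n = 0
        while fa > 0.0 and n < 200:
            b = a
            fb = fa
            a *= 2.0
            fa = _chain_dp(a, ch) - d_p
            n += 1
    side = 0
    m = 0.5 * (a + b)
    for _ in range(160):
        denom = fb - fa
        if denom == 0.0:
            break
        m = b - fb * (b - a) / denom
        if m <= a or m >= b:
            m = 0.5 * (a + b)
        fm = _chain_dp(m, ch) - d_p
        if abs(fm) < ftol or (b - a) < 1e-16 + 1e-12 * abs(m):
            return m
        if fm > 0.0:
            if side == 1:
                fa *= 0.5
            b = m
            fb = fm
            side = 1
        else:
            if side == -1:
                fb *= 0.5
            a = m
            fa = fm
            side = -1
    return m


@njit(cache=True)
def pc_setpoint_kernel(tau, t_insp, rise, p_pip, p_peep):
    """Pulse-wave pressure setpoint with linear ramps, Pa gauge; tau in [0, T)."""
    if tau < rise:
        return p_peep + (p_pip - p_peep) * tau / rise
    elif tau < t_insp:
        return p_pip
    elif tau < t_insp + rise:
        return p_pip - (p_pip - p_peep) * (tau - t_insp) / rise
    else:
        return p_peep


@njit(cache=True)
def vc_flow_kernel(tau, t_insp, rise, q_plateau):
    """Trapezoidal inspiratory flow setpoint, m3/s; zero during expiration."""
    if tau < rise:
        return q_plateau * tau / rise
    elif tau < t_insp - rise:
        return q_plateau
    elif tau < t_insp:
        return q_plateau * (t_insp - tau) / rise
    else:
        return 0.0


@njit(cache=True)
def _flows(t, y, p, scr):
    """Solve the four (five with source) connection flows at state y, kg/s.

    Returns (m_src, m_limb_A, m_limb_B, m_lung_A, m_lung_B), positive toward
    the patient.
    """
    rs = p[P_RS]
    mu = p[P_MU]
    patm = p[P_PATM]
    energy = p[P_ENERGY] != 0.0
    t_ref = p[P_T]
    p_i = y[0]
    p_a = y[1]
    p_b = y[2]
    if energy:
        t_i = y[8]
        t_a = y[9]
        t_b = y[10]
    else:
        t_i = t_ref
        t_a = t_ref
        t_b = t_ref
    rho_i = p_i / (rs * t_i)
    rho_a = p_a / (rs * t_a)
    rho_b = p_b / (rs * t_b)

    tau = t % p[P_PERIOD]
    ch = scr[0]
    if p[P_MODE] == 0.0 or tau >= p[P_TINSP]:
        if p[P_MODE] == 0.0:
            p_src = patm + pc_setpoint_kernel(tau, p[P_TINSP], p[P_RISE],
                                              p[P_PIP], p[P_PEEP])
        else:
            p_src = patm + p[P_PEEP]
        rho_s = p_src / (rs * t_ref)
        ch[0] = 0.0
        ch[1] = rho_s
        ch[2] = rho_i
        ch[3] = mu
        ch[4] = p[P_RFWD]
        ch[5] = p[P_RREV]
        ch[6] = p[P_QSM]
        ch[7] = p[P_LSH]
        ch[8] = p[P_DSH]
        m_src = _solve_chain(p_src, p_i, ch)
    else:
        m_src = rho_i * vc_flow_kernel(tau, p[P_TINSP], p[P_RISE], p[P_QVC])

    m_limb = np.zeros(2)
    m_lung = np.zeros(2)
    for i in range(2):
        if i == 1 and p[P_HASB] == 0.0:
            break
        off = LIMB_A if i == 0 else LIMB_B
        p_l = p_a if i == 0 else p_b
        rho_l = rho_a if i == 0 else rho_b
        vol = y[3 + i]
        ch = scr[1 + i]
        ch[0] = 1.0
        ch[1] = rho_i
        ch[2] = rho_l
        ch[3] = mu
        ch[4] = p[off + L_HASRES]
        ch[5] = p[off + L_DRES]
        ch[6] = p[off + L_LT]
        ch[7] = p[off + L_CD]
        ch[8] = p[off + L_KC]
        ch[9] = p[off + L_LTUBE]
        ch[10] = p[off + L_DTUBE]
        ch[11] = p[off + L_DTUBE]
        m_limb[i] = _solve_chain(p_i, p_l, ch)
        chl = scr[3 + i]
        chl[0] = 2.0
        chl[1] = rho_l
        chl[2] = rho_l
        chl[3] = mu
        chl[4] = p[off + L_DETT]
        chl[5] = p[off + L_LETT]
        chl[6] = p[off + L_RAW]
        p_alv = patm + vol / p[off + L_C]
        m_lung[i] = _solve_chain(p_l, p_alv, chl)
    return m_src, m_limb[0], m_limb[1], m_lung[0], m_lung[1]


@njit(cache=True)
def rhs_kernel(y, t, p, scr):
    """Time derivative of the circuit state (odeint convention f(y, t))."""
    rs = p[P_RS]
    energy = p[P_ENERGY] != 0.0
    t_ref = p[P_T]
    m_src, m_la, m_lb, m_ga, m_gb = _flows(t, y, p, scr)
    if energy:
        dy = np.zeros(NSTATE_ENERGY)
        t_i = y[8]
        t_a = y[9]
        t_b = y[10]
    else:
        dy = np.zeros(NSTATE_ISO)
        t_i = t_ref
        t_a = t_ref
        t_b = t_ref
    rho_a = y[1] / (rs * t_a)
    rho_b = y[2] / (rs * t_b)

    if not energy:
        rst = rs * t_ref
        dy[0] = (m_src - m_la - m_lb) * rst / p[P_VI]
        dy[1] = (m_la - m_ga) * rst / p[LIMB_A + L_VNODE]
        if p[P_HASB] != 0.0:
            dy[2] = (m_lb - m_gb) * rst / p[LIMB_B + L_VNODE]
    else:
        cv = p[P_CV]
        cp = cv + rs
        # enthalpy advection with upwind temperatures; Q_H = 0 (adiabatic walls)
        phi_src = m_src * cp * (t_ref if m_src > 0.0 else t_i)
        phi_a = m_la * cp * (t_i if m_la > 0.0 else t_a)
        phi_b = m_lb * cp * (t_i if m_lb > 0.0 else t_b)
        phi_ga = m_ga * cp * (t_a if m_ga > 0.0 else t_ref)
        phi_gb = m_gb * cp * (t_b if m_gb > 0.0 else t_ref)
        # dU/dp = V cv / R, dU/dT = 0 for an ideal gas at fixed p, V
        dy[0] = (phi_src - phi_a - phi_b) * rs / (p[P_VI] * cv)
        dy[1] = (phi_a - phi_ga) * rs / (p[LIMB_A + L_VNODE] * cv)
        # dM/dp dp/dt + dM/dT dT/dt = m_net  =>  dT/dt from the mass balance
        dy[8] = (t_i / y[0]) * dy[0] - (rs * t_i * t_i / (y[0] * p[P_VI])) * (
            m_src - m_la - m_lb)
        dy[9] = (t_a / y[1]) * dy[1] - (rs * t_a * t_a / (y[1] * p[LIMB_A + L_VNODE])) * (
            m_la - m_ga)
        if p[P_HASB] != 0.0:
            dy[2] = (phi_b - phi_gb) * rs / (p[LIMB_B + L_VNODE] * cv)
            dy[10] = (t_b / y[2]) * dy[2] - (rs * t_b * t_b / (y[2] * p[LIMB_B + L_VNODE])) * (
                m_lb - m_gb)

    dy[3] = m_ga / rho_a
    if p[P_HASB] != 0.0:
        dy[4] = m_gb / rho_b
    dy[5] = m_src
    dy[6] = m_la
    dy[7] = m_lb
    return dy


@njit(cache=True)
def recover_flows_kernel(ts, ys, p):
    """Re-solve all connection flows at sampled states; kg/s, (n, 5)."""
    n = ts.shape[0]
    out = np.empty((n, 5))
    scr = np.zeros((5, 16))
    for k in range(n):
        m_src, m_la, m_lb, m_ga, m_gb = _flows(ts[k], ys[k], p, scr)
        out[k, 0] = m_src
        out[k, 1] = m_la
        out[k, 2] = m_lb
        out[k, 3] = m_ga
        out[k, 4] = m_gb
    return out
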