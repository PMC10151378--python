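"""Fused network integrator.

One numba-compiled loop advances every HH population, the pooled
conductance synapses, the LC gap-junction grid and NE release cascade, the
lung/gas-exchange loop, the autonomic transmitter pools and the
FitzHugh-Nagumo cardiac cable with a shared Euler / Euler-Maruyama step.
The per-neuron membrane math mirrors :mod:`lcne.neuron_core` exactly (an
equivalence test holds the two together); everything is flat arrays so the
80 s production runs at dt = 1e-4 s stay within interactive budgets.

Scalar traces are recorded every ``rec_stride`` steps together with
per-population spike counts accumulated over each recording bin.
"""

import math

import numpy as np
from numba import njit

from ._dynamics import co2_gate_scalar, hill_ne_scalar, hill_ach_scalar

# ---- recorded scalar channel layout -------------------------------------
REC_GNE = 0
REC_INSP = 1
REC_EXP = 2
REC_VL = 3
REC_PCO2 = 4
REC_PO2 = 5
REC_PBRAIN = 6
REC_PNE = 7
REC_QACH = 8
REC_VHEART = 9
REC_PSR = 10
REC_PHI = 11
REC_RRVLM = 12
REC_RAMB = 13
N_REC_SCALARS = 14

# ---- respiratory parameter slot layout (rp array) -----------------------
RP_V_REST = 0
RP_ELAST = 1
RP_RESIST = 2
RP_P_INSP = 3
RP_P_EXP = 4
RP_TAU_MOT = 5
RP_RNORM_I = 6
RP_RNORM_E = 7
RP_PSR_SCALE = 8
RP_G_CO2 = 9
RP_BETA_CO2 = 10
RP_M_CO2 = 11
RP_G_O2 = 12
RP_BETA_O2 = 13
RP_M_O2 = 14
RP_PO2_AIR = 15
RP_CHEM_MID = 16
RP_CHEM_WID = 17
RP_TAU_BRAIN = 18
RP_S_SCALE = 19
RP_TAU0 = 20
RP_TAU1 = 21
RP_KAPPA = 22
RP_GNE0 = 23
RP_VSYN_I = 24
RP_G_GAP = 25
N_RP = 26

# ---- cardiac parameter slot layout (cp array) ---------------------------
CP_D_DIFF = 0
CP_ALPHA = 1
CP_D = 2
CP_C_MIN = 3
CP_C_MAX = 4
CP_B_MIN = 5
CP_B_MAX = 6
CP_P_MID = 7
CP_Q_MID = 8
CP_A_NE = 9
CP_A_ACH = 10
CP_TAU_MOD = 11
CP_K_NE = 12
CP_K_ACH = 13
CP_TAU_RATE = 14
CP_W_PACE = 15
CP_PACE_GRAD = 16
N_CP = 17

SPIKE_TH = -20.0
REFRAC_S = 2e-3

# ---- channel-kinetics lookup tables --------------------------------------
# the five voltage functions dominate the integration cost; they are
# tabulated on a 0.02 mV grid and linearly interpolated (error < 1e-6)
VT_MIN = -130.0
VT_MAX = 70.0
VT_STEP = 0.02
VT_N = int(round((VT_MAX - VT_MIN) / VT_STEP)) + 1


def build_tables():
    """Tabulate mK_inf, mNa_inf, hNa_inf, 1/tau_mK, 1/tau_hNa on the
    voltage grid, using the same scalar kinetics as the reference path."""
    import numpy as _np

    from ._dynamics import (alpha_k, beta_k, mna_inf, hna_inf, tau_mk,
                            tau_hna)

    v = VT_MIN + VT_STEP * _np.arange(VT_N)
    t_mk = _np.empty(VT_N)
    t_mna = _np.empty(VT_N)
    t_h = _np.empty(VT_N)
    t_itmk = _np.empty(VT_N)
    t_ith = _np.empty(VT_N)
    for i, vi in enumerate(v):
        ak = alpha_k(vi)
        bk = beta_k(vi)
        t_mk[i] = ak / (ak + bk)
        t_mna[i] = mna_inf(vi)
        t_h[i] = hna_inf(vi)
        t_itmk[i] = 1.0 / tau_mk(vi)
        t_ith[i] = 1.0 / tau_hna(vi)
    return t_mk, t_mna, t_h, t_itmk, t_ith


@njit(cache=True, fastmath=True)
def run_network(
    # per-neuron state / constants
    V, mK, hNa, EL, Cm, gK, gNa, gLk, EKv, ENav, sig, tauKs, bias,
    a_state, a_inc, a_dec, refrac,
    # population structure
    pop_start, g_chem, g_cchem, g_psr,
    # projections
    p_src, p_tgt, p_dec, p_w, p_E, p_phi, p_gate, p_depU, p_dep_dec, p_res,
    # LC specifics
    ip_lc, gap_nbr, gap_cnt,
    # special population indices (-1 if absent)
    ip_prei, ip_rampi, ip_cvrg, ip_rvlm, ip_amb,
    # subsystem parameter packs and cardiac state
    rp, cp, vcab, wcab,
    # run controls
    nsteps, dt, amp, freq, onset, rec_stride, clamp_pco2, seed,
    has_ne, has_resp, has_cardiac,
    # channel-kinetics tables
    t_mk, t_mna, t_h, t_itmk, t_ith,
    # outputs (preallocated)
    rec_scal, rec_counts, tot_counts,
):
    np.random.seed(seed)
    n = V.shape[0]
    npop = pop_start.shape[0] - 1
    nproj = p_src.shape[0]
    ncab = vcab.shape[0]
    dt_ms = dt * 1e3
    refrac_steps = max(1, int(round(REFRAC_S / dt)))
    two_pi_f = 2.0 * math.pi * freq

    # scalar state
    y_ne = 0.0
    g_ne = 0.0
    v_l = rp[RP_V_REST]
    pco2 = 40.0 if clamp_pco2 <= 0.0 else clamp_pco2
    po2 = 100.0
    pco2_alv = pco2 - 8.0
    po2_alv = po2 + 10.0
    pbrain = pco2
    r_insp = 0.0
    r_exp = 0.0
    insp_act = 0.0
    exp_act = 0.0
    psr = 0.0
    r_rvlm = 0.0
    r_amb = 0.0
    p_ne = cp[CP_P_MID]
    q_ach = cp[CP_Q_MID]
    phi = co2_gate_scalar(pco2, rp[RP_S_SCALE])
    chem = 0.5
    cchem = 0.5

    isyn = np.zeros(n)
    counts = np.zeros(npop)
    counts_bin = np.zeros(npop, dtype=np.float32)
    neuron_pop = np.empty(n, dtype=np.int64)
    for p in range(npop):
        for i in range(pop_start[p], pop_start[p + 1]):
            neuron_pop[i] = p
    lc_lo = pop_start[ip_lc] if ip_lc >= 0 else -1
    lc_hi = pop_start[ip_lc + 1] if ip_lc >= 0 else -1
    n_lc = lc_hi - lc_lo if ip_lc >= 0 else 0
    status = 0
    rec_row = 0

    for step in range(nsteps):
        t = step * dt

        # ---- scalar signals ------------------------------------------
        phi = co2_gate_scalar(pco2, rp[RP_S_SCALE])
        chem = 1.0 / (1.0 + math.exp(-(pco2 - rp[RP_CHEM_MID])
                                     / rp[RP_CHEM_WID]))
        cchem = 1.0 / (1.0 + math.exp(-(pbrain - rp[RP_CHEM_MID])
                                      / rp[RP_CHEM_WID]))
        if has_resp:
            stretch = (v_l - rp[RP_V_REST]) / rp[RP_PSR_SCALE]
            psr = stretch if stretch > 0.0 else 0.0

        i_vib = 0.0
        if amp != 0.0 and freq > 0.0 and t >= onset:
            i_vib = amp * math.sin(two_pi_f * (t - onset))

        # ---- synaptic currents ---------------------------------------
        for i in range(n):
            isyn[i] = 0.0
        for k in range(nproj):
            g = p_gate[k]
            if g <= 1e-12:
                continue
            wgtd = p_w[k] * g
            if p_phi[k]:
                wgtd *= phi
            erev = p_E[k]
            tgt = p_tgt[k]
            for i in range(pop_start[tgt], pop_start[tgt + 1]):
                isyn[i] += wgtd * (V[i] - erev)

        # ---- membrane update -----------------------------------------
        for p in range(npop):
            counts[p] = 0.0
        for i in range(n):
            v = V[i]
            p = neuron_pop[i]
            is_lc = 1 if (i >= lc_lo and i < lc_hi) else 0

            # channel kinetics via the interpolated tables
            xi = (v - VT_MIN) / VT_STEP
            if xi < 0.0:
                xi = 0.0
            elif xi > VT_N - 1.001:
                xi = VT_N - 1.001
            i0 = int(xi)
            fr = xi - i0
            mkinf = t_mk[i0] + fr * (t_mk[i0 + 1] - t_mk[i0])
            mna = t_mna[i0] + fr * (t_mna[i0 + 1] - t_mna[i0])
            hinf = t_h[i0] + fr * (t_h[i0 + 1] - t_h[i0])
            inv_tmk = (t_itmk[i0] + fr * (t_itmk[i0 + 1] - t_itmk[i0])) \
                / tauKs[i]
            inv_thna = t_ith[i0] + fr * (t_ith[i0 + 1] - t_ith[i0])

            gl_eff = gLk[i]
            i_extra = isyn[i]
            if is_lc:
                gl_eff *= phi
                # gap junctions from the 8-neighbourhood
                j0 = i - lc_lo
                acc = 0.0
                for q in range(gap_cnt[j0]):
                    acc += v - V[lc_lo + gap_nbr[j0, q]]
                i_extra += rp[RP_G_GAP] * acc
                # NE self-inhibition and the vibration input (-I slot)
                i_extra += rp[RP_GNE0] * g_ne * (v - rp[RP_VSYN_I])
                i_extra += i_vib

            mk2 = mK[i] * mK[i]
            i_ion = (gK[i] * mk2 * mk2 * (v - EKv[i])
                     + gNa[i] * mna * mna * mna * hNa[i] * (v - ENav[i])
                     + gl_eff * (v - EL[i])
                     + a_state[i] * (v - EKv[i]))

            i_noise = 0.0
            if sig[i] > 0.0:
                i_noise = sig[i] * np.random.normal(0.0, 1.0)

            # scalar-signal field drives (chemo- and stretch-receptor)
            i_field = (g_chem[p] * chem + g_cchem[p] * cchem
                       + g_psr[p] * psr)

            v_new = v + dt_ms * (-(i_ion + i_extra + i_noise)
                                 + bias[i] + i_field) / Cm[i]

            mk_new = mK[i] + (dt_ms * inv_tmk) * (mkinf - mK[i])
            if mk_new < 0.0:
                mk_new = 0.0
            elif mk_new > 1.0:
                mk_new = 1.0
            h_new = hNa[i] + (dt_ms * inv_thna) * (hinf - hNa[i])
            if h_new < 0.0:
                h_new = 0.0
            elif h_new > 1.0:
                h_new = 1.0

            spiked = 0
            if v < SPIKE_TH and v_new >= SPIKE_TH and refrac[i] <= 0:
                spiked = 1
                refrac[i] = refrac_steps
                counts[p] += 1.0
                a_state[i] += a_inc[i]
            elif refrac[i] > 0:
                refrac[i] -= 1

            a_state[i] *= a_dec[i]
            V[i] = v_new
            mK[i] = mk_new
            hNa[i] = h_new

        # numerical guard (cheap scan every 10 ms)
        if step % 100 == 0:
            for i in range(n):
                if not (-500.0 < V[i] < 500.0):
                    status = 1
                    return status, rec_row
        for p in range(npop):
            counts_bin[p] += counts[p]
            tot_counts[p] += counts[p]

        # ---- synaptic gates (with optional short-term depression) ----
        for k in range(nproj):
            src = p_src[k]
            nsrc = pop_start[src + 1] - pop_start[src]
            rel = counts[src] / nsrc
            if p_depU[k] > 0.0:
                p_gate[k] = p_gate[k] * p_dec[k] + p_res[k] * rel
                p_res[k] = 1.0 - (1.0 - p_res[k]) * p_dep_dec[k]
                if rel > 0.0:
                    p_res[k] *= math.exp(-p_depU[k] * rel)
            else:
                p_gate[k] = p_gate[k] * p_dec[k] + rel

        # ---- NE release cascade --------------------------------------
        if has_ne and ip_lc >= 0:
            y_ne += dt * (-y_ne) / rp[RP_TAU0] \
                + rp[RP_KAPPA] * counts[ip_lc] / rp[RP_TAU0]
            g_ne += dt * (y_ne - g_ne) / rp[RP_TAU1]

        # ---- respiratory mechanics and gas exchange ------------------
        if has_resp:
            if ip_rampi >= 0:
                nr = pop_start[ip_rampi + 1] - pop_start[ip_rampi]
                inst = counts[ip_rampi] / (nr * dt)
                r_insp += dt * (inst - r_insp) / rp[RP_TAU_MOT]
            if ip_cvrg >= 0:
                ne_ = pop_start[ip_cvrg + 1] - pop_start[ip_cvrg]
                inst = counts[ip_cvrg] / (ne_ * dt)
                r_exp += dt * (inst - r_exp) / rp[RP_TAU_MOT]
            insp_act = r_insp / rp[RP_RNORM_I]
            if insp_act > 1.0:
                insp_act = 1.0
            exp_act = r_exp / rp[RP_RNORM_E]
            if exp_act > 1.0:
                exp_act = 1.0

            flow = (rp[RP_P_INSP] * insp_act - rp[RP_P_EXP] * exp_act
                    - rp[RP_ELAST] * (v_l - rp[RP_V_REST])) / rp[RP_RESIST]
            v_l += dt * flow
            if v_l <= 0.1:
                status = 2
                return status, rec_row

            # gas exchange: blood <-> alveoli flux proportional to the
            # tension gradient; inspired air dilutes the alveolar gas
            # (inflow only -- expired gas leaves at alveolar composition)
            v_in = flow if flow > 0.0 else 0.0
            flux_c = rp[RP_G_CO2] * (pco2 - pco2_alv)        # [L/s]
            flux_o = rp[RP_G_O2] * (po2_alv - po2)
            pco2_alv += dt * (flux_c * 760.0 - v_in * pco2_alv) / v_l
            po2_alv += dt * (-flux_o * 760.0
                             + v_in * (rp[RP_PO2_AIR] - po2_alv)) / v_l
            if clamp_pco2 <= 0.0:
                pco2 += dt * (rp[RP_M_CO2] - flux_c) / rp[RP_BETA_CO2]
                po2 += dt * (flux_o - rp[RP_M_O2]) / rp[RP_BETA_O2]
                if pco2 < 5.0:
                    pco2 = 5.0
                if po2 < 20.0:
                    po2 = 20.0
            if pco2_alv < 0.0 or po2_alv < 0.0:
                status = 3
                return status, rec_row
            pbrain += dt * (pco2 - pbrain) / rp[RP_TAU_BRAIN]

        # ---- autonomic outflow and cardiac tissue --------------------
        if has_cardiac:
            if ip_rvlm >= 0:
                nr = pop_start[ip_rvlm + 1] - pop_start[ip_rvlm]
                inst = counts[ip_rvlm] / (nr * dt)
                r_rvlm += dt * (inst - r_rvlm) / cp[CP_TAU_RATE]
            if ip_amb >= 0:
                na = pop_start[ip_amb + 1] - pop_start[ip_amb]
                inst = counts[ip_amb] / (na * dt)
                r_amb += dt * (inst - r_amb) / cp[CP_TAU_RATE]
            p_ne += dt * (cp[CP_K_NE] * r_rvlm - p_ne) / cp[CP_TAU_MOD]
            q_ach += dt * (cp[CP_K_ACH] * r_amb - q_ach) / cp[CP_TAU_MOD]
            if p_ne < 1e-3:
                p_ne = 1e-3
            if q_ach < 1e-3:
                q_ach = 1e-3
            h_ne = hill_ne_scalar(p_ne, cp[CP_P_MID], cp[CP_A_NE])
            h_ach = hill_ach_scalar(q_ach, cp[CP_Q_MID], cp[CP_A_ACH])
            gc = (cp[CP_C_MAX] - cp[CP_C_MIN]) * h_ne + cp[CP_C_MIN]
            b = (cp[CP_B_MAX] - cp[CP_B_MIN]) * h_ach + cp[CP_B_MIN]
            dd = cp[CP_D_DIFF]
            al = cp[CP_ALPHA]
            dpar = cp[CP_D]
            for j in range(ncab):
                vj = vcab[j]
                lap = 0.0
                if j > 0:
                    lap += vcab[j - 1] - vj
                if j < ncab - 1:
                    lap += vcab[j + 1] - vj
                i_ext = dd * lap
                f = vj * (vj - al) * (1.0 - vj) - wcab[j]
                dv = gc * f + i_ext
                if dv < 0.0:
                    dv = gc * 0.22 * f + i_ext
                # graded intrinsic-rate offset: the pacemaker end leads and
                # the excitation propagates down the cable with a lag
                woff = cp[CP_W_PACE] * (1.0 - cp[CP_PACE_GRAD] * j
                                        / (ncab - 1))
                vcab[j] = vj + dt * dv
                wcab[j] += dt * b * (vj - dpar * wcab[j] - woff)

        # ---- recording -----------------------------------------------
        if (step + 1) % rec_stride == 0 and rec_row < rec_scal.shape[0]:
            rec_scal[rec_row, REC_GNE] = g_ne
            rec_scal[rec_row, REC_INSP] = insp_act
            rec_scal[rec_row, REC_EXP] = exp_act
            rec_scal[rec_row, REC_VL] = v_l
            rec_scal[rec_row, REC_PCO2] = pco2
            rec_scal[rec_row, REC_PO2] = po2
            rec_scal[rec_row, REC_PBRAIN] = pbrain
            rec_scal[rec_row, REC_PNE] = p_ne
            rec_scal[rec_row, REC_QACH] = q_ach
            rec_scal[rec_row, REC_VHEART] = vcab[ncab - 1]
            rec_scal[rec_row, REC_PSR] = psr
            rec_scal[rec_row, REC_PHI] = phi
            rec_scal[rec_row, REC_RRVLM] = r_rvlm
            rec_scal[rec_row, REC_RAMB] = r_amb
            for p in range(npop):
                rec_counts[rec_row, p] = counts_bin[p]
                counts_bin[p] = 0.0
            rec_row += 1

    return status, rec_row
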