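"""Time-stepped network integration.

Advances all populations in lock-step 0.5 ms map iterations.  Presynaptic
spikes are delivered through a ring buffer after their synapse's conduction
delay; per-neuron per-receptor conductances share a single exponential decay,
so only one conductance accumulator per (cell, receptor) is needed.
Depression and the mini-rate modulation depend only on the presynaptic spike
train and are therefore stored per presynaptic cell.

Miniature PSPs arrive as one aggregated Poisson process per postsynaptic
cell: the maximal per-neuron rate, modulated by the mean activity factor of
the cell's presynaptic pool, with each event adding the cell's mean
per-synapse mini conductance (compensation-scaled).  The modulated rate is
refreshed every few steps, far faster than its ~175 ms timescale.

All randomness derives from a single master seed through named substreams
recorded in the manifest.  Identical configuration and seed give bit-identical
spike rasters.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from numba import njit

from .connectome import (
    AMPA,
    NMDA,
    GABA_A,
    CORTICAL_EXC_CLASSES,
    LOCAL_INH,
    THALAMOCORTICAL,
    Connectome,
    N_LAYERS,
)
from .mesh import HemisphereMesh
from .neurons import BRAIN_STATES, MapParams, SynapseParams

logger = logging.getLogger(__name__)

DT_MS = 0.5


@dataclasses.dataclass
class RunConfig:
    """Engine knobs for one simulation run."""

    duration_s: float = 10.0
    seed: int = 0
    state: str = "sleep"
    dt_ms: float = DT_MS
    #: absolute synaptic strength: multiplies every cortical synaptic
    #: conductance.  The base connection strength is a free parameter of the
    #: model; the default is calibrated once so that the baseline sleep
    #: network at the default scale generates global slow waves (and the
    #: wake network fires tonically in the physiological range).
    syn_gain: float = 26.5
    minis_on: bool = True
    thalamus_on: bool = True
    I_DC: float = 0.0
    record_stride: int = 4            # per-cell voltage recording stride (steps)
    record_parcels: bool = False
    record_all_py_hist: bool = False
    hist_skip_s: float = 2.0          # burn-in excluded from the voltage histogram
    spike_buffer: int = 4_000_000
    #: steps between recomputations of the per-neuron mini rate (the
    #: activity modulation varies on a ~175 ms timescale, so a 10 ms refresh
    #: is effectively exact and removes the dominant per-step cost)
    mini_update_stride: int = 4
    # thalamic synaptic conversion (map-conductance -> uA/cm2 drive)
    thal_syn_scale: float = 1.0
    hh_substeps: int = 25          # 0.02 ms RK4 sub-steps inside each map step


@dataclasses.dataclass
class SimulationRun:
    """Recorded signals of one run (voltages mV, times in 0.5 ms steps)."""

    dt_ms: float
    n_steps: int
    state: str
    mean_v_l2: np.ndarray            # (n_steps,) mean L2 PY voltage, active columns
    mean_v_all: np.ndarray           # (n_steps,) mean PY voltage over all layers
    v_l2: np.ndarray                 # (n_rec, n_active_columns) f32, stride sampled
    record_stride: int
    active_columns: np.ndarray       # column ids for v_l2 columns
    spike_counts: np.ndarray         # (n_cells,)
    spikes: np.ndarray               # (n_spikes, 2) [cell, step], possibly truncated
    spikes_truncated: bool
    parcel_v: np.ndarray | None      # (n_steps, n_parcels) f32 mean voltage (all cells)
    py_hist: np.ndarray | None       # (160,) voltage histogram counts, 1 mV bins from -120
    final_state: dict | None
    manifest: dict

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_ms / 1000.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms / 1000.0


HIST_LO, HIST_BINS = -120.0, 160  # 1 mV bins, [-120, 40)


def set_brain_state(
    map_params: MapParams, syn_params: SynapseParams, state: str
) -> tuple[MapParams, SynapseParams, dict]:
    """Overlay the wake/sleep parameter set on the cortical/synaptic baselines.

    Returns new parameter objects plus the thalamic leak overlay; all other
    parameters are untouched.  Applying a state twice is idempotent.
    """
    if state not in BRAIN_STATES:
        raise ValueError(f"unknown brain state {state!r}; expected one of {sorted(BRAIN_STATES)}")
    ov = BRAIN_STATES[state]
    mp = dataclasses.replace(map_params, p_L=ov["p_L"], p_D=ov["p_D"])
    sy = dataclasses.replace(
        syn_params,
        G_AMPA_syn_py=ov["G_AMPA_syn_py"],
        G_AMPA_syn_in=ov["G_AMPA_syn_in"],
        G_GABA_syn_py=ov["G_GABA_syn_py"],
    )
    return mp, sy, {"g_KL_TC": ov["g_KL_TC"], "g_KL_RE": ov["g_KL_RE"]}


def _synapse_increments(
    conn: Connectome, syn: SynapseParams, cfg: RunConfig
) -> np.ndarray:
    """Per-synapse delivered conductance increment (before depression)."""
    w_norm = conn.normalized_weights().astype(np.float64)
    n_py = conn.n_py
    n_ctx = conn.n_cortical
    post = conn.post
    rec = conn.receptor
    G = np.zeros(conn.n_synapses)
    post_is_py = post < n_py
    post_is_ctx = post < n_ctx
    m_ampa = rec == AMPA
    G[m_ampa & post_is_py] = syn.G_AMPA_syn_py
    G[m_ampa & ~post_is_py & post_is_ctx] = syn.G_AMPA_syn_in
    G[(rec == NMDA) & post_is_ctx] = syn.G_NMDA_syn_py
    G[(rec == GABA_A) & post_is_ctx] = syn.G_GABA_syn_py
    # synapses onto thalamic cells use the same table scaled separately
    G[~post_is_ctx] = np.where(rec[~post_is_ctx] == GABA_A, syn.G_GABA_syn_py, syn.G_AMPA_syn_py)
    return (G * cfg.syn_gain * w_norm).astype(np.float64)


def _mini_csr(conn: Connectome, syn: SynapseParams, cfg: RunConfig):
    """CSR (by post cell) of intracortical AMPA synapses for mini generation."""
    n_py = conn.n_py
    mask = (
        (conn.receptor == AMPA)
        & (conn.pre < n_py)
        & (conn.post < conn.n_cortical)
        & (conn.weight_factor > 0)
    )
    post = conn.post[mask]
    pre = conn.pre[mask]
    order = np.argsort(post, kind="stable")
    post, pre = post[order], pre[order]
    indptr = np.zeros(conn.n_cells + 1, dtype=np.int64)
    np.add.at(indptr, post + 1, 1)
    indptr = np.cumsum(indptr)
    cnt = np.diff(indptr)
    nz = cnt > 0
    # Mini events arrive at the maximal rate mu_bar per target neuron, with
    # the rate modulated by the mean activity factor of that neuron's
    # presynaptic pool.  Each event adds the population-mean per-synapse mini
    # conductance (the per-neuron total mini drive is homogeneous across
    # cells and invariant under ablation-with-compensation).
    w_rel = np.repeat(1.0 / np.maximum(cnt, 1), cnt)
    budget = conn.base_denom[:, AMPA]
    abar = np.zeros(conn.n_cells)
    abar[nz] = syn.G_AMPA_mini * cfg.syn_gain * budget[nz] / cnt[nz]
    return indptr, pre.astype(np.int32), w_rel.astype(np.float64), abar, np.ones(conn.n_cells)


def _pre_csr(conn: Connectome):
    order = np.argsort(conn.pre, kind="stable")
    indptr = np.zeros(conn.n_cells + 1, dtype=np.int64)
    np.add.at(indptr, conn.pre + 1, 1)
    indptr = np.cumsum(indptr)
    return order, indptr


@njit(cache=True)
def _hh_deriv(V, m, h, n, mT, hT, mh, I_ext, is_tc,
              C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, g_T, E_Ca, g_KL, E_KL, g_h, E_h, V_tr):
    v2 = V - V_tr
    z = (13.0 - v2) / 4.0
    a_m = 0.32 * 4.0 * (1.0 - z / 2.0 if abs(z) < 1e-7 else z / (math.exp(z) - 1.0))
    z = (v2 - 40.0) / 5.0
    b_m = 0.28 * 5.0 * (1.0 - z / 2.0 if abs(z) < 1e-7 else z / (math.exp(z) - 1.0))
    a_h = 0.128 * math.exp((17.0 - v2) / 18.0)
    b_h = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    z = (15.0 - v2) / 5.0
    a_n = 0.032 * 5.0 * (1.0 - z / 2.0 if abs(z) < 1e-7 else z / (math.exp(z) - 1.0))
    b_n = 0.5 * math.exp((10.0 - v2) / 40.0)
    if is_tc:
        mT_inf = 1.0 / (1.0 + math.exp(-(V + 57.0) / 6.2))
        tau_mT = (0.612 + 1.0 / (math.exp(-(V + 132.0) / 16.7) + math.exp((V + 16.8) / 18.2))) / 3.74
        hT_inf = 1.0 / (1.0 + math.exp((V + 81.0) / 4.0))
        tau_hT = (30.8 + (211.4 + math.exp((V + 113.2) / 5.0)) / (1.0 + math.exp((V + 84.0) / 3.2))) / 3.74
    else:
        mT_inf = 1.0 / (1.0 + math.exp(-(V + 52.0) / 7.4))
        tau_mT = (1.0 + 0.33 / (math.exp((V + 27.0) / 10.0) + math.exp(-(V + 102.0) / 15.0))) / 3.0
        hT_inf = 1.0 / (1.0 + math.exp((V + 80.0) / 5.0))
        tau_hT = (85.0 + 1.0 / (math.exp((V + 48.0) / 4.0) + math.exp(-(V + 407.0) / 50.0))) / 3.0
    mh_inf = 1.0 / (1.0 + math.exp((V + 75.0) / 5.5))
    tau_mh = 20.0 + 1000.0 / (math.exp((V + 71.5) / 14.2) + math.exp(-(V + 89.0) / 11.6))

    I_Na = g_Na * m * m * m * h * (V - E_Na)
    I_K = g_K * n * n * n * n * (V - E_K)
    I_T = g_T * mT * mT * hT * (V - E_Ca)
    I_KL = g_KL * (V - E_KL)
    I_h = g_h * mh * (V - E_h) if is_tc else 0.0
    dV = (-g_L * (V - E_L) - I_Na - I_K - I_T - I_KL - I_h - I_ext) / C_m
    return (dV,
            a_m * (1.0 - m) - b_m * m,
            a_h * (1.0 - h) - b_h * h,
            a_n * (1.0 - n) - b_n * n,
            (mT_inf - mT) / tau_mT,
            (hT_inf - hT) / tau_hT,
            (mh_inf - mh) / tau_mh)


# numba compile-time constants for the online voltage histogram
HIST_LO_C = HIST_LO
HIST_BINS_C = HIST_BINS


@njit(cache=True)
def _step_loop(
    n_steps, seed, n_col, n_py, n_in, n_thal,
    # synapse structure (sorted by presynaptic cell)
    syn_post, syn_rec, syn_delay, syn_inc, pre_indptr,
    # mini structure (CSR by post cell)
    mini_indptr, mini_pre, mini_wrel, mini_abar, mini_wsum, p_mini, minis_on,
    mini_stride,
    # map parameters
    beta_x, alpha, w0, mu1, mu2, sigma, beta_y, gamma_down, gamma_up, delta,
    K1, K0, p_Nap, p_D, p_L, input_floor, k_printed,
    beta_x_in, alpha_in, y_star,
    # synapse parameters
    gamma_g, gamma_g_nmda, gamma_dep, gamma_rec, gamma_nmda_rec,
    V_AMPA_rev, V_GABA_rev, V_NMDA_rev,
    I_DC,
    # thalamic
    thal_on, thal_V, thal_m, thal_h, thal_n, thal_mT, thal_hT, thal_mh,
    thal_is_tc, thal_gKL, thal_scale, hh_substeps,
    # dynamic state (modified in place)
    x_py, y_py, u_py, k_py, x_in, x_in_prev,
    g_ampa, g_nmda, g_gaba, d_ampa, d_gaba, d_nmda, last_spike,
    ring, start_step,
    # recording
    active_l2_cells, layer2_of_col, is_active_py,
    mean_v_l2, mean_v_all, v_l2_rec, record_stride,
    parcel_of_cell, n_parcels, parcel_v, parcel_counts, record_parcels,
    py_hist, hist_on, hist_start,
    spike_counts, spike_buf, spike_buf_len,
):
    np.random.seed(seed)
    D = ring.shape[0]
    n_cells = g_ampa.shape[0]
    n_ctx = n_py + n_in
    n_spikes_stored = spike_buf_len
    spiked = np.zeros(n_cells, dtype=np.uint8)
    s_fac = np.zeros(n_py)
    lam_cache = np.zeros(n_ctx)
    n_act_l2 = len(active_l2_cells)

    for it in range(n_steps):
        n = start_step + it
        slot = n % D
        # --- conductances: decay + delayed deliveries arriving now
        for i in range(n_cells):
            g_ampa[i] = gamma_g * g_ampa[i] + ring[slot, i, 0]
            g_nmda[i] = gamma_g_nmda * g_nmda[i] + ring[slot, i, 1]
            g_gaba[i] = gamma_g * g_gaba[i] + ring[slot, i, 2]
            ring[slot, i, 0] = 0.0
            ring[slot, i, 1] = 0.0
            ring[slot, i, 2] = 0.0

        # --- miniature PSPs on intracortical AMPA synapses.  The activity
        # modulation factor varies on a ~175 ms timescale; the per-neuron
        # rate is refreshed every mini_stride steps.
        if minis_on:
            if it % mini_stride == 0:
                for j in range(n_py):
                    dn = float(n - last_spike[j]) - 350.0
                    s_fac[j] = 0.2 + 0.8 / (1.0 + math.exp(-0.1 * dn))
                for i in range(n_ctx):
                    lo, hi = mini_indptr[i], mini_indptr[i + 1]
                    if lo == hi:
                        lam_cache[i] = 2.0  # sentinel: no mini synapses
                        continue
                    lam = 0.0
                    for t in range(lo, hi):
                        lam += mini_wrel[t] * s_fac[mini_pre[t]]
                    # cache exp(-lambda): the Poisson sampler below needs it
                    lam_cache[i] = math.exp(-lam * p_mini) if lam > 0.0 else 2.0
            for i in range(n_ctx):
                L = lam_cache[i]
                if L <= 1.0:
                    # Knuth Poisson sampler; the common zero-event case
                    # costs a single uniform draw against the cached
                    # exp(-lambda) threshold
                    cnt = 0
                    prod = np.random.random()
                    while prod > L:
                        cnt += 1
                        prod *= np.random.random()
                    if cnt > 0:
                        g_ampa[i] += cnt * mini_abar[i]

        # --- PY updates
        sum_l2 = 0.0
        sum_all = 0.0
        cnt_all = 0
        rec_now = (it % record_stride) == 0
        for c in range(n_py):
            x = x_py[c]
            V = 50.0 * x - 15.0
            I_syn = g_ampa[c] * (V_AMPA_rev - V) + g_gaba[c] * (V_GABA_rev - V)
            if g_nmda[c] > 0.0:
                phi = 1.0 / (1.0 + math.exp(-(V + 25.0) / 12.5))
                I_syn += g_nmda[c] * phi * (V_NMDA_rev - V)
            I_Nap = p_Nap / (1.0 + math.exp(-20.0 * (x + 0.99)))
            I_D = -p_D * u_py[c] * (x + 1.2)
            I_leak = -p_L * (x - (sigma * p_L - 1.0))
            I_total = I_DC[c] + I_syn + I_Nap + I_D + I_leak

            bxI = beta_x * I_total
            if bxI < input_floor:
                bxI = input_floor
            w = y_py[c] + bxI
            if x >= 1.0:
                x_new = -1.0
            elif x >= -0.5:
                x_new = 1.0
            else:
                if w < w0:
                    x_new = alpha / (1.0 - x) + w
                else:
                    x_new = alpha / (1.0 - x) + w0 + (w - w0) * k_py[c]
                if x_new > -0.4:
                    x_new = -0.4
            y_py[c] = y_py[c] - mu1 * (x + 1.0) + mu2 * (sigma * p_L + beta_y * I_total)
            gam = gamma_down if x < -1.0 else gamma_up
            dlt = delta if (-0.5 < x < 1.0) else 0.0
            u_py[c] = gam * (u_py[c] + dlt)
            if k_printed:
                if x > -0.5:
                    k_py[c] = K1
                elif x < -1.0:
                    k_py[c] = K0
            else:
                if x > -0.5:
                    k_py[c] = K0
                elif x < -1.0:
                    k_py[c] = K1
            x_py[c] = x_new
            spiked[c] = 1 if x_new > 0.302 else 0
            if not math.isfinite(x_new):
                return -(n + 1), c, n_spikes_stored  # blow-up: step and cell id
            if is_active_py[c]:
                sum_all += 50.0 * x_new - 15.0
                cnt_all += 1
            if hist_on and rec_now and n >= hist_start:
                b = int(50.0 * x_new - 15.0 - HIST_LO_C)
                if 0 <= b < HIST_BINS_C:
                    py_hist[b] += 1

        # --- IN updates
        for idx in range(n_in):
            c = n_py + idx
            x = x_in[idx]
            V = 50.0 * x - 15.0
            I_syn = g_ampa[c] * (V_AMPA_rev - V) + g_gaba[c] * (V_GABA_rev - V)
            if g_nmda[c] > 0.0:
                phi = 1.0 / (1.0 + math.exp(-(V + 25.0) / 12.5))
                I_syn += g_nmda[c] * phi * (V_NMDA_rev - V)
            I_syn += I_DC[c]
            pz = beta_x_in * I_syn
            if pz < -1.0:
                pz = -1.0
            elif pz > 1.0:
                pz = 1.0
            w = y_star + pz
            if x <= 0.0:
                x_new = alpha_in / (1.0 - x) + w
            elif x <= alpha_in + w and x_in_prev[idx] <= 0.0:
                x_new = alpha_in + w
            else:
                x_new = -1.0
            sp = 1 if (0.0 < x <= alpha_in + w and x_in_prev[idx] <= 0.0) else 0
            spiked[c] = sp
            x_in_prev[idx] = x
            x_in[idx] = x_new
            if not math.isfinite(x_new):
                return -(n + 1), c, n_spikes_stored

        # --- thalamic HH updates
        if thal_on:
            dt_hh = 0.5 / hh_substeps
            for t in range(4 * n_thal):
                c = n_ctx + t
                V = thal_V[t]
                # synaptic drive held constant across the map step
                I_ext = thal_scale * (
                    g_ampa[c] * (V - V_AMPA_rev) + g_gaba[c] * (V - V_GABA_rev)
                ) - I_DC[c]
                is_tc = thal_is_tc[t] == 1
                if is_tc:
                    C_m, g_L, E_L = 1.0, 0.01, -70.0
                    g_Na, g_K, g_T = 90.0, 10.0, 2.2
                    g_h = 0.017
                else:
                    C_m, g_L, E_L = 1.0, 0.05, -77.0
                    g_Na, g_K, g_T = 100.0, 10.0, 2.3
                    g_h = 0.0
                Vv, mm, hh_, nn, mT, hT, mh = (
                    thal_V[t], thal_m[t], thal_h[t], thal_n[t], thal_mT[t], thal_hT[t], thal_mh[t]
                )
                ok = True
                for _ in range(hh_substeps):
                    k1 = _hh_deriv(Vv, mm, hh_, nn, mT, hT, mh, I_ext, is_tc,
                                   C_m, g_L, E_L, g_Na, 50.0, g_K, -95.0, g_T, 120.0,
                                   thal_gKL[t], -95.0, g_h, -43.0, -50.0)
                    k2 = _hh_deriv(Vv + 0.5 * dt_hh * k1[0], mm + 0.5 * dt_hh * k1[1],
                                   hh_ + 0.5 * dt_hh * k1[2], nn + 0.5 * dt_hh * k1[3],
                                   mT + 0.5 * dt_hh * k1[4], hT + 0.5 * dt_hh * k1[5],
                                   mh + 0.5 * dt_hh * k1[6], I_ext, is_tc,
                                   C_m, g_L, E_L, g_Na, 50.0, g_K, -95.0, g_T, 120.0,
                                   thal_gKL[t], -95.0, g_h, -43.0, -50.0)
                    k3 = _hh_deriv(Vv + 0.5 * dt_hh * k2[0], mm + 0.5 * dt_hh * k2[1],
                                   hh_ + 0.5 * dt_hh * k2[2], nn + 0.5 * dt_hh * k2[3],
                                   mT + 0.5 * dt_hh * k2[4], hT + 0.5 * dt_hh * k2[5],
                                   mh + 0.5 * dt_hh * k2[6], I_ext, is_tc,
                                   C_m, g_L, E_L, g_Na, 50.0, g_K, -95.0, g_T, 120.0,
                                   thal_gKL[t], -95.0, g_h, -43.0, -50.0)
                    k4 = _hh_deriv(Vv + dt_hh * k3[0], mm + dt_hh * k3[1],
                                   hh_ + dt_hh * k3[2], nn + dt_hh * k3[3],
                                   mT + dt_hh * k3[4], hT + dt_hh * k3[5],
                                   mh + dt_hh * k3[6], I_ext, is_tc,
                                   C_m, g_L, E_L, g_Na, 50.0, g_K, -95.0, g_T, 120.0,
                                   thal_gKL[t], -95.0, g_h, -43.0, -50.0)
                    Vv = Vv + (dt_hh / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                    mm = mm + (dt_hh / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                    hh_ = hh_ + (dt_hh / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                    nn = nn + (dt_hh / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
                    mT = mT + (dt_hh / 6.0) * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
                    hT = hT + (dt_hh / 6.0) * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
                    mh = mh + (dt_hh / 6.0) * (k1[6] + 2 * k2[6] + 2 * k3[6] + k4[6])
                    if abs(Vv) > 200.0:
                        return -(n + 1), c, n_spikes_stored
                # spike: upward crossing of 0 mV
                spiked[c] = 1 if (Vv > 0.0 and thal_V[t] <= 0.0) else 0
                thal_V[t], thal_m[t], thal_h[t], thal_n[t] = Vv, mm, hh_, nn
                thal_mT[t], thal_hT[t], thal_mh[t] = mT, hT, mh

        # --- spike delivery + depression bookkeeping
        for j in range(n_cells):
            if spiked[j] == 1:
                for s in range(pre_indptr[j], pre_indptr[j + 1]):
                    r = syn_rec[s]
                    if r == 0:
                        dd = d_ampa[j]
                    elif r == 1:
                        dd = d_nmda[j]
                    else:
                        dd = d_gaba[j]
                    ring[(n + syn_delay[s]) % D, syn_post[s], r] += syn_inc[s] * dd
                d_ampa[j] = gamma_dep * d_ampa[j]
                d_gaba[j] = gamma_dep * d_gaba[j]
                last_spike[j] = n
                spike_counts[j] += 1
                if n_spikes_stored < spike_buf.shape[0]:
                    spike_buf[n_spikes_stored, 0] = j
                    spike_buf[n_spikes_stored, 1] = n
                    n_spikes_stored += 1
            else:
                d_ampa[j] = d_ampa[j] + gamma_rec * (1.0 - d_ampa[j])
                d_gaba[j] = d_gaba[j] + gamma_rec * (1.0 - d_gaba[j])
                d_nmda[j] = 1.0 - (1.0 - gamma_nmda_rec) * (1.0 - d_nmda[j])

        # --- recording
        s2 = 0.0
        for a in range(n_act_l2):
            s2 += 50.0 * x_py[active_l2_cells[a]] - 15.0
        mean_v_l2[it] = s2 / n_act_l2
        mean_v_all[it] = sum_all / cnt_all if cnt_all > 0 else 0.0
        if rec_now:
            r = it // record_stride
            if r < v_l2_rec.shape[0]:
                for a in range(n_act_l2):
                    v_l2_rec[r, a] = 50.0 * x_py[active_l2_cells[a]] - 15.0
        if record_parcels:
            for pp in range(n_parcels):
                parcel_v[it, pp] = 0.0
            for c in range(n_ctx):
                pp = parcel_of_cell[c]
                if pp >= 0:
                    if c < n_py:
                        parcel_v[it, pp] += 50.0 * x_py[c] - 15.0
                    else:
                        parcel_v[it, pp] += 50.0 * x_in[c - n_py] - 15.0
            for pp in range(n_parcels):
                parcel_v[it, pp] /= parcel_counts[pp]

    return n_steps, -1, n_spikes_stored


def _rest_state(mp: MapParams) -> tuple[float, float, float, float, float]:
    """(x_py, y_py, u_py, k_py, x_in) quiescent initial values."""
    from .neurons import in_rest_state, py_rest_state

    x, y, u, k = py_rest_state(mp)
    xi = in_rest_state(mp)
    return x, y, u, k, xi


def run(
    conn: Connectome,
    mesh: HemisphereMesh,
    cfg: RunConfig,
    map_params: MapParams | None = None,
    syn_params: SynapseParams | None = None,
    I_DC: np.ndarray | float | None = None,
    initial: dict | None = None,
    keep_final_state: bool = False,
) -> SimulationRun:
    """Simulate the network for ``cfg.duration_s`` seconds.

    The wake/sleep overlay named by ``cfg.state`` is applied on top of the
    baseline parameters.  ``I_DC`` may be a scalar or a per-cell array
    (default: no injected current anywhere).  Passing ``initial`` (the
    ``final_state`` of a previous run) continues that run, which is how
    mid-run wake/sleep switching is composed.
    """
    mp0 = map_params or MapParams()
    sy0 = syn_params or SynapseParams(dt_ms=cfg.dt_ms)
    mp, sy, thal_ov = set_brain_state(mp0, sy0, cfg.state)

    n_col = conn.n_columns
    n_py, n_in, n_thal = conn.n_py, 6 * n_col, conn.n_thalamic
    n_ctx = conn.n_cortical
    n_cells = conn.n_cells
    n_steps = int(round(cfg.duration_s * 1000.0 / cfg.dt_ms))

    # synapse structure sorted by presynaptic cell
    order, pre_indptr = _pre_csr(conn)
    syn_post = conn.post[order].astype(np.int32)
    syn_rec = conn.receptor[order].astype(np.int8)
    syn_delay = conn.delay_steps[order].astype(np.int32)
    syn_inc = _synapse_increments(conn, sy, cfg)[order]
    mini_indptr, mini_pre, mini_wrel, mini_abar, mini_wsum = _mini_csr(conn, sy, cfg)

    D = int(conn.delay_steps.max(initial=1)) + 1
    thal_on = cfg.thalamus_on and n_thal > 0

    # dynamic state
    if initial is None:
        x0, y0, u0, k0, xi0 = _rest_state(mp)
        x_py = np.full(n_py, x0)
        y_py = np.full(n_py, y0)
        u_py = np.full(n_py, u0)
        k_py = np.full(n_py, k0)
        x_in = np.full(n_in, xi0)
        x_in_prev = x_in.copy()
        g_ampa = np.zeros(n_cells)
        g_nmda = np.zeros(n_cells)
        g_gaba = np.zeros(n_cells)
        d_ampa = np.ones(n_cells)
        d_gaba = np.ones(n_cells)
        d_nmda = np.ones(n_cells)
        last_spike = np.full(n_cells, -(10**9), dtype=np.int64)
        ring = np.zeros((D, n_cells, 3))
        thal_V = np.full(4 * n_thal, -68.0)
        thal_m = np.full(4 * n_thal, 0.05)
        thal_h = np.full(4 * n_thal, 0.6)
        thal_n = np.full(4 * n_thal, 0.3)
        thal_mT = np.full(4 * n_thal, 0.01)
        thal_hT = np.full(4 * n_thal, 0.3)
        thal_mh = np.full(4 * n_thal, 0.1)
        start_step = 0
    else:
        st = initial
        x_py, y_py, u_py, k_py = st["x_py"], st["y_py"], st["u_py"], st["k_py"]
        x_in, x_in_prev = st["x_in"], st["x_in_prev"]
        g_ampa, g_nmda, g_gaba = st["g_ampa"], st["g_nmda"], st["g_gaba"]
        d_ampa, d_gaba, d_nmda = st["d_ampa"], st["d_gaba"], st["d_nmda"]
        last_spike, ring = st["last_spike"], st["ring"]
        thal_V, thal_m, thal_h = st["thal_V"], st["thal_m"], st["thal_h"]
        thal_n, thal_mT, thal_hT, thal_mh = st["thal_n"], st["thal_mT"], st["thal_hT"], st["thal_mh"]
        start_step = st["step"]
        if ring.shape[0] != D:  # pragma: no cover - delay table changed between segments
            raise ValueError("cannot continue a run across a change of delay structure")

    thal_is_tc = np.zeros(4 * n_thal, dtype=np.int8)
    thal_is_tc[: 2 * n_thal] = 1  # TC core, TC matrix, then RE core, RE matrix
    thal_gKL = np.where(thal_is_tc == 1, thal_ov["g_KL_TC"], thal_ov["g_KL_RE"]).astype(np.float64)

    if I_DC is None:
        idc = np.zeros(n_cells)
    elif np.isscalar(I_DC):
        idc = np.full(n_cells, float(I_DC))
    else:
        idc = np.asarray(I_DC, dtype=np.float64)

    # recording structure
    layer2_of_col = np.arange(n_col) * N_LAYERS  # PY L2 cell of each column
    active_cols = np.flatnonzero(mesh.active)
    active_l2_cells = (active_cols * N_LAYERS).astype(np.int64)
    is_active_py = np.zeros(n_py, dtype=np.uint8)
    for L in range(N_LAYERS):
        is_active_py[active_cols * N_LAYERS + L] = 1

    n_rec = (n_steps + cfg.record_stride - 1) // cfg.record_stride
    mean_v_l2 = np.zeros(n_steps)
    mean_v_all = np.zeros(n_steps)
    v_l2_rec = np.zeros((n_rec, len(active_cols)), dtype=np.float32)

    n_parcels = mesh.n_parcels if cfg.record_parcels else 0
    parcel_of_cell = np.full(n_ctx, -1, dtype=np.int64)
    if cfg.record_parcels:
        lab = mesh.parcel_label
        for L in range(N_LAYERS):
            parcel_of_cell[np.arange(n_col) * N_LAYERS + L] = lab
            parcel_of_cell[n_py + np.arange(n_col) * N_LAYERS + L] = lab
        parcel_counts = np.bincount(
            parcel_of_cell[parcel_of_cell >= 0], minlength=max(n_parcels, 1)
        ).astype(np.float64)
        parcel_v = np.zeros((n_steps, max(n_parcels, 1)), dtype=np.float64)
    else:
        parcel_counts = np.ones(1)
        parcel_v = np.zeros((1, 1))

    py_hist = np.zeros(HIST_BINS, dtype=np.int64)
    hist_start = start_step + int(round(cfg.hist_skip_s * 1000.0 / cfg.dt_ms))

    spike_counts = np.zeros(n_cells, dtype=np.int64)
    spike_buf = np.zeros((cfg.spike_buffer, 2), dtype=np.int64)

    rc = _step_loop(
        n_steps, int(cfg.seed) & 0x7FFFFFFF, n_col, n_py, n_in, n_thal,
        syn_post, syn_rec, syn_delay, syn_inc, pre_indptr,
        mini_indptr, mini_pre, mini_wrel, mini_abar, mini_wsum,
        sy.mini_prob_per_step, cfg.minis_on, cfg.mini_update_stride,
        mp.beta_x, mp.alpha, mp.w0, mp.mu1, mp.mu2, mp.sigma, mp.beta_y,
        mp.gamma_down, mp.gamma_up, mp.delta,
        mp.K1, mp.K0, mp.p_Nap, mp.p_D, mp.p_L, mp.input_floor, mp.k_printed_form,
        mp.beta_x_in, mp.alpha_in, mp.y_star,
        sy.gamma_g, sy.gamma_g_nmda, sy.gamma_d_dep, sy.gamma_d_rec, sy.gamma_d_nmda_rec,
        sy.V_AMPA, sy.V_GABA, sy.V_NMDA,
        idc,
        thal_on, thal_V, thal_m, thal_h, thal_n, thal_mT, thal_hT, thal_mh,
        thal_is_tc, thal_gKL, cfg.thal_syn_scale, cfg.hh_substeps,
        x_py, y_py, u_py, k_py, x_in, x_in_prev,
        g_ampa, g_nmda, g_gaba, d_ampa, d_gaba, d_nmda, last_spike,
        ring, start_step,
        active_l2_cells, layer2_of_col, is_active_py,
        mean_v_l2, mean_v_all, v_l2_rec, cfg.record_stride,
        parcel_of_cell, n_parcels, parcel_v, parcel_counts, cfg.record_parcels,
        py_hist, cfg.record_all_py_hist, hist_start,
        spike_counts, spike_buf, 0,
    )
    steps_done, bad_cell, n_sp = rc
    if steps_done < 0:
        raise FloatingPointError(
            f"simulation blew up at step {-steps_done - 1} in cell {bad_cell}"
        )

    final = None
    if keep_final_state:
        final = dict(
            x_py=x_py, y_py=y_py, u_py=u_py, k_py=k_py,
            x_in=x_in, x_in_prev=x_in_prev,
            g_ampa=g_ampa, g_nmda=g_nmda, g_gaba=g_gaba,
            d_ampa=d_ampa, d_gaba=d_gaba, d_nmda=d_nmda,
            last_spike=last_spike, ring=ring,
            thal_V=thal_V, thal_m=thal_m, thal_h=thal_h, thal_n=thal_n,
            thal_mT=thal_mT, thal_hT=thal_hT, thal_mh=thal_mh,
            step=start_step + n_steps,
        )

    manifest = dict(
        seed=int(cfg.seed),
        state=cfg.state,
        duration_s=float(cfg.duration_s),
        dt_ms=float(cfg.dt_ms),
        syn_gain=float(cfg.syn_gain),
        minis_on=bool(cfg.minis_on),
        thalamus_on=bool(thal_on),
        n_columns=int(n_col),
        n_synapses=int(conn.n_synapses),
        start_step=int(start_step),
    )
    return SimulationRun(
        dt_ms=cfg.dt_ms,
        n_steps=n_steps,
        state=cfg.state,
        mean_v_l2=mean_v_l2,
        mean_v_all=mean_v_all,
        v_l2=v_l2_rec,
        record_stride=cfg.record_stride,
        active_columns=active_cols,
        spike_counts=spike_counts,
        spikes=spike_buf[:n_sp].copy(),
        spikes_truncated=bool(n_sp >= cfg.spike_buffer),
        parcel_v=parcel_v if cfg.record_parcels else None,
        py_hist=py_hist if cfg.record_all_py_hist else None,
        final_state=final,
        manifest=manifest,
    )


def record_lfp(
    run_: SimulationRun,
    mesh: HemisphereMesh,
    scope: str = "global",
    center: int | None = None,
    radius_mm: float | None = None,
    smooth_ms: float = 20.0,
) -> np.ndarray:
    """Local field potential: mean layer-2 PY voltage scaled by 20.

    ``scope='global'`` averages all active columns.  ``scope='region'``
    averages columns within ``radius_mm`` (geodesic) of column ``center`` and
    additionally smooths with a 20 ms running mean.  The medial wall is
    always excluded.
    """
    if scope == "global":
        return 20.0 * run_.mean_v_l2
    if scope != "region":
        raise ValueError("scope must be 'global' or 'region'")
    if center is None or radius_mm is None:
        raise ValueError("regional LFP needs center and radius_mm")
    from .mesh import geodesic_distances

    d = geodesic_distances(mesh, np.array([center]))[0][run_.active_columns]
    cols = np.flatnonzero(d <= radius_mm)
    if cols.size == 0:
        raise ValueError("empty region: no active columns within radius")
    # stride-sampled per-column voltages, upsampled back by repetition
    trace = run_.v_l2[:, cols].mean(axis=1).astype(np.float64)
    trace = np.repeat(trace, run_.record_stride)[: run_.n_steps] * 20.0
    win = max(1, int(round(smooth_ms / run_.dt_ms)))
    kernel = np.ones(win) / win
    return np.convolve(trace, kernel, mode="same")


def firing_rates(run_: SimulationRun, conn: Connectome, population: str = "PY") -> np.ndarray:
    """Per-cell firing rate in Hz over the whole run."""
    t = run_.duration_s
    if population == "PY":
        sl = slice(0, conn.n_py)
    elif population == "IN":
        sl = slice(conn.n_py, conn.n_cortical)
    elif population == "thal":
        sl = slice(conn.n_cortical, conn.n_cells)
    else:
        raise ValueError("population must be PY, IN or thal")
    return run_.spike_counts[sl] / t
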