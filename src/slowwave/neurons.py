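"""Single-cell dynamics: map-based cortical PY/IN neurons, dynamic synapses,
and Hodgkin-Huxley thalamic relay (TC) / reticular (RE) cells.

Cortical neurons are discrete-time maps advanced in 0.5 ms steps.  A PY cell
carries four variables: ``x`` (dimensionless voltage, membrane potential
``V = 50 x - 15`` mV), ``y`` (slow ion-channel dynamics), ``u`` (slow
hyperpolarizing current activation) and ``k`` (input sensitivity).  An IN
cell carries only ``x`` (plus the previous step's ``x`` for its two-step
spike condition).  A spike is flagged when ``V > 0.1`` mV, i.e.
``x > 0.302``.

The functions here are deliberately scalar and allocation-free: they are the
reference semantics.  The vectorized simulation engine must reproduce them
bit-exactly (asserted by the test suite), so any change here is a change of
model definition.

Interpretation note: in the leak current and in the slow-variable drive the
resting-potential term is ``sigma * p_L - 1``.  With the tabulated values
this puts the uncoupled resting potential near -70 mV awake and -82 mV
asleep, i.e. sleep hyperpolarizes the cortex, which is the physiological
direction of the wake-to-sleep leak increase.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

# voltage mapping V = 50 x - 15; spike iff V > V_THETA
V_THETA = 0.1
X_SPIKE = (V_THETA + 15.0) / 50.0  # = 0.302
INPUT_FLOOR = 1e-4


def x_to_v(x):
    """Map the dimensionless voltage variable to membrane potential in mV."""
    return 50.0 * np.asarray(x) - 15.0


def v_to_x(v):
    return (np.asarray(v) + 15.0) / 50.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MapParams:
    """Map-neuron parameters (sleep-state cortical defaults).

    ``gamma_down``/``gamma_up`` are the two admissible adaptation rates
    (0.99 below x = -1, 0.995 otherwise); ``delta`` acts only while
    -0.5 < x < 1, i.e. once per emitted spike.
    """

    # PY
    beta_x: float = 0.133
    alpha: float = 3.65
    w0: float = -2.819
    mu1: float = 0.0008
    mu2: float = 0.002
    sigma: float = -0.4
    beta_y: float = 1.0
    gamma_down: float = 0.99
    gamma_up: float = 0.995
    delta: float = 0.24
    K1: float = 0.25
    K0: float = 0.0025
    p_Nap: float = 0.15
    p_D: float = 4.0
    p_L: float = 0.5
    input_floor: float = INPUT_FLOOR
    #: orientation of the sensitivity switch.  True (default): high
    #: sensitivity (K1) while the cell is in the Up state, low sensitivity
    #: (K0) restored once it leaves (x < -1), which supports sustained firing
    #: during Up states and a stable Down state.  False uses the opposite
    #: orientation, under which a cell that has entered an Up state can no
    #: longer reach the firing branch (spike-branch gain K0) until it is
    #: hyperpolarized below x = -1 — the network then freezes in a
    #: depolarized silent state.
    k_printed_form: bool = True
    # IN
    beta_x_in: float = 0.05
    alpha_in: float = 3.8
    y_star: float = -2.93

    def __post_init__(self):
        if not (self.K1 > self.K0 > 0):
            raise ValueError("requires K1 > K0 > 0")
        for name in ("mu1", "mu2", "gamma_down", "gamma_up"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclasses.dataclass
class SynapseParams:
    """Dynamic-synapse constants (per receptor; post-synaptic type in names)."""

    gamma_g: float = 0.995            # AMPA/GABA_A conductance decay per step
    gamma_g_nmda: float = 0.995
    G_AMPA_syn_py: float = 7.3e-5     # PY->PY (sleep)
    G_AMPA_syn_in: float = 2.3e-4     # PY->IN (sleep)
    G_GABA_syn_py: float = 5e-5       # IN->PY (sleep)
    G_NMDA_syn_py: float = 6.7e-10
    G_AMPA_mini: float = 1.6e-6
    G_GABA_mini: float = 0.0
    mu_bar: float = 500.0             # maximal mini frequency (events/s)
    mini_rate_scale: float = 1.0      # free scale on the per-synapse mini rate
    gamma_d_dep: float = 0.05         # depression multiplier on a presynaptic spike
    gamma_d_rec: float = 0.005        # AMPA/GABA recovery rate
    gamma_d_nmda_rec: float = 5e-5    # NMDA recovery rate
    V_AMPA: float = 0.0
    V_GABA: float = -70.0
    V_NMDA: float = 0.0
    dt_ms: float = 0.5

    @property
    def mini_prob_per_step(self) -> float:
        """Maximal per-synapse mini probability per 0.5 ms step."""
        return self.mu_bar * self.mini_rate_scale * self.dt_ms * 1e-3


#: wake/sleep parameter overlays: the wake-to-sleep transition increases the
#: cortical leak and slow hyperpolarizing currents and strengthens AMPA/GABA,
#: and retunes the thalamic potassium leak.
BRAIN_STATES = {
    "wake": {
        "p_L": 0.15,
        "p_D": 1.6,
        "G_AMPA_syn_py": 2e-5,
        "G_AMPA_syn_in": 6.3e-5,
        "G_GABA_syn_py": 3e-5,
        "g_KL_TC": 0.007,
        "g_KL_RE": 0.022,
    },
    "sleep": {
        "p_L": 0.5,
        "p_D": 4.0,
        "G_AMPA_syn_py": 7.3e-5,
        "G_AMPA_syn_in": 2.3e-4,
        "G_GABA_syn_py": 5e-5,
        "g_KL_TC": 0.012,
        "g_KL_RE": 0.015,
    },
}


# ---------------------------------------------------------------------------
# PY map
# ---------------------------------------------------------------------------

def f_py(x: float, w: float, k: float, p: MapParams) -> float:
    """Spike-generating nonlinearity of the PY map (three-branch form).

    The sub-threshold branches are capped at the plateau entry value -0.4:
    under very strong drive the sensitivity branch would otherwise overshoot
    to arbitrarily large voltages in a single step, skipping the spike
    upstroke (and with it the per-spike adaptation increment).  The cap is
    inactive in all physiological regimes, where the branch lands well below
    the plateau.
    """
    if x >= 1.0:
        return -1.0
    if x >= -0.5:
        return 1.0
    if w < p.w0:
        xn = p.alpha / (1.0 - x) + w
    else:
        xn = p.alpha / (1.0 - x) + p.w0 + (w - p.w0) * k
    return xn if xn < -0.4 else -0.4


def total_current(x: float, u: float, I_syn: float, I_DC: float, p: MapParams) -> float:
    """Total input current: DC + synaptic + persistent Na+ + slow K+ + leak."""
    I_Nap = p.p_Nap / (1.0 + math.exp(-20.0 * (x + 0.99)))
    I_D = -p.p_D * u * (x + 1.2)
    I_leak = -p.p_L * (x - (p.sigma * p.p_L - 1.0))
    return I_DC + I_syn + I_Nap + I_D + I_leak


def py_step(
    x: float, y: float, u: float, k: float, I_total: float, p: MapParams
) -> tuple[float, float, float, float]:
    """One 0.5 ms update of a PY cell.  Returns (x', y', u', k')."""
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(u)):
        raise FloatingPointError("non-finite PY state")
    bxI = p.beta_x * I_total
    # lower bound: keeps the fast-map input term positive.  Hyperpolarizing
    # currents act through the slow variable y, whose drive is not clamped;
    # an unbounded negative fast input would destabilize the map.
    if bxI < p.input_floor:
        bxI = p.input_floor
    w = y + bxI
    x_new = f_py(x, w, k, p)
    y_new = y - p.mu1 * (x + 1.0) + p.mu2 * (p.sigma * p.p_L + p.beta_y * I_total)
    gamma = p.gamma_down if x < -1.0 else p.gamma_up
    delta = p.delta if (-0.5 < x < 1.0) else 0.0
    u_new = gamma * (u + delta)
    if p.k_printed_form:
        k_hi_thresh, k_lo = p.K1, p.K0
    else:
        k_hi_thresh, k_lo = p.K0, p.K1
    k_new = k
    if x > -0.5:
        k_new = k_hi_thresh     # entered the Up state
    elif x < -1.0:
        k_new = k_lo            # left the Up state
    return x_new, y_new, u_new, k_new


def py_rest_state(p: MapParams, n_iter: int = 20000) -> tuple[float, float, float, float]:
    """Quiescent fixed point of the PY map with zero synaptic input."""
    x, y, u, k = -1.3, -2.9, 0.0, p.K1 if not p.k_printed_form else p.K0
    for _ in range(n_iter):
        I = total_current(x, u, 0.0, 0.0, p)
        x, y, u, k = py_step(x, y, u, k, I, p)
    return x, y, u, k


# ---------------------------------------------------------------------------
# IN map
# ---------------------------------------------------------------------------

def psi(w: float) -> float:
    """Input clipping of the IN map."""
    return -1.0 if w < -1.0 else (1.0 if w > 1.0 else w)


def in_step(x: float, x_prev: float, I_syn: float, p: MapParams) -> tuple[float, bool]:
    """One update of an IN cell.  Returns (x', spiked).

    The IN spike condition is two-step: a spike is flagged when x has just
    crossed above 0 (previous x <= 0) and remains below its peak value
    ``alpha + w``.
    """
    if not math.isfinite(x):
        raise FloatingPointError("non-finite IN state")
    w = p.y_star + psi(p.beta_x_in * I_syn)
    if x <= 0.0:
        x_new = p.alpha_in / (1.0 - x) + w
    elif x <= p.alpha_in + w and x_prev <= 0.0:
        x_new = p.alpha_in + w
    else:
        x_new = -1.0
    spiked = (0.0 < x <= p.alpha_in + w) and x_prev <= 0.0
    return x_new, spiked


def in_rest_state(p: MapParams, n_iter: int = 20000) -> float:
    x, x_prev = -1.0, -1.0
    for _ in range(n_iter):
        x_new, _ = in_step(x, x_prev, 0.0, p)
        x_prev, x = x, x_new
    return x


# ---------------------------------------------------------------------------
# dynamic synapses (reference semantics)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SynapseDynState:
    g: float = 0.0      # conductance
    d: float = 1.0      # depression in (0, 1]
    n0: int = -10**9    # step of most recent presynaptic spike


def mini_rate_factor(n: int, n0: int) -> float:
    """Activity-dependent modulation of the mini rate.

    Drops to 20% of maximum right after a presynaptic spike and sigmoidally
    recovers (midpoint 350 steps = 175 ms after the spike).
    """
    return 0.2 + 0.8 / (1.0 + math.exp(-0.1 * (n - n0 - 350.0)))


def synapse_step(
    syn: SynapseDynState,
    presyn_spiked: bool,
    receptor: str,
    params: SynapseParams,
    rng: np.random.Generator | None = None,
    n: int = 0,
    G_syn: float | None = None,
    weight: float = 1.0,
) -> SynapseDynState:
    """One update of a single dynamic synapse (first-order activation scheme).

    ``weight`` is the normalized synaptic weight (weight factor divided by
    the per-neuron sum of incoming factors).  Minis exist on AMPA synapses
    only (the GABA mini strength is zero).
    """
    if receptor not in ("AMPA", "NMDA", "GABA_A"):
        raise ValueError(f"unknown receptor {receptor!r}")
    is_nmda = receptor == "NMDA"
    gamma_g = params.gamma_g_nmda if is_nmda else params.gamma_g
    if G_syn is None:
        G_syn = {
            "AMPA": params.G_AMPA_syn_py,
            "NMDA": params.G_NMDA_syn_py,
            "GABA_A": params.G_GABA_syn_py,
        }[receptor]
    g = gamma_g * syn.g
    if presyn_spiked:
        g += syn.d * G_syn * weight
    G_mini = params.G_AMPA_mini if receptor == "AMPA" else params.G_GABA_mini
    if G_mini > 0.0 and rng is not None:
        p_mini = params.mini_prob_per_step * mini_rate_factor(n, syn.n0)
        if rng.random() < p_mini:
            g += G_mini * weight
    if is_nmda:
        d = syn.d if presyn_spiked else 1.0 - (1.0 - params.gamma_d_nmda_rec) * (1.0 - syn.d)
    else:
        # recovery mirrors the NMDA scheme: the deficit (1 - d) relaxes with
        # rate gamma_d_rec per step (time constant ~100 ms)
        d = params.gamma_d_dep * syn.d if presyn_spiked else syn.d + params.gamma_d_rec * (1.0 - syn.d)
    n0 = n if presyn_spiked else syn.n0
    return SynapseDynState(g=g, d=d, n0=n0)


def nmda_gate(V: float) -> float:
    """Voltage dependence of the NMDA conductance (half-open at -25 mV)."""
    return 1.0 / (1.0 + math.exp(-(V + 25.0) / 12.5))


def synaptic_current(g: float, V_post: float, receptor: str, params: SynapseParams | None = None) -> float:
    """Instantaneous synaptic current ``g (V_rev - V)``; NMDA is additionally
    gated by its voltage-dependent magnesium-block factor."""
    p = params or SynapseParams()
    if receptor == "AMPA":
        return g * (p.V_AMPA - V_post)
    if receptor == "GABA_A":
        return g * (p.V_GABA - V_post)
    if receptor == "NMDA":
        return g * nmda_gate(V_post) * (p.V_NMDA - V_post)
    raise ValueError(f"unknown receptor {receptor!r}")


# ---------------------------------------------------------------------------
# Hodgkin-Huxley thalamic cells
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ThalamicParams:
    """Single-compartment TC/RE parameters (conductances mS/cm2, potentials mV).

    Intrinsic currents follow the standard published relay/reticular
    formulations: fast Na+/K+ spike currents, low-threshold Ca2+ current
    (I_T, the rebound-burst generator), K+ leak, and for TC cells the
    hyperpolarization-activated cation current I_h.
    """

    cell_type: str = "TC"        # "TC" or "RE"
    C_m: float = 1.0             # uF/cm2
    g_L: float = 0.01
    E_L: float = -70.0
    area_cm2: float = 1.43e-4
    g_Na: float = 90.0
    E_Na: float = 50.0
    g_K: float = 10.0
    E_K: float = -95.0
    g_T: float = 2.2
    E_Ca: float = 120.0
    g_KL: float = 0.012
    E_KL: float = -95.0
    g_h: float = 0.017
    E_h: float = -43.0
    V_traub: float = -50.0       # spike-kinetics voltage shift

    @classmethod
    def tc(cls, g_KL: float = 0.012) -> "ThalamicParams":
        return cls(cell_type="TC", g_KL=g_KL)

    @classmethod
    def re(cls, g_KL: float = 0.015) -> "ThalamicParams":
        return cls(
            cell_type="RE",
            g_L=0.05,
            E_L=-77.0,
            area_cm2=2.9e-4,
            g_Na=100.0,
            g_K=10.0,
            g_T=2.3,
            g_KL=g_KL,
            g_h=0.0,
        )

    def __post_init__(self):
        if self.area_cm2 <= 0:
            raise ValueError("cell area must be positive")
        for name in ("g_L", "g_Na", "g_K", "g_T", "g_KL", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class ThalamicState:
    V: float
    m: float = 0.05
    h: float = 0.6
    n: float = 0.3
    mT: float = 0.0
    hT: float = 0.3
    mh: float = 0.1   # I_h activation (TC only)


def _exprel(x: float) -> float:
    """x / (exp(x) - 1), stable near zero."""
    if abs(x) < 1e-7:
        return 1.0 - x / 2.0
    return x / (math.exp(x) - 1.0)


def _thalamic_rates(V: float, p: ThalamicParams):
    # clamp the voltage entering the rate functions: intermediate Runge-
    # Kutta stages can overshoot during a spike, and the exponentials must
    # not overflow before the per-step divergence check fires
    V = min(max(V, -200.0), 200.0)
    v2 = V - p.V_traub
    a_m = 0.32 * 4.0 * _exprel((13.0 - v2) / 4.0)
    b_m = 0.28 * 5.0 * _exprel((v2 - 40.0) / 5.0)
    a_h = 0.128 * math.exp((17.0 - v2) / 18.0)
    b_h = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    a_n = 0.032 * 5.0 * _exprel((15.0 - v2) / 5.0)
    b_n = 0.5 * math.exp((10.0 - v2) / 40.0)
    if p.cell_type == "TC":
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
    return a_m, b_m, a_h, b_h, a_n, b_n, mT_inf, tau_mT, hT_inf, tau_hT, mh_inf, tau_mh


def _thalamic_deriv(s: ThalamicState, I_syn_density: float, p: ThalamicParams):
    (a_m, b_m, a_h, b_h, a_n, b_n,
     mT_inf, tau_mT, hT_inf, tau_hT, mh_inf, tau_mh) = _thalamic_rates(s.V, p)
    I_Na = p.g_Na * s.m**3 * s.h * (s.V - p.E_Na)
    I_K = p.g_K * s.n**4 * (s.V - p.E_K)
    I_T = p.g_T * s.mT**2 * s.hT * (s.V - p.E_Ca)
    I_KL = p.g_KL * (s.V - p.E_KL)
    I_h = p.g_h * s.mh * (s.V - p.E_h) if p.cell_type == "TC" else 0.0
    dV = (-p.g_L * (s.V - p.E_L) - I_Na - I_K - I_T - I_KL - I_h - I_syn_density) / p.C_m
    return (
        dV,
        a_m * (1.0 - s.m) - b_m * s.m,
        a_h * (1.0 - s.h) - b_h * s.h,
        a_n * (1.0 - s.n) - b_n * s.n,
        (mT_inf - s.mT) / tau_mT,
        (hT_inf - s.hT) / tau_hT,
        (mh_inf - s.mh) / tau_mh,
    )


def hh_step(
    state: ThalamicState,
    I_syn_density: float,
    params: ThalamicParams,
    dt_hh: float = 0.02,
    n_sub: int | None = None,
) -> ThalamicState:
    """Advance a thalamic cell by one 0.5 ms map step using RK4 sub-stepping.

    ``I_syn_density`` is the synaptic (plus injected) current density in
    uA/cm2, held constant over the map step.
    """
    if n_sub is None:
        n_sub = max(1, int(round(0.5 / dt_hh)))
    dt = 0.5 / n_sub
    s = state
    vals = np.array([s.V, s.m, s.h, s.n, s.mT, s.hT, s.mh])
    for _ in range(n_sub):
        def deriv(v):
            st = ThalamicState(*v)
            return np.array(_thalamic_deriv(st, I_syn_density, params))
        k1 = deriv(vals)
        k2 = deriv(vals + 0.5 * dt * k1)
        k3 = deriv(vals + 0.5 * dt * k2)
        k4 = deriv(vals + dt * k3)
        vals = vals + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if abs(vals[0]) > 200.0:
            raise FloatingPointError("thalamic membrane potential blew up (|V| > 200 mV)")
    return ThalamicState(*vals)


def thalamic_rest(params: ThalamicParams, t_ms: float = 500.0) -> ThalamicState:
    s = ThalamicState(V=-68.0)
    for _ in range(int(t_ms / 0.5)):
        s = hh_step(s, 0.0, params, n_sub=25)
    return s
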