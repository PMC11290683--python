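"""Synapse-table generation for the hemisphere network.

The network contains, per cortical column, one excitatory (PY) and one
inhibitory (IN) cell in each of six layers (L2, L3, L4, L5a, L5b, L6), plus
four thalamic populations (core/matrix x relay/reticular) on a coarser
aligned sphere.  Wiring combines:

* the canonical within-column circuit (directed layer-to-layer edges),
* long-range PY->PY projections drawn per ordered column pair with
  probability ``beta * exp(-fiber / lambda)``, where fiber length is a
  rational-function map of geodesic distance,
* strictly local, same-layer IN->PY inhibition (own column plus first- and
  second-order mesh neighbors),
* thalamocortical fanouts with population-specific radii.

Every synapse carries a relative ``weight_factor``.  The tabulated synaptic
conductances are per-synapse quantities; the effective weight additionally
carries the ratio of the intact to the current per-neuron, per-receptor
incoming-factor sum.  In the intact model that ratio is one; ablation
experiments (density, radius) zero weight factors and recompute the current
sum, so the surviving synapses are compensatorily strengthened and every
neuron's total synaptic budget returns exactly to its intact value.
Strength-scaling experiments deliberately bypass the compensation.

Cell index layout (``n`` columns, ``m`` thalamic cells per population)::

    PY:        col * 6 + layer                  [0, 6n)
    IN:        6n + col * 6 + layer             [6n, 12n)
    TC core:   12n + [0, m)
    TC matrix: 12n + m + [0, m)
    RE core:   12n + 2m + [0, m)
    RE matrix: 12n + 3m + [0, m)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import trimesh

from .mesh import HemisphereMesh, geodesic_distances, neighbor_rings

logger = logging.getLogger(__name__)

LAYERS = ("L2", "L3", "L4", "L5a", "L5b", "L6")
N_LAYERS = 6

# receptors
AMPA, NMDA, GABA_A = 0, 1, 2
RECEPTOR_NAMES = ("AMPA", "NMDA", "GABA_A")

# connection classes
WITHIN_COLUMN = 0
WITHIN_PARCEL = 1
WEAK_FF = 2
STRONG_FF = 3
WEAK_FB = 4
STRONG_FB = 5
LOCAL_INH = 6
THALAMOCORTICAL = 7
CORTICOTHALAMIC = 8
INTRATHALAMIC = 9
CLASS_NAMES = (
    "within_column",
    "within_parcel",
    "weak_ff",
    "strong_ff",
    "weak_fb",
    "strong_fb",
    "local_inh",
    "thalamocortical",
    "corticothalamic",
    "intrathalamic",
)
CORTICAL_EXC_CLASSES = (WITHIN_COLUMN, WITHIN_PARCEL, WEAK_FF, STRONG_FF, WEAK_FB, STRONG_FB)

#: canonical within-column circuit: directed PY->PY layer pairs.  The
#: granular layer relays upward (L4 -> L2/3), the supragranular pair is
#: recurrently coupled and projects to the infragranular layers, which are
#: recurrently coupled in turn and close the loop through L6.  L4 receives
#: within-column excitation from L6 only.
DEFAULT_INTRACOLUMN_ADJACENCY = (
    ("L4", "L3"),
    ("L4", "L2"),
    ("L3", "L2"),
    ("L2", "L3"),
    ("L2", "L5a"),
    ("L3", "L5b"),
    ("L5a", "L5b"),
    ("L5b", "L5a"),
    ("L5a", "L6"),
    ("L5b", "L6"),
    ("L6", "L4"),
)

#: originating layer and terminating layers per long-range class: feedforward
#: projections leave the supragranular layers, feedback leaves infragranular
#: layers; terminations innervate the full column depth by default (the
#: class-by-layer weight tables are configuration slots).
DEFAULT_CLASS_LAYERS = {
    "within_parcel": ("L3", ("L2", "L3", "L4", "L5a", "L5b", "L6")),
    "weak_ff": ("L3", ("L2", "L3", "L4", "L5a", "L5b", "L6")),
    "strong_ff": ("L3", ("L2", "L3", "L4", "L5a", "L5b", "L6")),
    "weak_fb": ("L5b", ("L2", "L3", "L4", "L5a", "L5b", "L6")),
    "strong_fb": ("L5b", ("L2", "L3", "L4", "L5a", "L5b", "L6")),
}


@dataclasses.dataclass
class ConnectivityConfig:
    """Constants of the generative connectivity model (distances in mm)."""

    lambda_mm: float = 23.4          # length constant of the exponential kernel
    beta: float = 0.17               # kernel scale (probability at zero fiber length)
    p1: float = 295.6                # rational geodesic->fiber map coefficients
    p2: float = -2256.0
    q1: float = 69.4
    max_delay_ms: float = 40.0
    max_fiber_mm: float = 226.1
    dt_ms: float = 0.5
    proximal_radius_mm: float = 0.1
    proximal_factor: float = 5.0
    inh_within_column_factor: float = 2.0
    inh_neighbor_order: int = 2
    matrix_tc_pe_radius_mm: float = 45.0
    matrix_tc_in_radius_mm: float = 80.0
    core_tc_pe_radius_mm: float = 12.0
    core_tc_in_radius_mm: float = 13.0
    intrathalamic_radius_mm: float = 11.0
    corticothalamic_radius_mm: float = 11.0
    intracolumn_adjacency: tuple = DEFAULT_INTRACOLUMN_ADJACENCY
    class_layers: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_CLASS_LAYERS))
    #: weight multiplier per connection class (slots for the class x layer-pair
    #: scaling tables; identity by default, overridable)
    class_factor: dict = dataclasses.field(
        default_factory=lambda: {name: 1.0 for name in CLASS_NAMES}
    )
    #: optional (n_parcels, n_parcels) residual connectivity added to the
    #: exponential kernel (distance-independent parcel-pair term)
    residual_parcel_connectivity: np.ndarray | None = None
    #: reference column count of the full-resolution surface.  At reduced
    #: mesh resolution each simulated column represents ``n_ref / n`` columns
    #: of the full surface, and the number of synapses drawn for an ordered
    #: column pair is Poisson with mean ``(n_ref / n) * p`` so that per-cell
    #: in-degree (the connectivity statistic the dynamics depend on) is
    #: resolution-invariant.  At full resolution the draw reduces to the
    #: plain Bernoulli kernel.  Set to None to disable the correction.
    reference_columns: int | None = 10242
    thalamus_level: int | None = 3
    matrix_target_layers: tuple = ("L2", "L5a")
    core_target_layers: tuple = ("L4",)
    corticothalamic_layer: str = "L6"

    def __post_init__(self):
        if self.lambda_mm <= 0:
            raise ValueError("lambda_mm must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        for name in ("matrix_tc_pe_radius_mm", "matrix_tc_in_radius_mm",
                     "core_tc_pe_radius_mm", "core_tc_in_radius_mm",
                     "intrathalamic_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for pre, post in self.intracolumn_adjacency:
            if pre not in LAYERS or post not in LAYERS:
                raise ValueError(f"intracolumn adjacency names unknown layer: {pre}->{post}")


def layer_index(name: str) -> int:
    return LAYERS.index(name)


@dataclasses.dataclass
class Connectome:
    """Flat synapse table plus the per-neuron normalization state."""

    n_columns: int
    n_thalamic: int                      # cells per thalamic population (0 = no thalamus)
    pre: np.ndarray                      # int32 cell ids
    post: np.ndarray
    receptor: np.ndarray                 # int8
    weight_factor: np.ndarray            # float32, 0 = ablated
    cls: np.ndarray                      # int8
    length_mm: np.ndarray                # float32 geodesic length
    fiber_mm: np.ndarray                 # float32 mapped fiber length
    delay_steps: np.ndarray              # int16
    norm_denom: np.ndarray | None = None   # (n_cells, 3) float64, current
    base_denom: np.ndarray | None = None   # (n_cells, 3) float64, intact model
    manifest: dict = dataclasses.field(default_factory=dict)

    # --- index helpers -----------------------------------------------------
    @property
    def n_py(self) -> int:
        return 6 * self.n_columns

    @property
    def n_cortical(self) -> int:
        return 12 * self.n_columns

    @property
    def n_cells(self) -> int:
        return self.n_cortical + 4 * self.n_thalamic

    def py_id(self, col, layer):
        return np.asarray(col) * N_LAYERS + layer

    def in_id(self, col, layer):
        return self.n_py + np.asarray(col) * N_LAYERS + layer

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def recompute_normalization(self) -> None:
        """Per-neuron, per-receptor sum of incoming weight factors.

        Synaptic strengths are per-synapse quantities; compensation after
        ablation rescales every surviving synapse by the ratio of the intact
        to the current incoming-factor sum, so each neuron's total synaptic
        budget stays at its intact-model value no matter how many synapses
        deliver it.  The intact sum is frozen the first time this is called
        (at construction).
        """
        denom = np.zeros((self.n_cells, 3), dtype=np.float64)
        np.add.at(denom, (self.post, self.receptor.astype(np.int64)), self.weight_factor)
        denom[denom == 0.0] = 1.0
        self.norm_denom = denom
        if self.base_denom is None:
            self.base_denom = denom.copy()

    def normalized_weights(self) -> np.ndarray:
        """Effective per-synapse weight: factor x (intact / current) incoming sum."""
        if self.norm_denom is None:
            self.recompute_normalization()
        idx = (self.post, self.receptor.astype(np.int64))
        return self.weight_factor * (self.base_denom[idx] / self.norm_denom[idx])

    def copy(self) -> "Connectome":
        return Connectome(
            n_columns=self.n_columns,
            n_thalamic=self.n_thalamic,
            pre=self.pre.copy(),
            post=self.post.copy(),
            receptor=self.receptor.copy(),
            weight_factor=self.weight_factor.copy(),
            cls=self.cls.copy(),
            length_mm=self.length_mm.copy(),
            fiber_mm=self.fiber_mm.copy(),
            delay_steps=self.delay_steps.copy(),
            norm_denom=None if self.norm_denom is None else self.norm_denom.copy(),
            base_denom=None if self.base_denom is None else self.base_denom.copy(),
            manifest=dict(self.manifest),
        )


# ---------------------------------------------------------------------------
# distance -> fiber -> probability
# ---------------------------------------------------------------------------

def geodesic_to_fiber(geodesic_mm, config: ConnectivityConfig | None = None):
    """Map geodesic surface distance to approximate white-matter fiber length.

    ``F(x) = (p1 x + p2) / (x + q1)``, floored at the geodesic distance itself
    (a fiber cannot be shorter than the surface path; the rational map dips
    below the identity for very short and very long distances).
    """
    cfg = config or ConnectivityConfig()
    x = np.asarray(geodesic_mm, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("geodesic distance must be >= 0")
    f = (cfg.p1 * x + cfg.p2) / (x + cfg.q1)
    return np.maximum(f, x)


def connection_probability(fiber_mm, config: ConnectivityConfig | None = None, residual=0.0):
    """Distance-dependent connection probability ``beta * exp(-fiber/lambda)``.

    An optional parcel-pair ``residual`` term (distance-independent
    connectivity) is added; the result is clipped to [0, 1].
    """
    cfg = config or ConnectivityConfig()
    f = np.asarray(fiber_mm, dtype=np.float64)
    p = cfg.beta * np.exp(-f / cfg.lambda_mm) + residual
    return np.clip(p, 0.0, 1.0)


def classify_hierarchical(pre_parcel, post_parcel, hierarchy, median_abs_dh):
    """Hierarchical class of an inter-column connection.

    Same parcel -> within_parcel; otherwise feedforward iff the post parcel
    sits higher in the hierarchy than the pre parcel, with the strong/weak
    split at the median absolute hierarchy difference of all realized
    inter-parcel connections.
    """
    pre_parcel = np.asarray(pre_parcel)
    post_parcel = np.asarray(post_parcel)
    dh = np.asarray(hierarchy)[post_parcel] - np.asarray(hierarchy)[pre_parcel]
    strong = np.abs(dh) > median_abs_dh
    out = np.where(
        pre_parcel == post_parcel,
        WITHIN_PARCEL,
        np.where(dh > 0, np.where(strong, STRONG_FF, WEAK_FF), np.where(strong, STRONG_FB, WEAK_FB)),
    )
    return out.astype(np.int8)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _empty_parts():
    return dict(pre=[], post=[], receptor=[], wf=[], cls=[], length=[])


def _append(parts, pre, post, receptor, wf, cls, length):
    parts["pre"].append(np.asarray(pre, dtype=np.int64))
    parts["post"].append(np.asarray(post, dtype=np.int64))
    n = len(parts["pre"][-1])
    parts["receptor"].append(np.full(n, receptor, dtype=np.int8))
    parts["wf"].append(np.broadcast_to(np.asarray(wf, dtype=np.float32), (n,)).copy())
    parts["cls"].append(np.full(n, cls, dtype=np.int8))
    parts["length"].append(np.broadcast_to(np.asarray(length, dtype=np.float32), (n,)).copy())


def build_long_range(
    mesh: HemisphereMesh,
    config: ConnectivityConfig,
    seed: int,
    geo: np.ndarray | None = None,
) -> dict:
    """Draw long-range PY->PY projections for every ordered active column pair.

    One independent uniform per ordered pair; a realized pair contributes one
    AMPA synapse and one NMDA co-synapse between the class-specific layers.
    """
    if mesh.hierarchy_index is None:
        raise ValueError("mesh needs parcels and hierarchy before long-range wiring")
    rng = np.random.default_rng(seed)
    active = np.flatnonzero(mesh.active)
    labels = mesh.parcel_label
    hier = mesh.hierarchy_index
    if geo is None:
        geo = geodesic_distances(mesh)

    resid = config.residual_parcel_connectivity
    mult = 1.0
    if config.reference_columns is not None:
        mult = max(1.0, config.reference_columns / mesh.n_columns)
    pre_cols, post_cols, lengths = [], [], []
    for i_block in np.array_split(active, max(1, len(active) // 512)):
        d = geo[np.ix_(i_block, active)]
        fiber = geodesic_to_fiber(d, config)
        if resid is not None:
            r = resid[np.ix_(labels[i_block], labels[active])]
        else:
            r = 0.0
        p = connection_probability(fiber, config, residual=r)
        # no self-projection
        p[i_block[:, None] == active[None, :]] = 0.0
        if mult > 1.0:
            cnt = rng.poisson(mult * p)
        else:
            cnt = (rng.random(p.shape) < p).astype(np.int64)
        ii, jj = np.nonzero(cnt)
        reps = cnt[ii, jj]
        pre_cols.append(np.repeat(i_block[ii], reps))
        post_cols.append(np.repeat(active[jj], reps))
        lengths.append(np.repeat(d[ii, jj], reps))
    pre_col = np.concatenate(pre_cols)
    post_col = np.concatenate(post_cols)
    length = np.concatenate(lengths)

    inter = labels[pre_col] != labels[post_col]
    dh = np.abs(hier[labels[post_col]] - hier[labels[pre_col]])
    median_dh = float(np.median(dh[inter])) if inter.any() else 0.0
    cls = classify_hierarchical(labels[pre_col], labels[post_col], hier, median_dh)

    parts = _empty_parts()
    for c in (WITHIN_PARCEL, WEAK_FF, STRONG_FF, WEAK_FB, STRONG_FB):
        m = cls == c
        if not m.any():
            continue
        lp, lqs = config.class_layers[CLASS_NAMES[c]]
        if isinstance(lqs, str):
            lqs = (lqs,)
        wf = np.full(m.sum(), config.class_factor[CLASS_NAMES[c]], dtype=np.float32)
        wf[length[m] <= config.proximal_radius_mm] *= config.proximal_factor
        pre_id = pre_col[m] * N_LAYERS + layer_index(lp)
        for lq in lqs:
            post_id = post_col[m] * N_LAYERS + layer_index(lq)
            _append(parts, pre_id, post_id, AMPA, wf, 0, length[m])
            parts["cls"][-1] = cls[m].copy()
            _append(parts, pre_id, post_id, NMDA, wf, 0, length[m])
            parts["cls"][-1] = cls[m].copy()
    parts["median_abs_dh"] = median_dh
    return parts


def build_intracolumn(mesh: HemisphereMesh, config: ConnectivityConfig) -> dict:
    """Within-column canonical circuit plus same-layer PY->IN drive."""
    n_py = 6 * mesh.n_columns
    cols = np.arange(mesh.n_columns)[mesh.active]
    parts = _empty_parts()
    wf = np.float32(config.proximal_factor)  # zero-length => proximal strengthening
    for pre_name, post_name in config.intracolumn_adjacency:
        li, lj = layer_index(pre_name), layer_index(post_name)
        _append(parts, cols * N_LAYERS + li, cols * N_LAYERS + lj, AMPA, wf, WITHIN_COLUMN, 0.0)
        _append(parts, cols * N_LAYERS + li, cols * N_LAYERS + lj, NMDA, wf, WITHIN_COLUMN, 0.0)
    for layer in range(N_LAYERS):
        _append(
            parts,
            cols * N_LAYERS + layer,
            n_py + cols * N_LAYERS + layer,
            AMPA,
            wf,
            WITHIN_COLUMN,
            0.0,
        )
    return parts


def build_inhibition(mesh: HemisphereMesh, config: ConnectivityConfig) -> dict:
    """Local same-layer inhibitory circuit.

    IN->PY GABA_A: own column (double weight) plus mesh neighbors up to
    second order, same layer only.  The reciprocal PY->IN excitation pools
    over the same neighborhood, so an interneuron integrates the local
    population rather than a single pyramidal cell."""
    n_py = 6 * mesh.n_columns
    rings = neighbor_rings(mesh, config.inh_neighbor_order)
    active = mesh.active
    geo_cache = mesh.vertices  # used only for neighbor lengths below
    parts = _empty_parts()
    cols = np.flatnonzero(active)
    # own column: inhibition is doubled within the local column (the proximal
    # x5 strengthening applies to excitatory synapses only)
    for layer in range(N_LAYERS):
        _append(
            parts,
            n_py + cols * N_LAYERS + layer,
            cols * N_LAYERS + layer,
            GABA_A,
            np.float32(config.inh_within_column_factor),
            LOCAL_INH,
            0.0,
        )
    # neighbors
    pre_c, post_c, lens = [], [], []
    for c in cols:
        nbrs = rings[c]
        nbrs = nbrs[active[nbrs]]
        if nbrs.size == 0:
            continue
        pre_c.append(np.full(nbrs.size, c))
        post_c.append(nbrs)
        if mesh.sphere_radius is not None:
            r = mesh.sphere_radius
            u = mesh.vertices / r
            d = r * np.arccos(np.clip(u[c] @ u[nbrs].T, -1, 1))
        else:
            d = np.linalg.norm(geo_cache[nbrs] - geo_cache[c], axis=1)
        lens.append(d)
    if pre_c:
        pre_c = np.concatenate(pre_c)
        post_c = np.concatenate(post_c)
        lens = np.concatenate(lens)
        prox = np.where(lens <= config.proximal_radius_mm, config.proximal_factor, 1.0)
        for layer in range(N_LAYERS):
            _append(
                parts,
                n_py + pre_c * N_LAYERS + layer,
                post_c * N_LAYERS + layer,
                GABA_A,
                prox.astype(np.float32),
                LOCAL_INH,
                lens,
            )
            # neighborhood PY -> IN drive (same layer, excitatory)
            _append(
                parts,
                pre_c * N_LAYERS + layer,
                n_py + post_c * N_LAYERS + layer,
                AMPA,
                prox.astype(np.float32),
                WITHIN_PARCEL,
                lens,
            )
    return parts


def thalamic_positions(mesh: HemisphereMesh, config: ConnectivityConfig) -> np.ndarray:
    """Positions of one thalamic population: a coarser icosphere aligned with
    (and scaled to) the cortical sphere."""
    level = config.thalamus_level
    if level is None:
        return np.zeros((0, 3))
    if mesh.sphere_radius is None:
        raise ValueError("thalamic placement requires a spherical cortical mesh")
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    v = np.asarray(ico.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * mesh.sphere_radius


def build_thalamic(
    mesh: HemisphereMesh, thal_pos: np.ndarray, config: ConnectivityConfig
) -> dict:
    """Thalamocortical, corticothalamic and intrathalamic fanouts by radius."""
    n_col = mesh.n_columns
    n_py = 6 * n_col
    n_ctx = 12 * n_col
    m = len(thal_pos)
    if m == 0:
        return _empty_parts()
    r_sph = mesh.sphere_radius
    unit_c = mesh.vertices / r_sph
    unit_t = thal_pos / np.linalg.norm(thal_pos, axis=1, keepdims=True)
    d_tc = r_sph * np.arccos(np.clip(unit_t @ unit_c.T, -1, 1))  # (m, n_col)
    d_tt = r_sph * np.arccos(np.clip(unit_t @ unit_t.T, -1, 1))

    max_geo = np.pi * r_sph
    for name in ("matrix_tc_pe_radius_mm", "matrix_tc_in_radius_mm"):
        if getattr(config, name) > max_geo:
            logger.warning("%s exceeds the mesh extent (%.1f mm)", name, max_geo)

    tc_core0 = n_ctx
    tc_mat0 = n_ctx + m
    re_core0 = n_ctx + 2 * m
    re_mat0 = n_ctx + 3 * m

    active = mesh.active
    parts = _empty_parts()

    def fanout(pop0, radius, target_layers, to_in):
        ti, ci = np.nonzero((d_tc <= radius) & active[None, :])
        for lname in target_layers:
            layer = layer_index(lname)
            base = 6 * n_col if to_in else 0
            _append(
                parts,
                pop0 + ti,
                base + ci * N_LAYERS + layer,
                AMPA,
                1.0,
                THALAMOCORTICAL,
                d_tc[ti, ci],
            )

    fanout(tc_mat0, config.matrix_tc_pe_radius_mm, config.matrix_target_layers, to_in=False)
    fanout(tc_mat0, config.matrix_tc_in_radius_mm, config.matrix_target_layers, to_in=True)
    fanout(tc_core0, config.core_tc_pe_radius_mm, config.core_target_layers, to_in=False)
    fanout(tc_core0, config.core_tc_in_radius_mm, config.core_target_layers, to_in=True)

    # cortex -> thalamus (L6 PY to TC and RE of both subsystems)
    layer = layer_index(config.corticothalamic_layer)
    ci, ti = np.nonzero((d_tc.T <= config.corticothalamic_radius_mm) & active[:, None])
    for pop0 in (tc_core0, tc_mat0, re_core0, re_mat0):
        _append(parts, ci * N_LAYERS + layer, pop0 + ti, AMPA, 1.0, CORTICOTHALAMIC, d_tc[ti, ci])

    # intrathalamic: TC->RE (AMPA), RE->TC and RE->RE (GABA), within subsystem
    ti, tj = np.nonzero(d_tt <= config.intrathalamic_radius_mm)
    for tc0, re0 in ((tc_core0, re_core0), (tc_mat0, re_mat0)):
        _append(parts, tc0 + ti, re0 + tj, AMPA, 1.0, INTRATHALAMIC, d_tt[ti, tj])
        _append(parts, re0 + ti, tc0 + tj, GABA_A, 1.0, INTRATHALAMIC, d_tt[ti, tj])
        keep = ti != tj
        _append(parts, re0 + ti[keep], re0 + tj[keep], GABA_A, 1.0, INTRATHALAMIC, d_tt[ti[keep], tj[keep]])
    return parts


def assign_delays(fiber_mm: np.ndarray, config: ConnectivityConfig) -> np.ndarray:
    """Delays proportional to fiber length: ``max_delay * fiber / max_fiber``,
    rounded up to 0.5 ms steps, minimum one step."""
    fiber = np.asarray(fiber_mm, dtype=np.float64)
    over = fiber > config.max_fiber_mm
    if over.any():
        logger.warning("%d synapses exceed max fiber length; delays clamped", int(over.sum()))
    delay_ms = config.max_delay_ms * np.minimum(fiber, config.max_fiber_mm) / config.max_fiber_mm
    steps = np.ceil(delay_ms / config.dt_ms - 1e-9).astype(np.int16)
    return np.maximum(steps, 1)


def build_connectome(
    mesh: HemisphereMesh,
    config: ConnectivityConfig | None = None,
    seed: int = 0,
    thalamus: bool = True,
    geo: np.ndarray | None = None,
) -> Connectome:
    """Assemble the full synapse table for a parcellated hemisphere mesh."""
    cfg = config or ConnectivityConfig()
    lr = build_long_range(mesh, cfg, seed, geo=geo)
    ic = build_intracolumn(mesh, cfg)
    inh = build_inhibition(mesh, cfg)
    if thalamus and cfg.thalamus_level is not None:
        tpos = thalamic_positions(mesh, cfg)
        th = build_thalamic(mesh, tpos, cfg)
        n_thal = len(tpos)
    else:
        th = _empty_parts()
        n_thal = 0

    parts = _empty_parts()
    for p in (lr, ic, inh, th):
        for k in parts:
            parts[k].extend(p[k])
    pre = np.concatenate(parts["pre"]).astype(np.int32)
    post = np.concatenate(parts["post"]).astype(np.int32)
    receptor = np.concatenate(parts["receptor"])
    wf = np.concatenate(parts["wf"])
    cls = np.concatenate(parts["cls"])
    length = np.concatenate(parts["length"])
    if np.any(pre == post):
        raise AssertionError("self-synapse generated")  # construction invariant
    fiber = np.where(
        np.isin(cls, (WITHIN_COLUMN, LOCAL_INH)) | (length == 0),
        length,
        geodesic_to_fiber(length, cfg),
    ).astype(np.float32)
    # local wiring rides on the surface: fiber = geodesic there
    local = np.isin(cls, (LOCAL_INH, WITHIN_COLUMN, THALAMOCORTICAL, CORTICOTHALAMIC, INTRATHALAMIC))
    fiber[local] = length[local]
    delays = assign_delays(fiber, cfg)

    conn = Connectome(
        n_columns=mesh.n_columns,
        n_thalamic=n_thal,
        pre=pre,
        post=post,
        receptor=receptor,
        weight_factor=wf,
        cls=cls,
        length_mm=length,
        fiber_mm=fiber,
        delay_steps=delays,
        manifest={
            "seed": int(seed),
            "n_columns": int(mesh.n_columns),
            "n_thalamic": int(n_thal),
            "median_abs_dh": lr.get("median_abs_dh"),
            "synapses_per_class": {
                CLASS_NAMES[c]: int((cls == c).sum()) for c in range(len(CLASS_NAMES))
            },
        },
    )
    conn.recompute_normalization()
    for c in range(len(CLASS_NAMES)):
        logger.info("class %-16s: %8d synapses", CLASS_NAMES[c], int((cls == c).sum()))
    return conn


# ---------------------------------------------------------------------------
# manipulation protocols
# ---------------------------------------------------------------------------

def apply_density(conn: Connectome, P: float, seed: int = 0) -> Connectome:
    """Retain each inter-column cortical excitatory synapse independently
    with probability P.

    The manipulation thins the connectivity between regions; the canonical
    within-column circuit is not part of the generative density and is left
    intact.  Ablation is implemented by zeroing the weight factor; the
    normalization is recomputed, so surviving synapses are compensatorily
    strengthened.  The distance distribution of survivors is unchanged in
    expectation.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    out = conn.copy()
    rng = np.random.default_rng(seed)
    target = np.isin(out.cls, CORTICAL_EXC_CLASSES) & (out.cls != WITHIN_COLUMN)
    if P < 1.0:
        drop = target & (rng.random(out.n_synapses) >= P)
        out.weight_factor[drop] = 0.0
    out.recompute_normalization()
    out.manifest["density_P"] = float(P)
    return out


def apply_radius(conn: Connectome, R_mm: float) -> Connectome:
    """Zero all cortical excitatory synapses with geodesic length > R (deterministic),
    with compensatory renormalization."""
    if R_mm <= 0:
        raise ValueError("R_mm must be positive")
    out = conn.copy()
    target = np.isin(out.cls, CORTICAL_EXC_CLASSES) & (out.length_mm > R_mm)
    out.weight_factor[target] = 0.0
    out.recompute_normalization()
    out.manifest["radius_R_mm"] = float(R_mm)
    return out


def apply_strength_scaling(
    conn: Connectome, factor: float, R_threshold_mm: float | None = None
) -> Connectome:
    """Scale cortical excitatory weights (all, or only beyond a radius).

    Deliberately does NOT recompute the normalization: total synaptic input
    per cell is allowed to change, altering the excitation/inhibition balance.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = conn.copy()
    target = np.isin(out.cls, CORTICAL_EXC_CLASSES)
    if R_threshold_mm is not None:
        target &= out.length_mm > R_threshold_mm
    out.weight_factor[target] *= factor
    out.manifest["strength_factor"] = float(factor)
    out.manifest["strength_R_th_mm"] = None if R_threshold_mm is None else float(R_threshold_mm)
    return out


def apply_delay_scaling(conn: Connectome, max_delay_ms: float, dt_ms: float = 0.5) -> Connectome:
    """Rescale all delays proportionally so the longest fiber gets ``max_delay_ms``."""
    out = conn.copy()
    cfg = ConnectivityConfig(max_delay_ms=max_delay_ms, dt_ms=dt_ms)
    out.delay_steps = assign_delays(out.fiber_mm, cfg)
    out.manifest["max_delay_ms"] = float(max_delay_ms)
    return out


def apply_uniform_delay(conn: Connectome, delay_ms: float, dt_ms: float = 0.5) -> Connectome:
    out = conn.copy()
    steps = max(1, int(np.ceil(delay_ms / dt_ms - 1e-9)))
    out.delay_steps = np.full(out.n_synapses, steps, dtype=np.int16)
    out.manifest["uniform_delay_ms"] = float(delay_ms)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_connectome(conn: Connectome, outdir: str | Path) -> None:
    """Edge list TSV + per-receptor Matrix Market weight matrices + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "pre": conn.pre,
            "post": conn.post,
            "receptor": np.array(RECEPTOR_NAMES)[conn.receptor],
            "weight_factor": conn.weight_factor,
            "class": np.array(CLASS_NAMES)[conn.cls],
            "delay_steps": conn.delay_steps,
            "length_mm": conn.length_mm,
            "fiber_mm": conn.fiber_mm,
        }
    )
    df.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    for r, name in enumerate(RECEPTOR_NAMES):
        m = conn.receptor == r
        mat = sp.coo_matrix(
            (conn.weight_factor[m], (conn.pre[m], conn.post[m])),
            shape=(conn.n_cells, conn.n_cells),
        )
        scipy.io.mmwrite(outdir / f"weights_{name}.mtx", mat)
    (outdir / "manifest.json").write_text(json.dumps(conn.manifest, indent=2, default=str))


def load_connectome(outdir: str | Path, n_columns: int, n_thalamic: int = 0) -> Connectome:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "edges.tsv", sep="\t")
    rec = np.array([RECEPTOR_NAMES.index(r) for r in df["receptor"]], dtype=np.int8)
    cls = np.array([CLASS_NAMES.index(c) for c in df["class"]], dtype=np.int8)
    manifest = json.loads((outdir / "manifest.json").read_text()) if (outdir / "manifest.json").exists() else {}
    conn = Connectome(
        n_columns=n_columns,
        n_thalamic=n_thalamic,
        pre=df["pre"].to_numpy(np.int32),
        post=df["post"].to_numpy(np.int32),
        receptor=rec,
        weight_factor=df["weight_factor"].to_numpy(np.float32),
        cls=cls,
        length_mm=df["length_mm"].to_numpy(np.float32),
        fiber_mm=df["fiber_mm"].to_numpy(np.float32),
        delay_steps=df["delay_steps"].to_numpy(np.int16),
        manifest=manifest,
    )
    conn.recompute_normalization()
    return conn
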