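import numpy as np
import pytest

from slowwave.connectome import (
    AMPA,
    GABA_A,
    LOCAL_INH,
    NMDA,
    STRONG_FB,
    STRONG_FF,
    WEAK_FB,
    WEAK_FF,
    WITHIN_COLUMN,
    WITHIN_PARCEL,
    CORTICAL_EXC_CLASSES,
    ConnectivityConfig,
    Connectome,
    apply_density,
    apply_radius,
    apply_strength_scaling,
    assign_delays,
    build_connectome,
    build_intracolumn,
    build_long_range,
    classify_hierarchical,
    connection_probability,
    geodesic_to_fiber,
    load_connectome,
    save_connectome,
)
from slowwave.mesh import assign_hierarchy, assign_parcels, build_icosphere
from slowwave.so import intact_score

CFG = ConnectivityConfig()


class TestFiberMap:
    def test_printed_constants_at_100mm(self):
        # (295.6*100 - 2256) / (100 + 69.4)
        assert geodesic_to_fiber(100.0) == pytest.approx(27304.0 / 169.4)

    def test_floored_at_geodesic_below_numerator_root(self):
        root = 2256.0 / 295.6  # ~7.632 mm, raw F = 0
        assert geodesic_to_fiber(root) == pytest.approx(root)
        assert geodesic_to_fiber(2.0) == pytest.approx(2.0)

    def test_monotone_increasing(self):
        x = np.linspace(0, 300, 2000)
        f = geodesic_to_fiber(x)
        assert np.all(np.diff(f) >= -1e-12)

    def test_fiber_never_shorter_than_surface_path(self):
        x = np.linspace(0, 300, 500)
        assert np.all(geodesic_to_fiber(x) >= x - 1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            geodesic_to_fiber(-1.0)


class TestConnectionProbability:
    def test_zero_distance_gives_beta(self):
        assert connection_probability(0.0) == pytest.approx(0.17)

    def test_one_length_constant_gives_beta_over_e(self):
        assert connection_probability(23.4) == pytest.approx(0.17 * np.exp(-1))

    def test_limit_and_clipping(self):
        assert connection_probability(1e6) == pytest.approx(0.0, abs=1e-12)
        assert connection_probability(0.0, residual=5.0) == 1.0
        assert connection_probability(0.0, residual=-5.0) == 0.0


class TestClassification:
    def test_same_parcel_is_within_parcel(self):
        h = np.array([0.2, 0.8])
        assert classify_hierarchical([0], [0], h, 0.1)[0] == WITHIN_PARCEL

    def test_direction_and_strength(self):
        h = np.array([0.1, 0.9, 0.5])
        assert classify_hierarchical([0], [1], h, 0.5)[0] == STRONG_FF
        assert classify_hierarchical([0], [2], h, 0.5)[0] == WEAK_FF
        assert classify_hierarchical([1], [0], h, 0.5)[0] == STRONG_FB
        assert classify_hierarchical([2], [0], h, 0.5)[0] == WEAK_FB

    def test_swap_maps_ff_to_fb(self):
        h = np.linspace(0, 1, 10)
        pre = np.arange(5)
        post = np.arange(5, 10)
        fwd = classify_hierarchical(pre, post, h, 0.3)
        bwd = classify_hierarchical(post, pre, h, 0.3)
        swap = {WEAK_FF: WEAK_FB, STRONG_FF: STRONG_FB}
        assert all(swap[f] == b for f, b in zip(fwd, bwd))


class TestLongRange:
    def test_beta_zero_yields_no_synapses(self, ico1_mesh):
        cfg = ConnectivityConfig(beta=0.0, thalamus_level=None, reference_columns=None)
        parts = build_long_range(ico1_mesh, cfg, seed=0)
        assert sum(len(p) for p in parts["pre"]) == 0

    def test_expected_count_matches_binomial_sum(self, ico1_mesh):
        """Mean draw count over seeds agrees with the summed kernel."""
        from slowwave.mesh import geodesic_distances

        cfg = ConnectivityConfig(thalamus_level=None, reference_columns=None)
        geo = geodesic_distances(ico1_mesh)
        active = np.flatnonzero(ico1_mesh.active)
        d = geo[np.ix_(active, active)]
        p = connection_probability(geodesic_to_fiber(d, cfg), cfg)
        np.fill_diagonal(p, 0.0)
        expect = p.sum()
        sd = np.sqrt((p * (1 - p)).sum())
        counts = []
        for seed in range(10):
            parts = build_long_range(ico1_mesh, cfg, seed=seed)
            n_pairs = sum(len(x) for x in parts["pre"]) / 2  # AMPA + NMDA co-synapse
            n_pairs /= len(cfg.class_layers["weak_ff"][1])   # one synapse per target layer
            counts.append(n_pairs)
        assert abs(np.mean(counts) - expect) < 3 * sd / np.sqrt(10)

    def test_missing_hierarchy_rejected(self):
        mesh = build_icosphere(1)
        with pytest.raises(ValueError):
            build_long_range(mesh, CFG, seed=0)


class TestIntracolumn:
    def test_l4_receives_only_from_l6_within_column(self, ico1_network):
        mesh, conn = ico1_network
        m = (conn.cls == WITHIN_COLUMN) & (conn.receptor == AMPA) & (conn.post < conn.n_py)
        post_layer = conn.post[m] % 6
        pre_layer = conn.pre[m] % 6
        to_l4 = post_layer == 2  # L4
        assert to_l4.any()
        assert np.all(pre_layer[to_l4] == 5)  # L6

    def test_no_self_synapses_anywhere(self, ico1_network):
        _, conn = ico1_network
        assert np.all(conn.pre != conn.post)

    def test_empty_adjacency_gives_only_py_in_drive(self, ico1_mesh):
        cfg = ConnectivityConfig(intracolumn_adjacency=(), thalamus_level=None)
        parts = build_intracolumn(ico1_mesh, cfg)
        # only the same-layer PY->IN synapses remain
        assert all(r == AMPA for arr in parts["receptor"] for r in arr)
        assert all(int(q) >= 6 * ico1_mesh.n_columns
                   for arr in parts["post"] for q in arr)


class TestInhibition:
    def test_same_layer_only(self, ico1_network):
        _, conn = ico1_network
        m = conn.cls == LOCAL_INH
        assert np.all(conn.pre[m] % 6 == conn.post[m] % 6)

    def test_within_column_weight_doubled(self, ico1_network):
        _, conn = ico1_network
        m = conn.cls == LOCAL_INH
        own = conn.length_mm[m] == 0.0
        ratio = conn.weight_factor[m][own].mean() / conn.weight_factor[m][~own].mean()
        assert ratio == pytest.approx(2.0)

    def test_neighbors_within_second_order(self, ico1_network):
        from slowwave.mesh import neighbor_rings

        mesh, conn = ico1_network
        rings = neighbor_rings(mesh, 2)
        m = (conn.cls == LOCAL_INH) & (conn.length_mm > 0)
        pre_col = (conn.pre[m] - conn.n_py) // 6
        post_col = conn.post[m] // 6
        for a, b in zip(pre_col[:200], post_col[:200]):
            assert b in rings[a]


class TestThalamic:
    def test_matrix_fanout_within_radius(self, ico1_network):
        mesh, conn = ico1_network
        from slowwave.connectome import THALAMOCORTICAL

        m = (conn.cls == THALAMOCORTICAL) & (conn.post < conn.n_py)
        assert m.any()
        assert conn.length_mm[m].max() <= CFG.matrix_tc_pe_radius_mm + 1e-6

    def test_core_fanout_smaller_than_matrix(self, ico1_network):
        mesh, conn = ico1_network
        from slowwave.connectome import THALAMOCORTICAL

        n_thal = conn.n_thalamic
        tc_core0 = conn.n_cortical
        tc_mat0 = conn.n_cortical + n_thal
        m = (conn.cls == THALAMOCORTICAL) & (conn.post < conn.n_py)
        core = np.isin(conn.pre[m], np.arange(tc_core0, tc_core0 + n_thal))
        mat = np.isin(conn.pre[m], np.arange(tc_mat0, tc_mat0 + n_thal))
        assert core.sum() < mat.sum()


class TestDelays:
    def test_longest_fiber_gets_max_delay(self):
        steps = assign_delays(np.array([226.1]), CFG)
        assert steps[0] == 80  # 40 ms at 0.5 ms steps

    def test_linear_in_fiber_length(self):
        steps = assign_delays(np.array([113.05]), CFG)
        assert steps[0] == 40  # 20 ms

    def test_zero_fiber_one_step_floor(self):
        assert assign_delays(np.array([0.0]), CFG)[0] == 1

    def test_overlong_fiber_clamped(self, caplog):
        steps = assign_delays(np.array([500.0]), CFG)
        assert steps[0] == 80

    def test_all_delays_within_bounds(self, ico1_network):
        _, conn = ico1_network
        assert conn.delay_steps.min() >= 1
        assert conn.delay_steps.max() <= 80


class TestDensity:
    def test_p_one_is_identity(self, ico2_network):
        _, conn = ico2_network
        out = apply_density(conn, 1.0, seed=0)
        assert np.array_equal(out.weight_factor, conn.weight_factor)

    def test_retention_fraction_binomial(self, ico2_network):
        _, conn = ico2_network
        out = apply_density(conn, 0.5, seed=3)
        # density thins the inter-column excitatory connectivity; the
        # canonical within-column circuit is untouched
        target = np.isin(conn.cls, CORTICAL_EXC_CLASSES) & (conn.cls != WITHIN_COLUMN)
        kept = (out.weight_factor[target] > 0).mean()
        n = target.sum()
        assert abs(kept - 0.5) < 3 * np.sqrt(0.25 / n)
        within = conn.cls == WITHIN_COLUMN
        assert np.all(out.weight_factor[within] == conn.weight_factor[within])

    def test_distance_distribution_preserved(self, ico2_network):
        from scipy.stats import ks_2samp

        _, conn = ico2_network
        out = apply_density(conn, 0.5, seed=3)
        target = np.isin(conn.cls, CORTICAL_EXC_CLASSES) & (conn.length_mm > 0)
        before = conn.length_mm[target]
        after = out.length_mm[target & (out.weight_factor > 0)]
        assert ks_2samp(before, after).pvalue > 0.01

    def test_compensation_invariant_exact(self, ico2_network):
        """Per-neuron per-receptor effective input is unchanged by ablation."""
        _, conn = ico2_network
        out = apply_density(conn, 0.4, seed=7)
        for c in (conn, out):
            w = c.normalized_weights()
            tot = np.zeros((c.n_cells, 3))
            np.add.at(tot, (c.post, c.receptor.astype(int)), w)
        w0 = conn.normalized_weights()
        t0 = np.zeros((conn.n_cells, 3))
        np.add.at(t0, (conn.post, conn.receptor.astype(int)), w0)
        w1 = out.normalized_weights()
        t1 = np.zeros((out.n_cells, 3))
        np.add.at(t1, (out.post, out.receptor.astype(int)), w1)
        nz = t0 > 0
        # cells that lost every synapse of a receptor cannot be compensated
        lost = (t1 == 0) & nz
        keep = nz & ~lost
        assert np.max(np.abs(t1[keep] - t0[keep]) / t0[keep]) < 1e-12


class TestRadius:
    def test_large_radius_identity(self, ico2_network):
        _, conn = ico2_network
        out = apply_radius(conn, 1e6)
        assert np.array_equal(out.weight_factor, conn.weight_factor)

    def test_retained_count_monotone_in_radius(self, ico2_network):
        _, conn = ico2_network
        counts = [(apply_radius(conn, r).weight_factor > 0).sum() for r in (5, 20, 80, 300)]
        assert counts == sorted(counts)

    def test_small_radius_keeps_only_local_excitation(self, ico2_network):
        mesh, conn = ico2_network
        # ico2 spacing ~20 mm: a 2.5 mm radius keeps only zero-length wiring
        out = apply_radius(conn, 2.5)
        exc = np.isin(out.cls, CORTICAL_EXC_CLASSES) & (out.weight_factor > 0)
        assert np.all(out.length_mm[exc] <= 2.5)


class TestStrengthScaling:
    def test_identity_factor(self, ico2_network):
        _, conn = ico2_network
        out = apply_strength_scaling(conn, 1.0)
        assert np.allclose(out.normalized_weights(), conn.normalized_weights())

    def test_long_range_only_scaling(self, ico2_network):
        _, conn = ico2_network
        out = apply_strength_scaling(conn, 0.2, R_threshold_mm=10.0)
        target = np.isin(conn.cls, CORTICAL_EXC_CLASSES) & (conn.length_mm > 10.0)
        assert np.allclose(out.weight_factor[target], conn.weight_factor[target] * 0.2)
        assert np.array_equal(out.weight_factor[~target], conn.weight_factor[~target])

    def test_no_compensation_triggered(self, ico2_network):
        """Scaling deliberately changes total synaptic input per cell."""
        _, conn = ico2_network
        out = apply_strength_scaling(conn, 0.5)
        assert np.allclose(out.normalized_weights(),
                           np.where(np.isin(conn.cls, CORTICAL_EXC_CLASSES),
                                    conn.normalized_weights() * 0.5,
                                    conn.normalized_weights()))


class TestIntactScore:
    def test_identity_is_100(self, ico2_network):
        _, conn = ico2_network
        assert intact_score(conn, conn) == pytest.approx(100.0)

    def test_halving_gives_50(self, ico2_network):
        _, conn = ico2_network
        out = apply_strength_scaling(conn, 0.5)
        assert intact_score(out, conn) == pytest.approx(50.0)

    def test_long_range_scaling_matches_analytic_mixture(self, ico2_network):
        _, conn = ico2_network
        out = apply_strength_scaling(conn, 0.2, R_threshold_mm=10.0)
        w = conn.normalized_weights()
        exc = np.isin(conn.cls, CORTICAL_EXC_CLASSES) & (conn.receptor != GABA_A)
        far = exc & (conn.length_mm > 10.0)
        expected = 100.0 * (w[exc & ~far].sum() + 0.2 * w[far].sum()) / w[exc].sum()
        assert intact_score(out, conn) == pytest.approx(expected, rel=1e-6)


def test_connectome_io_roundtrip(tmp_path, ico1_network):
    _, conn = ico1_network
    save_connectome(conn, tmp_path)
    back = load_connectome(tmp_path, conn.n_columns, conn.n_thalamic)
    assert back.n_synapses == conn.n_synapses
    assert np.array_equal(back.pre, conn.pre)
    assert np.array_equal(back.delay_steps, conn.delay_steps)
    assert np.allclose(back.weight_factor, conn.weight_factor)
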