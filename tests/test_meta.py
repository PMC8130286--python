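import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fastripple as fr
from fastripple.causality import CausalEpochResult
from fastripple.meta import (
    adjust_pvalues,
    pool_connection,
    pool_all_connections,
    build_network,
    classify_nodes,
)

REGIONS = ("DG", "CA3", "CA1")


def _epoch(pre, post, event_id=0, pre_ok=True, post_ok=True):
    return CausalEpochResult(
        event_id=event_id, regions=REGIONS,
        pre_matrix=np.asarray(pre, float), post_matrix=np.asarray(post, float),
        pre_stationary=pre_ok, post_stationary=post_ok,
    )


def _mat(value):
    m = np.full((3, 3), float(value))
    np.fill_diagonal(m, np.nan)
    return m


class TestBonferroni:
    def test_times_six(self):
        out = adjust_pvalues([_epoch(_mat(0.01), _mat(0.01))])[0]
        assert out.pre_matrix[0, 1] == pytest.approx(0.06)

    def test_capped_at_one(self):
        out = adjust_pvalues([_epoch(_mat(0.5), _mat(0.5))])[0]
        assert out.pre_matrix[0, 1] == 1.0

    def test_nan_propagates(self):
        out = adjust_pvalues([_epoch(_mat(np.nan), _mat(0.2))])[0]
        assert np.isnan(out.pre_matrix[0, 1])

    def test_inputs_not_mutated(self):
        ep = _epoch(_mat(0.01), _mat(0.01))
        adjust_pvalues([ep])
        assert ep.pre_matrix[0, 1] == 0.01


def _normal_cdf(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestNormalCurvePooling:
    def test_null_center_is_exact(self):
        c = pool_connection(np.full(17, 0.5), "DG", "CA3", "pre")
        assert c.z == 0.0
        assert c.overall_p == 0.5

    def test_hand_computed_case(self):
        c = pool_connection(np.full(4, 0.1), "DG", "CA3", "pre")
        z = (0.1 - 0.5) / (0.2887 / 2.0)
        assert c.z == pytest.approx(z, abs=1e-12)
        assert c.z == pytest.approx(-2.771, abs=1e-3)
        assert c.overall_p == pytest.approx(_normal_cdf(z), abs=1e-12)
        assert c.overall_p == pytest.approx(0.0028, abs=2e-4)

    def test_all_ones_n_nine(self):
        c = pool_connection(np.ones(9), "DG", "CA3", "post")
        assert c.z == pytest.approx((1.0 - 0.5) / (0.2887 / 3.0), abs=1e-12)
        assert c.z == pytest.approx(5.196, abs=1e-3)
        assert c.overall_p > 0.999999

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="insufficient"):
            pool_connection(np.array([0.2]), "DG", "CA3", "pre")

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariance(self, ps, rnd):
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        a = pool_connection(np.array(ps), "DG", "CA3", "pre")
        b = pool_connection(np.array(shuffled), "DG", "CA3", "pre")
        assert a.overall_p == pytest.approx(b.overall_p, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20),
        st.integers(0, 19),
        st.floats(0.001, 0.99),
    )
    def test_lowering_any_p_never_raises_overall(self, ps, idx, frac):
        idx = idx % len(ps)
        base = pool_connection(np.array(ps), "DG", "CA3", "pre").overall_p
        lowered = list(ps)
        lowered[idx] = lowered[idx] * frac
        after = pool_connection(np.array(lowered), "DG", "CA3", "pre").overall_p
        assert after <= base + 1e-12

    def test_excluded_events_reduce_n(self):
        eps = [
            _epoch(_mat(0.01), _mat(0.5), event_id=0),
            _epoch(_mat(0.01), _mat(0.5), event_id=1, pre_ok=False),
            _epoch(_mat(0.01), _mat(0.5), event_id=2),
        ]
        pooled = pool_all_connections(eps)
        assert all(c.n == 2 for c in pooled["pre"])


class TestNetworkMetrics:
    def _pooled(self, sig_edges, epoch="pre", n=10):
        out = []
        for i in REGIONS:
            for j in REGIONS:
                if i == j:
                    continue
                p = np.full(n, 0.01 if (i, j) in sig_edges else 0.99)
                out.append(pool_connection(p, i, j, epoch))
        return out

    def test_empty_network_all_zero(self):
        net = build_network(self._pooled(set()), "pre", REGIONS)
        assert net.edges == []
        assert all(v == 0 for v in net.unit_causal_density.values())
        assert all(v == 0 for v in net.causal_flow.values())
        assert all(not r["hub"] and r["flow_role"] == "neutral"
                   for r in classify_nodes(net).values())

    def test_pre_event_loop_densities_and_flows(self):
        """The closed pre-event loop has zero net flow and CA3 as the hub."""
        edges = {("DG", "CA3"), ("CA3", "DG"), ("CA3", "CA1"), ("CA1", "CA3")}
        net = build_network(self._pooled(edges), "pre", REGIONS)
        assert net.edge_set() == edges
        assert net.causal_flow == {"DG": 0, "CA3": 0, "CA1": 0}
        assert net.unit_causal_density["DG"] == pytest.approx(2 / 3)
        assert net.unit_causal_density["CA3"] == pytest.approx(4 / 3)
        assert net.unit_causal_density["CA1"] == pytest.approx(2 / 3)
        roles = classify_nodes(net)
        assert roles["CA3"]["hub"] and not roles["DG"]["hub"]

    def test_post_event_circuit_source_and_sink(self):
        """Feed-forward circuit: DG is the causal source, CA3 the sink."""
        edges = {("DG", "CA3"), ("CA3", "CA1"), ("CA1", "CA3")}
        net = build_network(self._pooled(edges, epoch="post"), "post", REGIONS)
        assert net.causal_flow == {"DG": 1, "CA3": -1, "CA1": 0}
        roles = classify_nodes(net)
        assert roles["DG"]["flow_role"] == "source"
        assert roles["CA3"]["flow_role"] == "sink"
        assert roles["CA1"]["flow_role"] == "neutral"

    def test_fully_connected_digraph(self):
        # each node is involved in 4 of the 6 directed edges: density 4/3
        edges = {(i, j) for i in REGIONS for j in REGIONS if i != j}
        net = build_network(self._pooled(edges), "pre", REGIONS)
        assert all(v == pytest.approx(4.0 / 3.0) for v in net.unit_causal_density.values())
        assert all(v == 0 for v in net.causal_flow.values())

    @settings(deadline=None, max_examples=40)
    @given(st.sets(st.sampled_from(
        [(i, j) for i in REGIONS for j in REGIONS if i != j])))
    def test_causal_flow_sums_to_zero(self, edges):
        net = build_network(self._pooled(edges), "pre", REGIONS)
        assert sum(net.causal_flow.values()) == 0

    def test_graph_export_carries_attributes(self):
        edges = {("DG", "CA3"), ("CA3", "CA1"), ("CA1", "CA3")}
        g = build_network(self._pooled(edges, epoch="post"), "post", REGIONS).to_graph()
        assert set(g.nodes) == set(REGIONS)
        assert g.nodes["DG"]["flow_role"] == "source"
        assert g.has_edge("DG", "CA3")
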