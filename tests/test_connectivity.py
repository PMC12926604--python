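"""Connectivity-matrix and network-construction tests."""

import numpy as np
import pandas as pd
import pytest

from fcgraph import connectivity as C
from fcgraph.timeseries import RegionalTimeSeries

from conftest import make_net


def ts_from(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"r{i}" for i in range(values.shape[1])]
    return RegionalTimeSeries(values=values, tr_seconds=2.0, region_labels=labels)


def random_cm(rng, n):
    m = np.abs(rng.random((n, n)))
    m = np.triu(m, 1)
    m = m + m.T
    return C.ConnectivityMatrix(values=m, region_labels=[f"r{i}" for i in range(n)])


class TestCorrelationMatrix:
    def test_identical_and_negated_regions_give_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        cm = C.correlation_matrix(ts_from(np.column_stack([x, x, -x])))
        assert cm.values[0, 1] == pytest.approx(1.0)
        assert cm.values[0, 2] == pytest.approx(1.0)  # absolute-value rule
        assert np.all(np.diag(cm.values) == 0)

    def test_matches_manual_pearson(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (40, 3))
        cm = C.correlation_matrix(ts_from(vals))
        for i in range(3):
            for j in range(i + 1, 3):
                xi = vals[:, i] - vals[:, i].mean()
                xj = vals[:, j] - vals[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cm.values[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_region_error_names_label(self):
        vals = np.column_stack([np.random.default_rng(2).normal(0, 1, 20), np.ones(20)])
        with pytest.raises(ValueError, match="flat"):
            C.correlation_matrix(ts_from(vals, labels=["ok", "flat"]))

    def test_censored_frames_excluded(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (30, 2))
        mask = np.ones(30, dtype=bool)
        mask[10:20] = False
        ts = RegionalTimeSeries(
            values=vals, tr_seconds=2.0, region_labels=["a", "b"], censor_mask=mask
        )
        cm = C.correlation_matrix(ts)
        sub = ts_from(vals[mask])
        cm_sub = C.correlation_matrix(sub)
        assert np.allclose(cm.values, cm_sub.values)


class TestAbsoluteThreshold:
    def test_rule_keeps_edges_at_or_above(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.2
        m[0, 2] = m[2, 0] = 0.6
        m[1, 2] = m[2, 1] = 0.7
        cm = C.ConnectivityMatrix(values=m, region_labels=["a", "b", "c"])
        net = C.threshold_absolute(cm, 0.5)
        assert net.n_edges == 2
        # boundary: non-strict by default
        assert C.threshold_absolute(cm, 0.6).n_edges == 2
        assert C.threshold_absolute(cm, 0.6, strict=True).n_edges == 1

    def test_zero_threshold_complete_on_nonzero(self, rng):
        cm = random_cm(rng, 6)
        net = C.threshold_absolute(cm, 0.0)
        assert net.n_edges == 15

    def test_above_max_gives_empty_graph(self, rng):
        cm = random_cm(rng, 5)
        net = C.threshold_absolute(cm, 1.0)
        assert net.n_edges == 0
        assert C.count_components(net) == 5

    def test_edge_count_non_increasing_in_threshold(self, rng):
        cm = random_cm(rng, 12)
        counts = [
            C.threshold_absolute(cm, t).n_edges for t in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestProportionalThreshold:
    def test_rounding_rule_n10_p025(self, rng):
        cm = random_cm(rng, 10)  # 45 possible edges, 0.25*45 = 11.25 -> 11
        assert C.threshold_proportional(cm, 0.25).n_edges == 11

    def test_p_one_keeps_all(self, rng):
        cm = random_cm(rng, 8)
        assert C.threshold_proportional(cm, 1.0).n_edges == 28

    def test_tie_break_deterministic(self):
        m = np.zeros((4, 4))
        # two entries tied exactly at the cutoff
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = 0.5
        m[1, 3] = m[3, 1] = 0.5
        m[2, 3] = m[3, 2] = 0.1
        cm = C.ConnectivityMatrix(values=m, region_labels=list("abcd"))
        net1 = C.threshold_proportional(cm, 2 / 6)  # k = 2 of 6
        net2 = C.threshold_proportional(cm, 2 / 6)
        assert np.array_equal(net1.adjacency, net2.adjacency)
        # smaller (i, j) kept among the tied pair: (0, 2) beats (1, 3)
        assert net1.adjacency[0, 2] == 1.0
        assert net1.adjacency[1, 3] == 0.0

    def test_density_matches_requested_within_rounding(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 16))
            cm = random_cm(rng, n)
            p = float(rng.uniform(0.1, 0.9))
            net = C.threshold_proportional(cm, p)
            m = n * (n - 1) // 2
            assert net.n_edges == int(np.floor(p * m + 0.5))

    def test_matches_brute_force_sort_oracle(self, rng):
        for _ in range(10):
            cm = random_cm(rng, 12)
            p = 0.3
            net = C.threshold_proportional(cm, p)
            iu, ju = np.triu_indices(12, 1)
            order = sorted(
                zip(cm.values[iu, ju], iu, ju), key=lambda t: (-t[0], t[1], t[2])
            )
            k = round(p * len(order))
            expected = np.zeros((12, 12))
            for w, i, j in order[:k]:
                expected[i, j] = expected[j, i] = 1.0
            assert np.array_equal(net.adjacency, expected)

    def test_degenerate_zero_edges_raises(self, rng):
        cm = random_cm(rng, 10)
        with pytest.raises(ValueError, match="degenerate"):
            C.threshold_proportional(cm, 0.001)

    def test_permutation_equivariance(self, rng):
        cm = random_cm(rng, 9)
        perm = rng.permutation(9)
        pm = C.ConnectivityMatrix(
            values=cm.values[np.ix_(perm, perm)],
            region_labels=[cm.region_labels[i] for i in perm],
        )
        a = C.threshold_proportional(cm, 0.4).adjacency
        b = C.threshold_proportional(pm, 0.4).adjacency
        assert np.array_equal(a[np.ix_(perm, perm)], b)


class TestSweep:
    def test_default_absolute_has_12_thresholds(self):
        sweep = C.make_sweep("absolute", 0.10, 0.65, 0.05)
        assert len(sweep.thresholds) == 12
        assert sweep.thresholds[0] == pytest.approx(0.10)
        assert sweep.thresholds[-1] == pytest.approx(0.65)

    def test_default_proportional_has_9_thresholds(self):
        sweep = C.make_sweep("proportional", 0.25, 0.65, 0.05)
        assert len(sweep.thresholds) == 9

    def test_single_threshold(self):
        assert C.make_sweep("absolute", 0.3, 0.3, 0.05).thresholds == [0.3]

    def test_non_multiple_span_raises(self):
        with pytest.raises(ValueError, match="integer multiple"):
            C.make_sweep("absolute", 0.1, 0.33, 0.05)


class TestComponents:
    def test_complete_graph_one_component(self, k4):
        assert C.count_components(k4) == 1

    def test_empty_graph_n_components(self):
        assert C.count_components(make_net(np.zeros((7, 7)))) == 7

    def test_two_disjoint_triangles(self, two_triangles):
        assert C.count_components(two_triangles) == 2


class TestSweepDiagnostics:
    def test_connected_cohort_no_flags(self, rng):
        mats = []
        for _ in range(4):
            m = rng.uniform(0.7, 0.95, (8, 8))
            m = np.triu(m, 1)
            m = m + m.T
            mats.append(C.ConnectivityMatrix(m, [f"r{i}" for i in range(8)]))
        diag = C.validate_sweep_bounds(mats, C.make_sweep("absolute", 0.1, 0.3, 0.05))
        assert not diag["flagged"].any()
        assert diag["all_connected"].all()

    def test_threshold_above_max_flags_n_components(self, rng):
        mats = [random_cm(rng, 6)]
        # entries < 1, so t = 1.0 empties the network
        diag = C.validate_sweep_bounds(mats, C.make_sweep("absolute", 1.0, 1.0, 0.05))
        assert diag["flagged"].iloc[0]
        assert diag["mean_components"].iloc[0] == 6

    def test_fragmentation_transition_matches_component_oracle(self, rng):
        import networkx as nx

        mats = [random_cm(rng, 10) for _ in range(3)]
        sweep = C.make_sweep("absolute", 0.2, 0.8, 0.1)
        diag = C.validate_sweep_bounds(mats, sweep)
        for _, row in diag.iterrows():
            counts = []
            for cm in mats:
                net = C.threshold_absolute(cm, row["threshold"])
                g = nx.from_numpy_array(net.adjacency)
                counts.append(nx.number_connected_components(g))
            assert row["mean_components"] == pytest.approx(np.mean(counts))
            assert row["median_components"] == pytest.approx(np.median(counts))


class TestMatrixIO:
    def test_roundtrip(self, rng, tmp_path):
        cm = random_cm(rng, 6)
        C.write_matrix(cm, tmp_path / "m.tsv")
        back = C.read_matrix(tmp_path / "m.tsv")
        assert back.region_labels == cm.region_labels
        assert np.allclose(back.values, cm.values, atol=1e-9)

    def test_edgelist_contents_and_sidecar(self, rng, tmp_path):
        import json

        cm = random_cm(rng, 5)
        net = C.threshold_proportional(cm, 0.5)
        C.write_edgelist(net, tmp_path / "e.tsv")
        df = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(df) == net.n_edges
        assert set(df.columns) == {"region_i", "region_j", "weight"}
        meta = json.loads((tmp_path / "e.tsv.meta.json").read_text())
        assert meta["scheme"] == "proportional"
        assert meta["n_regions"] == 5
        assert meta["density"] == net.density


from hypothesis import given, settings
from hypothesis import strategies as st


class TestThresholdProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n=st.integers(4, 16), p=st.floats(0.05, 1.0), seed=st.integers(0, 10**6))
    def test_proportional_edge_count_formula(self, n, p, seed):
        """Retained edge count always equals round-half-away(p * possible)."""
        rng = np.random.default_rng(seed)
        cm = random_cm(rng, n)
        m = n * (n - 1) // 2
        k = int(np.floor(p * m + 0.5))
        if k == 0:
            with pytest.raises(ValueError):
                C.threshold_proportional(cm, p)
        else:
            assert C.threshold_proportional(cm, p).n_edges == k

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(4, 14),
        t1=st.floats(0.0, 1.0),
        t2=st.floats(0.0, 1.0),
        seed=st.integers(0, 10**6),
    )
    def test_absolute_threshold_monotonicity(self, n, t1, t2, seed):
        """A higher cutoff never keeps more edges."""
        lo, hi = min(t1, t2), max(t1, t2)
        rng = np.random.default_rng(seed)
        cm = random_cm(rng, n)
        assert (
            C.threshold_absolute(cm, hi).n_edges
            <= C.threshold_absolute(cm, lo).n_edges
        )
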