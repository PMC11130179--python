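"""Deconvolution, neuron events, functional graphs, clusters, and CC."""

import itertools

import numpy as np
import pytest
from scipy.signal import lfilter

from glioscope import ensembles as en
from glioscope import synth
from glioscope.ensembles import ClusterSet, CorrelationGraph


def ar1(spikes, gamma):
    return lfilter([1.0], [1.0, -gamma], spikes)


class TestDeconvolve:
    def test_zero_trace_zero_output(self):
        assert not en.deconvolve(np.zeros(100), 0.9).any()

    def test_single_spike_exact_inversion(self):
        s = np.zeros(200); s[50] = 1.2
        out = en.deconvolve(ar1(s, 0.85), 0.85, noise_sd=0.0)
        np.testing.assert_array_equal(np.flatnonzero(out), [50])
        assert out[50] == pytest.approx(1.2)

    def test_two_spikes_recovered_at_correct_frames(self):
        s = np.zeros(200); s[[60, 80]] = [1.0, 0.7]
        out = en.deconvolve(ar1(s, 0.9), 0.9, noise_sd=0.0)
        np.testing.assert_array_equal(np.flatnonzero(out), [60, 80])

    def test_noiseless_support_recovery_random_spikes(self):
        rng = np.random.default_rng(0)
        for gamma in (0.7, 0.9, 0.95):
            s = np.zeros(500)
            idx = rng.choice(500, size=20, replace=False)
            s[idx] = rng.uniform(0.5, 2.0, 20)
            out = en.deconvolve(ar1(s, gamma), gamma, noise_sd=0.0)
            np.testing.assert_array_equal(np.flatnonzero(out > 1e-9),
                                          np.sort(idx))

    def test_reconvolution_approximates_input(self):
        rng = np.random.default_rng(1)
        s = (rng.random(800) < 0.02) * 1.0
        y = ar1(s, 0.9) + rng.normal(0, 0.1, 800)
        out = en.deconvolve(y, 0.9, noise_sd=0.1)
        resid = y - ar1(out, 0.9)
        assert resid.std() < 2 * 0.1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            en.deconvolve(np.array([1.0, np.nan]), 0.9)
        with pytest.raises(ValueError):
            en.deconvolve(np.zeros(10), 1.0)


class TestNeuronEvents:
    def test_all_zero_row(self):
        events, metrics = en.extract_neuron_events(np.zeros(600), 10.0)
        assert len(events) == 0
        assert metrics == {"ddff_per_min": 0.0, "events_per_sec": 0.0,
                           "mean_amplitude": 0.0}

    def test_planted_poisson_rate_recovered(self):
        """events/s within 10% of the planted rate, averaged over 100 neurons."""
        rng = np.random.default_rng(2)
        fs, dur, lam = 10.0, 300.0, 0.5
        rates = []
        for i in range(100):
            s = (rng.random(int(fs * dur)) < lam / fs) * rng.uniform(
                0.8, 1.2, int(fs * dur))
            y = ar1(s, 0.9) + rng.normal(0, 0.05, len(s))
            ddff = en.deconvolve(y, 0.9, noise_sd=0.05)
            _, m = en.extract_neuron_events(ddff, fs)
            rates.append(m["events_per_sec"])
        assert np.mean(rates) == pytest.approx(lam, rel=0.10)

    def test_amplitude_scales_rate_does_not(self):
        rng = np.random.default_rng(3)
        s = (rng.random(3000) < 0.03) * 1.0
        ddff = en.deconvolve(ar1(s, 0.9) + rng.normal(0, 0.05, 3000), 0.9, 0.05)
        _, m1 = en.extract_neuron_events(ddff, 10.0)
        _, m2 = en.extract_neuron_events(2 * ddff, 10.0)
        assert m2["mean_amplitude"] == pytest.approx(2 * m1["mean_amplitude"])
        assert m2["events_per_sec"] == m1["events_per_sec"]
        assert m2["ddff_per_min"] == pytest.approx(2 * m1["ddff_per_min"])


class TestCorrelationGraph:
    def test_identical_traces_weight_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        g = en.correlation_graph(np.stack([x, x, rng.normal(size=200)]))
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(g.weights) == 0)

    def test_independent_traces_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 2000))
        g = en.correlation_graph(x)
        off = g.weights[np.triu_indices(10, k=1)]
        assert off.max() < 3.0 / np.sqrt(2000) + 0.02

    def test_anticorrelated_pair_clipped_to_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        g = en.correlation_graph(np.stack([x, -x, rng.normal(size=200)]))
        assert g.weights[0, 1] == 0.0

    def test_zero_variance_neuron_warns(self):
        rng = np.random.default_rng(3)
        mat = np.vstack([np.zeros(200), rng.normal(size=(2, 200))])
        with pytest.warns(UserWarning, match="zero-variance"):
            g = en.correlation_graph(mat)
        assert np.all(g.weights[0] == 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="100"):
            en.correlation_graph(np.random.default_rng(0).normal(size=(4, 50)))


def brute_force_best_cohesiveness(w, penalty=2.0):
    n = w.shape[0]
    best, best_f = None, -1.0
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            f = en.cohesiveness(w, sub, penalty)
            if f > best_f:
                best_f, best = f, set(sub)
    return best, best_f


class TestClusterDetection:
    def test_two_isolated_nodes_yield_empty_set(self):
        g = CorrelationGraph(weights=np.zeros((2, 2)))
        assert len(en.detect_clusters(g)) == 0

    def test_min_size_enforced(self):
        w = np.zeros((4, 4)); w[0, 1] = w[1, 0] = 0.9
        assert len(en.detect_clusters(CorrelationGraph(weights=w))) == 0
        with pytest.raises(ValueError):
            ClusterSet(clusters=[{0, 1}])

    def test_three_planted_near_cliques_recovered(self):
        rng = np.random.default_rng(5)
        n = 36
        w = rng.uniform(0.0, 0.1, (n, n))
        for c in range(3):
            blk = slice(c * 12, (c + 1) * 12)
            w[blk, blk] = rng.uniform(0.8, 1.0, (12, 12))
        w = np.triu(w, 1); w = w + w.T
        clusters = en.detect_clusters(CorrelationGraph(weights=np.clip(w, 0, 1)))
        assert len(clusters) == 3
        planted = [frozenset(range(c * 12, (c + 1) * 12)) for c in range(3)]
        for p in planted:
            overlap = max(len(p & c) / len(p | c) for c in clusters)
            assert overlap >= 0.9

    def test_complete_uniform_graph_is_one_cluster(self):
        w = np.ones((5, 5)) - np.eye(5)
        clusters = en.detect_clusters(CorrelationGraph(weights=w))
        assert [sorted(c) for c in clusters] == [[0, 1, 2, 3, 4]]

    def test_greedy_matches_exhaustive_best_cohesiveness(self):
        """On small random graphs the best detected cluster attains the
        globally maximal cohesiveness found by enumerating all subsets."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 9))
            w = rng.random((n, n)); w = np.triu(w, 1); w = w + w.T
            _, best_f = brute_force_best_cohesiveness(w)
            clusters = en.detect_clusters(CorrelationGraph(weights=w),
                                          density_threshold=0.0)
            found = max(en.cohesiveness(w, c) for c in clusters)
            assert found == pytest.approx(best_f, abs=1e-9)

    def test_empty_graph(self):
        assert len(en.detect_clusters(CorrelationGraph(weights=np.zeros((0, 0))))) == 0


def brute_force_cc(w):
    n = w.shape[0]
    if n == 0 or w.max() == 0:
        return np.zeros(n)
    wh = (w / w.max()) ** (1.0 / 3.0)
    cc = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(w[i] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j != i and l != i and j != l:
                    total += wh[i, j] * wh[j, l] * wh[i, l]
        cc[i] = total / (k * (k - 1))
    return cc


class TestClusteringCoefficient:
    def test_binary_triangle_is_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(
            en.clustering_coefficient(CorrelationGraph(weights=w)), 1.0)

    def test_star_graph_is_zero(self):
        w = np.zeros((5, 5)); w[0, 1:] = w[1:, 0] = 0.8
        np.testing.assert_allclose(
            en.clustering_coefficient(CorrelationGraph(weights=w)), 0.0)

    def test_matches_exhaustive_triangle_enumeration(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 11))
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            w = np.triu(w, 1); w = w + w.T
            g = CorrelationGraph(weights=w)
            np.testing.assert_allclose(en.clustering_coefficient(g),
                                       brute_force_cc(w), atol=1e-12)

    def test_equal_weights_reduce_to_unweighted_cc(self):
        rng = np.random.default_rng(7)
        adj = (rng.random((8, 8)) < 0.5)
        adj = np.triu(adj, 1); adj = adj | adj.T
        w = 0.42 * adj.astype(float)
        got = en.clustering_coefficient(CorrelationGraph(weights=w))
        # unweighted CC: triangles through i / (k_i (k_i - 1) / 2), halved pairs
        a = adj.astype(float)
        tri = np.diagonal(a @ a @ a)
        k = a.sum(axis=1)
        expected = np.where(k >= 2, tri / np.maximum(k * (k - 1), 1), 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPlantedEnsemblePipeline:
    def pop_spec(self, seed, coactivation=0.9, noise_sd=0.1):
        return synth.PopulationSpec(
            n_neurons=40, n_clusters=2, cluster_sizes=[10, 10],
            within_cluster_coactivation_prob=coactivation,
            background_rate=0.1, ar_decay=0.9, transient_amplitude=1.0,
            noise_sd=noise_sd, frame_rate_hz=10.0, duration_s=200.0, seed=seed)

    def run(self, seed, **kw):
        dff, _, memberships, _ = synth.generate_population(self.pop_spec(seed, **kw))
        ddff = en.deconvolve_matrix(dff, 0.9, noise_sd=0.1)
        graph = en.correlation_graph(ddff)
        return graph, memberships

    def test_planted_clusters_recovered_with_high_jaccard(self):
        jaccards = []
        for seed in range(5):
            graph, memberships = self.run(seed)
            clusters = en.detect_clusters(graph)
            for planted in memberships:
                p = frozenset(planted)
                best = max((len(p & c) / len(p | c) for c in clusters),
                           default=0.0)
                jaccards.append(best)
        assert np.mean(jaccards) >= 0.8

    def test_cluster_members_have_higher_cc_than_background(self):
        wins = 0
        for seed in range(20):
            graph, memberships = self.run(seed)
            cc = en.clustering_coefficient(graph)
            members = sorted(set().union(*memberships))
            background = sorted(set(range(40)) - set(members))
            if cc[members].mean() > cc[background].mean():
                wins += 1
        assert wins >= 18


class TestAssembleGroups:
    def tables(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        t1 = pd.DataFrame({"ddff_per_min": rng.random(40)})
        t2 = pd.DataFrame({"ddff_per_min": rng.random(100)})
        return {"g1": [t1, t2]}

    def test_equal_per_recording_draw(self):
        out = en.assemble_groups(self.tables(), n_per_group=80, seed=0)
        counts = out.groupby("recording").size()
        assert counts[0] == counts[1] == 40

    def test_seeded_determinism(self):
        a = en.assemble_groups(self.tables(), n_per_group=50, seed=3)
        b = en.assemble_groups(self.tables(), n_per_group=50, seed=3)
        assert a.equals(b)

    def test_pool_smaller_than_request_uses_all_without_duplication(self):
        with pytest.warns(UserWarning, match="smaller"):
            out = en.assemble_groups(self.tables(), n_per_group=200, seed=0)
        assert len(out) == 80
        assert out.index.is_unique
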