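"""Graph metrics against independent brute-force oracles, thresholding
invariants, and surrogate normalization behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sedanet as sn
from sedanet.graphs import (
    DEFAULT_DENSITIES,
    ThresholdedGraph,
    metrics_at_density,
    phase_randomize,
)
from sedanet.spectral import BANDS


def random_symmetric(n: int, rng: np.random.Generator, density: float = 1.0) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2
    m[rng.random((n, n)) > density] = 0
    m = np.triu(m, 1)
    m = m + m.T
    return m


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Triple-loop Onnela clustering with max-weight rescaling."""
    n = w.shape[0]
    w_hat = w / w.max()
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall_mean(w: np.ndarray) -> float:
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[w > 0] = 1.0 / w[w > 0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = ~np.eye(n, dtype=bool)
    vals = dist[off]
    return float(vals[np.isfinite(vals)].mean())


def modularity_oracle(w: np.ndarray, labels) -> float:
    """Newman weighted modularity, Q = sum_m (e_mm - a_m^2)."""
    labels = np.asarray(labels)
    total = w.sum()  # counts both directions
    q = 0.0
    for m in np.unique(labels):
        mask = labels == m
        e_mm = w[np.ix_(mask, mask)].sum() / total
        a_m = w[mask].sum() / total
        q += e_mm - a_m**2
    return q


def best_partition_exhaustive(w: np.ndarray) -> float:
    """Maximum modularity over all partitions (Bell-number enumeration)."""
    n = w.shape[0]

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for m, block in enumerate(part):
            labels[block] = m
        best = max(best, modularity_oracle(w, labels))
    return best


def participation_oracle(w: np.ndarray, labels) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = w[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(labels):
            acc += (w[i, np.asarray(labels) == m].sum() / k) ** 2
        out[i] = 1 - acc
    return out


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

class TestThresholdProportional:
    def test_91_channel_edge_count_at_10_percent(self, rng):
        m = random_symmetric(91, rng)
        g = sn.threshold_proportional(m, 0.10)
        assert g.n_edges == 410  # round-half-up of 0.10 * 4095

    def test_full_density_preserves_matrix(self, rng):
        m = random_symmetric(8, rng)
        g = sn.threshold_proportional(m, 1.0)
        assert np.allclose(g.adjacency, m)

    def test_keeps_three_largest_of_five(self):
        m = np.zeros((5, 5))
        entries = {(0, 1): 0.9, (0, 2): 0.7, (1, 3): 0.5, (2, 4): 0.3, (3, 4): 0.1}
        for (i, j), v in entries.items():
            m[i, j] = m[j, i] = v
        g = sn.threshold_proportional(m, 3 / 10)
        kept = {tuple(sorted(e)) for e in zip(*np.nonzero(np.triu(g.adjacency)))}
        assert kept == {(0, 1), (0, 2), (1, 3)}

    def test_rejects_nonpositive_density(self, rng):
        with pytest.raises(ValueError):
            sn.threshold_proportional(random_symmetric(4, rng), -0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.45))
    def test_edge_sets_nest_across_densities(self, seed, d_low):
        rng = np.random.default_rng(seed)
        m = random_symmetric(10, rng)
        lo = sn.threshold_proportional(m, d_low)
        hi = sn.threshold_proportional(m, min(d_low + 0.3, 1.0))
        lo_edges = set(zip(*np.nonzero(np.triu(lo.adjacency))))
        hi_edges = set(zip(*np.nonzero(np.triu(hi.adjacency))))
        assert lo_edges <= hi_edges


# ---------------------------------------------------------------------------
# metrics vs oracles
# ---------------------------------------------------------------------------

class TestClusteringCoefficient:
    def test_triangle_is_fully_clustered(self):
        w = np.ones((3, 3)) - np.eye(3)
        c, mean = sn.clustering_coefficient(ThresholdedGraph(w, 1.0))
        assert np.allclose(c, 1.0) and mean == 1.0

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        c, mean = sn.clustering_coefficient(ThresholdedGraph(w, 1.0))
        assert np.allclose(c, 0.0)

    def test_matches_bruteforce_on_random_graph(self, rng):
        w = random_symmetric(8, rng, density=0.6)
        c, _ = sn.clustering_coefficient(ThresholdedGraph(w, 1.0))
        assert np.allclose(c, clustering_oracle(w), atol=1e-12)


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        w = np.ones((5, 5)) - np.eye(5)
        L, unreach = sn.characteristic_path_length(ThresholdedGraph(w, 1.0))
        assert L == 1.0 and unreach == 0

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        L, _ = sn.characteristic_path_length(ThresholdedGraph(w, 1.0))
        assert L == pytest.approx(4 / 3)

    def test_matches_floyd_warshall(self, rng):
        w = random_symmetric(10, rng, density=0.4)
        L, _ = sn.characteristic_path_length(ThresholdedGraph(w, 1.0))
        assert L == pytest.approx(floyd_warshall_mean(w), abs=1e-12)

    def test_unreachable_pairs_counted(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        L, unreach = sn.characteristic_path_length(ThresholdedGraph(w, 1.0))
        assert L == 1.0 and unreach == 8


class TestLouvain:
    def test_two_cliques_recovered_with_q_half(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 1.0
        labels, q = sn.louvain_partition(ThresholdedGraph(w, 1.0), reps=10, seed=0)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert q == pytest.approx(0.5, abs=1e-9)

    def test_uniform_complete_graph_has_no_structure(self):
        w = np.ones((6, 6)) - np.eye(6)
        _, q = sn.louvain_partition(ThresholdedGraph(w, 1.0), reps=10, seed=0)
        assert q <= 1e-9

    def test_best_q_matches_exhaustive_search(self, rng):
        w = random_symmetric(7, rng, density=0.5)
        labels, _ = sn.louvain_partition(ThresholdedGraph(w, 1.0), reps=20, seed=1)
        q_found = modularity_oracle(w, labels)
        q_best = best_partition_exhaustive(w)
        assert q_found == pytest.approx(q_best, abs=1e-9)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            sn.louvain_partition(ThresholdedGraph(np.zeros((4, 4)), 1.0))


class TestParticipation:
    def test_all_strength_within_module_is_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        p, _ = sn.participation_coefficients(
            ThresholdedGraph(w, 1.0), [0, 0, 1, 1]
        )
        assert np.allclose(p, 0.0)

    def test_equal_split_over_two_modules(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        p, _ = sn.participation_coefficients(
            ThresholdedGraph(w, 1.0), [0, 0, 1]
        )
        assert p[0] == pytest.approx(0.5)

    def test_matches_bruteforce(self, rng):
        w = random_symmetric(9, rng, density=0.5)
        labels = rng.integers(0, 3, size=9)
        p, sd = sn.participation_coefficients(ThresholdedGraph(w, 1.0), labels)
        expected = participation_oracle(w, labels)
        assert np.allclose(p, expected, atol=1e-12)
        assert sd == pytest.approx(expected.std(), abs=1e-12)


class TestSmallWorldness:
    @pytest.mark.parametrize("c,l,expected", [(1.0, 1.0, 1.0), (2.0, 1.0, 2.0)])
    def test_exact_ratio(self, c, l, expected):
        assert sn.small_worldness(c, l) == expected

    def test_nonpositive_inputs_are_missing(self):
        assert np.isnan(sn.small_worldness(-0.5, 1.0))
        assert np.isnan(sn.small_worldness(1.0, 0.0))

    def test_lattice_with_shortcuts_is_small_world(self, rng):
        # Watts-Strogatz-style construction vs degree-matched random graphs
        n = 24
        w = np.zeros((n, n))
        for i in range(n):
            for s in (1, 2):
                w[i, (i + s) % n] = w[(i + s) % n, i] = 1.0
        for _ in range(4):
            i, j = rng.integers(0, n, 2)
            if i != j:
                w[i, j] = w[j, i] = 1.0
        g = ThresholdedGraph(w, 1.0)
        _, c_obs = sn.clustering_coefficient(g)
        l_obs, _ = sn.characteristic_path_length(g)
        c_null, l_null = [], []
        n_edges = int(np.count_nonzero(np.triu(w)))
        for k in range(20):
            null = sn.threshold_proportional(
                random_symmetric(n, np.random.default_rng(k)),
                n_edges / (n * (n - 1) / 2),
            )
            null.adjacency[null.adjacency > 0] = 1.0
            _, cm = sn.clustering_coefficient(null)
            lm, _ = sn.characteristic_path_length(null)
            c_null.append(cm)
            l_null.append(lm)
        sw = sn.small_worldness(
            c_obs / np.mean(c_null), l_obs / np.mean(l_null)
        )
        assert sw > 1.0


class TestDensitySweep:
    def test_default_grid_has_17_levels(self):
        assert len(DEFAULT_DENSITIES) == 17
        assert DEFAULT_DENSITIES[0] == 0.10 and DEFAULT_DENSITIES[-1] == 0.50
        assert np.allclose(np.diff(DEFAULT_DENSITIES), 0.025)

    def test_constant_metric_summary(self, rng):
        m = random_symmetric(12, rng)
        gm = sn.density_sweep(m, np.array([0.3, 0.3, 0.3]), louvain_reps=3, seed=0)
        s = gm.summary()
        assert s["clustering"] == pytest.approx(gm.raw["clustering"][0])

    def test_degree_floor_warning_on_sparse_graph(self, rng):
        m = random_symmetric(40, rng)
        _, _, warns = metrics_at_density(m, 0.05, louvain_reps=2, seed=0)
        assert any("estimability floor" in w for w in warns)

    def test_fragmentation_warning_on_near_empty_matrix(self):
        m = np.zeros((12, 12))
        m[0, 1] = m[1, 0] = 1.0
        m[2, 3] = m[3, 2] = 0.9
        gm = sn.density_sweep(m, np.array([0.1]), louvain_reps=2, seed=0)
        assert any("fragmented" in w for w in gm.warnings)


@pytest.fixture(scope="module")
def noise_tf():
    cfg = sn.SimulationConfig(n_channels=8, n_epochs=12, seed=21)
    ep = sn.baseline_correct(sn.epoch(sn.bandpass(sn.simulate_recording(cfg))))
    return sn.tf_decompose(ep, fmax=20.0)


class TestSurrogateNormalize:
    def test_deterministic_given_seed(self, noise_tf):
        kwargs = dict(
            band=BANDS["alpha"], densities=np.array([0.3]),
            n_surrogates=3, louvain_reps=2, seed=5,
        )
        a = sn.surrogate_normalize(noise_tf, **kwargs)
        b = sn.surrogate_normalize(noise_tf, **kwargs)
        for k in a.raw:
            assert np.array_equal(a.normalized[k], b.normalized[k])

    def test_phase_randomization_preserves_amplitudes(self, noise_tf, rng):
        surr = phase_randomize(noise_tf, rng)
        assert np.allclose(np.abs(surr.coeffs), np.abs(noise_tf.coeffs), atol=1e-5)
        assert not np.allclose(surr.coeffs, noise_tf.coeffs)

    def test_modular_coupling_raises_normalized_clustering(self):
        g, _ = sn.modular_coupling_graph(12)
        cfg = sn.SimulationConfig(
            n_channels=12, n_epochs=12, coupling_graph=g, snr=2.0, seed=3
        )
        ep = sn.baseline_correct(sn.epoch(sn.bandpass(sn.simulate_recording(cfg))))
        tf = sn.tf_decompose(ep, fmax=20.0)
        gm = sn.surrogate_normalize(
            tf, BANDS["alpha"], densities=np.array([0.2, 0.3]),
            n_surrogates=5, louvain_reps=3, seed=9,
        )
        assert np.nanmean(gm.normalized["clustering"]) > 1.0
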