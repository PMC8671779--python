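"""Graph metrics against exhaustive oracles and closed forms."""

import itertools

import numpy as np
import pytest

from eegbiotype import (
    GraphMetrics,
    NetworkFeatures,
    SurrogateEnsemble,
    clustering_coefficient,
    connectivity_strength,
    modulation,
    path_length,
    simulate_structural_matrix,
    small_world,
    structural_metrics,
)


def random_weighted_matrix(n, rng, low=0.05, high=1.0):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(low, high, len(iu[0]))
    return m + m.T


def brute_force_clc(m):
    """Geometric-mean triangle clustering by explicit triple enumeration."""
    n = len(m)
    w = m / m.max()
    vals = []
    for i in range(n):
        k = np.count_nonzero(m[i] > 0) - (1 if m[i, i] > 0 else 0)
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3:
                    acc += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        vals.append(acc / (k * (k - 1)) if k > 1 else 0.0)
    return float(np.mean(vals))


def brute_force_pl(m):
    """Mean shortest 1/weight path by enumerating every simple path."""
    n = len(m)
    total = 0.0
    for i, j in itertools.permutations(range(n), 2):
        best = np.inf
        others = [v for v in range(n) if v not in (i, j)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                nodes = (i, *mid, j)
                cost = sum(
                    1.0 / m[a, b] for a, b in zip(nodes[:-1], nodes[1:])
                )
                best = min(best, cost)
        total += best
    return total / (n * (n - 1))


class TestConnectivityStrength:
    def test_constant_matrix(self):
        m = np.full((5, 5), 0.3)
        np.fill_diagonal(m, 1.0)
        assert connectivity_strength(m) == pytest.approx(0.3)

    def test_zero_and_unit_matrices(self):
        assert connectivity_strength(np.zeros((4, 4))) == 0.0
        assert connectivity_strength(np.ones((4, 4))) == 1.0

    def test_asymmetry_rejected(self):
        m = np.ones((3, 3))
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            connectivity_strength(m)


class TestExhaustiveOracles:
    def test_clc_matches_brute_force_on_small_graphs(self, rng):
        """Weighted clustering equals explicit triangle enumeration on all
        graphs with up to 6 nodes (100 random weight draws)."""
        for draw in range(100):
            n = int(rng.integers(3, 7))
            m = random_weighted_matrix(n, rng)
            assert clustering_coefficient(m) == pytest.approx(
                brute_force_clc(m), abs=1e-10
            )

    def test_pl_matches_exhaustive_path_enumeration(self, rng):
        for draw in range(100):
            n = int(rng.integers(3, 7))
            m = random_weighted_matrix(n, rng)
            assert path_length(m) == pytest.approx(
                brute_force_pl(m), abs=1e-10
            )

    def test_clc_agrees_with_networkx(self, rng):
        import networkx as nx

        for draw in range(10):
            m = random_weighted_matrix(6, rng)
            g = nx.from_numpy_array(m)
            expected = nx.average_clustering(g, weight="weight")
            assert clustering_coefficient(m) == pytest.approx(
                expected, abs=1e-10
            )


class TestClosedForms:
    def test_uniform_complete_graph(self):
        m = np.full((6, 6), 0.4)
        np.fill_diagonal(m, 0.0)
        assert clustering_coefficient(m) == pytest.approx(1.0)
        assert path_length(m) == pytest.approx(1.0 / 0.4)

    def test_pl_homogeneity_under_weight_scaling(self, rng):
        m = random_weighted_matrix(6, rng)
        assert path_length(2.5 * m) == pytest.approx(path_length(m) / 2.5)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            clustering_coefficient(np.ones((2, 2)))

    def test_disconnected_graph_rejected(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            path_length(m)


class TestSmallWorld:
    @pytest.mark.parametrize(
        "clc,pl,expected",
        [(1.005, 1.083, 0.928), (1.005, 1.077, 0.933), (0.996, 1.014, 0.982)],
    )
    def test_published_identities_at_three_decimals(self, clc, pl, expected):
        assert round(small_world(clc, pl), 3) == expected

    def test_equal_inputs_give_one(self):
        assert small_world(0.7, 0.7) == 1.0

    def test_zero_path_length_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            small_world(1.0, 0.0)


class TestModulation:
    def _metrics(self, cs, clc, pl, band="broadband", window="prestimulus"):
        return GraphMetrics(cs=cs, clc=clc, pl=pl, sw=clc / pl, band=band,
                            window=window)

    def test_identical_windows_give_zero(self):
        a = self._metrics(0.3, 1.0, 1.1)
        out = modulation(a, a)
        assert out.cs == out.clc == out.pl == out.sw == 0.0

    def test_sign_convention_decrease_is_negative(self):
        pre = self._metrics(0.3, 1.0, 1.100)
        resp = self._metrics(0.3, 1.0, 1.094, window="response")
        assert modulation(resp, pre).pl == pytest.approx(-0.006)

    def test_band_mismatch_rejected(self):
        pre = self._metrics(0.3, 1.0, 1.1, band="theta")
        resp = self._metrics(0.3, 1.0, 1.1, band="broadband")
        with pytest.raises(ValueError, match="band"):
            modulation(resp, pre)

    def test_sw_modulation_is_definitionally_consistent(self, rng):
        m_pre = random_weighted_matrix(6, rng)
        m_resp = random_weighted_matrix(6, rng, low=0.2)
        nf = NetworkFeatures.from_matrices(
            m_pre, m_resp, band="broadband", normalize=False
        )
        expected = (
            nf.response.clc / nf.response.pl
            - nf.prestimulus.clc / nf.prestimulus.pl
        )
        assert nf.modulation.sw == pytest.approx(expected, abs=1e-12)


class TestSurrogates:
    def test_draws_preserve_symmetry_and_weight_multiset(self, rng):
        m = random_weighted_matrix(8, rng)
        ens = SurrogateEnsemble(n_surrogates=5, seed=3)
        iu = np.triu_indices(8, k=1)
        for s in ens.draws(m):
            np.testing.assert_array_equal(s, s.T)
            np.testing.assert_allclose(
                np.sort(s[iu]), np.sort(m[iu]), atol=1e-12
            )

    def test_self_normalisation_is_near_one(self, rng):
        """Normalising a surrogate draw by its own ensemble gives ~1."""
        m = random_weighted_matrix(12, rng, low=0.05, high=0.95)
        ens = SurrogateEnsemble(n_surrogates=50, seed=7)
        surr = next(ens.draws(m))
        assert clustering_coefficient(
            surr, normalize=True, ensemble=ens
        ) == pytest.approx(1.0, abs=0.05)
        assert path_length(
            surr, normalize=True, ensemble=ens
        ) == pytest.approx(1.0, abs=0.05)

    def test_ring_lattice_beats_degree_matched_random(self):
        """Classic ordering: a weighted ring lattice has higher clustering
        and longer paths than its weight-shuffled counterpart."""
        n = 20
        m = np.full((n, n), 1e-3)
        for i in range(n):
            for d in (1, 2):
                m[i, (i + d) % n] = m[(i + d) % n, i] = 1.0
        np.fill_diagonal(m, 0.0)
        rng = np.random.default_rng(0)
        iu = np.triu_indices(n, k=1)
        r = np.zeros_like(m)
        r[iu] = rng.permutation(m[iu])
        r = r + r.T
        assert clustering_coefficient(m) > clustering_coefficient(r)
        assert path_length(m) > path_length(r)


class TestStructuralMetrics:
    def test_mean_weight_recovered_as_cs(self):
        m = simulate_structural_matrix(20, mean_weight=0.345, seed=4)
        gm = structural_metrics(m, normalize=False)
        assert gm.cs == pytest.approx(0.345, abs=0.02)

    def test_uniform_matrix_closed_form(self):
        m = np.full((8, 8), 0.5)
        np.fill_diagonal(m, 0.0)
        gm = structural_metrics(m, normalize=False)
        assert gm.sw == pytest.approx(gm.clc / gm.pl)
        assert gm.clc == pytest.approx(1.0)
        assert gm.pl == pytest.approx(2.0)

    def test_negative_weights_rejected(self):
        m = np.full((4, 4), -0.1)
        np.fill_diagonal(m, 0.0)
        with pytest.raises(ValueError, match=">= 0"):
            structural_metrics(m)

    def test_sw_identity_holds_for_every_graph(self, rng):
        for _ in range(10):
            m = random_weighted_matrix(7, rng)
            gm = GraphMetrics.from_matrix(m, normalize=False)
            assert gm.sw == pytest.approx(gm.clc / gm.pl, abs=1e-12)
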