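"""The 12 bipartite network-level metrics against hand values and oracles."""

import numpy as np
import pytest

from pollinet import (
    ActiveMatrix,
    MetricsConfig,
    batch_means,
    canonical_matrix,
    connectance,
    linkage_density,
    links_per_species,
    modularity,
    nestedness_temperature,
    network_level,
    nodf,
    robustness,
    web_asymmetry,
    weighted_nestedness,
)
from pollinet.metrics import METRIC_NAMES, MetricsRecord, barber_q

from _oracles import (
    entropy_linkage_density,
    max_modularity_enumeration,
    nodf_loops,
    robustness_exact,
)


def random_active(rng, max_side=8, p=0.5):
    """Random binary matrix guaranteed to have no empty rows/columns."""
    while True:
        P = int(rng.integers(2, max_side + 1))
        A = int(rng.integers(2, max_side + 1))
        m = (rng.random((P, A)) < p).astype(np.int8)
        if m.any(axis=1).all() and m.any(axis=0).all():
            return m


class TestSimpleRatios:
    def test_connectance(self, rng):
        assert connectance(canonical_matrix("complete", 3, 4)) == 1.0
        assert connectance(np.eye(2, dtype=np.int8)) == 0.5
        m = random_active(rng)
        assert connectance(m) == pytest.approx(m.sum() / m.size)

    def test_web_asymmetry(self):
        assert web_asymmetry(canonical_matrix("complete", 3, 3)) == 0.0
        assert web_asymmetry(np.ones((3, 1), dtype=np.int8)) == -0.5
        assert web_asymmetry(np.ones((1, 3), dtype=np.int8)) == 0.5

    def test_links_per_species(self):
        assert links_per_species(np.eye(2, dtype=np.int8)) == 0.5
        assert links_per_species(canonical_matrix("complete", 2, 2)) == 1.0
        assert links_per_species(np.ones((1, 1), dtype=np.int8)) == 0.5


class TestLinkageDensity:
    def test_hand_values(self):
        assert linkage_density(canonical_matrix("complete", 2, 2)) == pytest.approx(2.0)
        assert linkage_density(np.eye(2, dtype=np.int8)) == pytest.approx(1.0)

    def test_matches_entropy_oracle(self, rng):
        for _ in range(20):
            m = random_active(rng)
            assert linkage_density(m) == pytest.approx(entropy_linkage_density(m))


class TestNodf:
    def test_stair_is_fully_nested(self):
        assert nodf(canonical_matrix("stair", 3, 3)) == pytest.approx(100.0)

    def test_identity_has_no_nested_pairs(self):
        assert nodf(np.eye(2, dtype=np.int8)) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            m = random_active(rng, max_side=10)
            assert nodf(m) == pytest.approx(nodf_loops(m))

    def test_stairs_of_any_size(self):
        for n in range(2, 7):
            assert nodf(canonical_matrix("stair", n, n)) == pytest.approx(100.0)


class TestWeightedNestedness:
    def test_stair_and_identity(self):
        assert weighted_nestedness(canonical_matrix("stair", 3, 3)) == pytest.approx(100.0)
        assert weighted_nestedness(np.eye(2, dtype=np.int8)) == 0.0

    def test_reduces_to_nodf_on_binary(self, rng):
        """On 0/1 data the tie rule makes the weighted variant coincide
        with plain NODF (documented equivalence)."""
        for _ in range(15):
            m = random_active(rng)
            assert weighted_nestedness(m) == pytest.approx(nodf(m))


class TestTemperature:
    def test_perfectly_nested_is_cold(self):
        for n in range(2, 7):
            assert nestedness_temperature(canonical_matrix("stair", n, n)) == 0.0

    def test_antidiagonal_hotter_than_stair(self):
        t_anti = nestedness_temperature(canonical_matrix("antidiagonal", 4, 4))
        t_stair = nestedness_temperature(canonical_matrix("stair", 4, 4))
        assert t_anti > t_stair

    def test_permutation_invariance(self, rng):
        for _ in range(10):
            m = random_active(rng, max_side=7)
            t0 = nestedness_temperature(m)
            perm = m[rng.permutation(m.shape[0])][:, rng.permutation(m.shape[1])]
            assert nestedness_temperature(perm) == pytest.approx(t0)

    def test_bounds(self, rng):
        for _ in range(20):
            t = nestedness_temperature(random_active(rng))
            assert 0.0 <= t <= 100.0


class TestModularity:
    def test_two_blocks(self):
        q, (row_lab, col_lab) = modularity(canonical_matrix("block2", 4, 4), seed=0)
        assert q == pytest.approx(0.5)
        # the two blocks land in different modules
        assert row_lab[0] == row_lab[1] != row_lab[2] == row_lab[3]

    def test_complete_graph_single_module(self):
        q, _ = modularity(canonical_matrix("complete", 3, 3), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_small_matrices(self, rng):
        """The label-propagation heuristic finds the exhaustive optimum on
        every fuzzed matrix with at most 8 species."""
        for _ in range(12):
            while True:
                P = int(rng.integers(2, 5))
                A = int(rng.integers(2, 9 - P))
                m = (rng.random((P, A)) < 0.5).astype(np.int8)
                if m.any(axis=1).all() and m.any(axis=0).all():
                    break
            q, _ = modularity(m, seed=1, restarts=10)
            assert q == pytest.approx(max_modularity_enumeration(m), abs=1e-9)

    def test_partition_q_consistency(self, rng):
        m = random_active(rng, max_side=6)
        q, (row_lab, col_lab) = modularity(m, seed=0)
        assert barber_q(m, row_lab, col_lab) == pytest.approx(q)

    def test_deterministic_given_seed(self, rng):
        m = random_active(rng)
        assert modularity(m, seed=5)[0] == modularity(m, seed=5)[0]


class TestRobustness:
    def test_single_link_hand_trapezoid(self):
        m = np.ones((1, 1), dtype=np.int8)
        assert robustness(m, "HL", "random", reps=3, seed=0) == pytest.approx(0.5)
        assert robustness(m, "LL", "degree_asc") == pytest.approx(0.5)

    @pytest.mark.parametrize("P,A", [(2, 2), (3, 4), (5, 2)])
    def test_complete_closed_form(self, P, A):
        m = canonical_matrix("complete", P, A)
        for level, S in (("HL", A), ("LL", P)):
            expected = 1.0 - 1.0 / (2 * S)
            assert robustness(m, level, "random", reps=5, seed=0) == pytest.approx(expected)
            assert robustness(m, level, "degree_desc") == pytest.approx(expected)

    def test_monte_carlo_matches_exact_expectation(self, rng):
        """Random-order robustness agrees with the exhaustive S! expectation
        within 3 standard errors on networks with <= 5 removable species."""
        for _ in range(5):
            P = int(rng.integers(2, 5))
            A = int(rng.integers(2, 6))
            m = (rng.random((P, A)) < 0.6).astype(np.int8)
            if not (m.any(axis=1).all() and m.any(axis=0).all()):
                continue
            reps = 200
            got = robustness(m, "HL", "random", reps=reps, seed=7)
            exact_mean, exact_sd = robustness_exact(m)
            se = exact_sd / np.sqrt(reps)
            assert abs(got - exact_mean) <= 3 * se + 1e-12

    def test_degree_order_directions(self, rng):
        m = random_active(rng, max_side=6)
        # removing hubs first can never be gentler than removing rare species first
        assert robustness(m, "HL", "degree_desc") <= robustness(m, "HL", "degree_asc") + 1e-9


class TestNetworkLevel:
    def test_single_link_degeneracies(self):
        rec = network_level(np.ones((1, 1), dtype=np.int8))
        assert rec.connectance == 1.0
        assert rec.nodf is None and rec.nestedness_temperature is None
        assert rec.weighted_nestedness is None
        assert rec.robustness_hl == pytest.approx(0.5)
        assert rec.n_species_hl == 1 and rec.n_species_ll == 1

    def test_consistent_with_individual_operations(self):
        m = canonical_matrix("stair", 3, 3)
        cfg = MetricsConfig(seed=3)
        rec = network_level(m, cfg)
        assert rec.connectance == pytest.approx(connectance(m))
        assert rec.nodf == pytest.approx(nodf(m))
        assert rec.nestedness_temperature == pytest.approx(nestedness_temperature(m))
        assert rec.modularity_q == pytest.approx(modularity(m, seed=3)[0])
        assert rec.linkage_density == pytest.approx(linkage_density(m))

    def test_isolated_species_do_not_change_metrics(self, rng):
        m = random_active(rng)
        padded = np.zeros((m.shape[0] + 2, m.shape[1] + 1), dtype=np.int8)
        padded[: m.shape[0], : m.shape[1]] = m
        cfg = MetricsConfig(seed=0, robustness_reps=20)
        rec_a, rec_b = network_level(m, cfg), network_level(padded, cfg)
        for name in METRIC_NAMES:
            va, vb = getattr(rec_a, name), getattr(rec_b, name)
            if va is None:
                assert vb is None
            else:
                assert vb == pytest.approx(va)
        active = ActiveMatrix.from_links(padded)
        assert active.n_dropped_plants == 2 and active.n_dropped_pollinators == 1

    def test_record_bounds_fuzz(self, rng):
        """MetricsRecord invariants hold across a large fuzz batch."""
        cfg = MetricsConfig(seed=0, robustness_reps=10, modularity_restarts=3)
        for _ in range(300):
            P, A = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            m = (rng.random((P, A)) < rng.uniform(0.2, 0.9)).astype(np.int8)
            if not m.any():
                continue
            rec = network_level(m, cfg)
            assert 0.0 <= rec.connectance <= 1.0
            assert -1.0 <= rec.web_asymmetry <= 1.0
            if rec.nodf is not None:
                assert 0.0 <= rec.nodf <= 100.0
            if rec.nestedness_temperature is not None:
                assert 0.0 <= rec.nestedness_temperature <= 100.0
            for level in (rec.robustness_hl, rec.robustness_ll):
                if level is not None:
                    assert 0.0 <= level <= 1.0
            assert rec.n_species_hl >= 0 and rec.n_species_ll >= 0

    def test_adding_link_never_decreases_connectance(self, rng):
        m = random_active(rng)
        zeros = np.argwhere(m == 0)
        if len(zeros):
            i, j = zeros[rng.integers(len(zeros))]
            m2 = m.copy()
            m2[i, j] = 1
            # same active shape: adding a link to active species
            assert connectance(ActiveMatrix(m2)) >= connectance(ActiveMatrix(m))


class TestBatchMeans:
    def _rec(self, **kwargs):
        base = {name: None for name in METRIC_NAMES}
        base.update(kwargs)
        return MetricsRecord(**base)

    def test_simple_mean(self):
        recs = [self._rec(connectance=0.2), self._rec(connectance=0.4)]
        out = batch_means(recs)
        assert out["connectance"] == {"mean": pytest.approx(0.3), "n": 2}

    def test_not_computable_skipped(self):
        recs = [self._rec(nodf=50.0), self._rec(), self._rec()]
        out = batch_means(recs)
        assert out["nodf"] == {"mean": 50.0, "n": 1}
        assert out["modularity_q"] == {"mean": None, "n": 0}

    def test_matches_loop_oracle(self, rng):
        recs = []
        for _ in range(30):
            m = random_active(rng, max_side=5)
            recs.append(network_level(m, MetricsConfig(robustness_reps=5)))
        out = batch_means(recs)
        for name in METRIC_NAMES:
            values = [getattr(r, name) for r in recs if getattr(r, name) is not None]
            assert out[name]["n"] == len(values)
            if values:
                assert out[name]["mean"] == pytest.approx(sum(values) / len(values))
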