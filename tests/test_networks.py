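"""Half-weight association, interaction matrices and centrality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinnet import (
    DyadCounts,
    DyadicMatrix,
    FocalSample,
    Individual,
    InteractionEvent,
    InvariantError,
    UndefinedDyadError,
    build_association_matrix,
    build_interaction_matrix,
    eigenvector_centrality,
    half_weight_index,
    strength_centrality,
    tabulate_dyad_counts,
)


def brute_force_counts(samples, a, b):
    """Independent tabulation oracle: direct set membership over samples."""
    x = ya = yb = 0
    for s in samples:
        present = s.present_ids
        if a in present and b in present:
            x += 1
        elif a in present:
            ya += 1
        elif b in present:
            yb += 1
    return DyadCounts(X=x, Ya=ya, Yb=yb)


def power_iteration(adj, tol=1e-12, max_iter=100_000):
    """Dominant-eigenvector oracle on a symmetric non-negative matrix.

    Iterates on adj + I (same eigenvectors, shifted spectrum) so bipartite
    structures with a +/- eigenvalue pair of equal magnitude still converge.
    """
    shifted = adj + np.eye(adj.shape[0])
    v = np.ones(adj.shape[0])
    for _ in range(max_iter):
        nxt = shifted @ v
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) < tol:
            break
        v = nxt
    return np.abs(v) / np.abs(v).max()


class TestHalfWeightIndex:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (DyadCounts(X=10, Ya=0, Yb=0), 1.0),
            (DyadCounts(X=0, Ya=4, Yb=6), 0.0),
            (DyadCounts(X=5, Ya=3, Yb=1), 5 / 7),
            (DyadCounts(X=3, Ya=1, Yb=1, Yab=2), 3 / 6),
        ],
    )
    def test_printed_formula(self, counts, expected):
        assert half_weight_index(counts) == pytest.approx(expected)

    def test_all_zero_counts_is_undefined_not_imputed(self):
        with pytest.raises(UndefinedDyadError):
            half_weight_index(DyadCounts(X=0, Ya=0, Yb=0))

    @given(
        x=st.integers(0, 50), ya=st.integers(0, 50),
        yb=st.integers(0, 50), yab=st.integers(0, 50),
        k=st.integers(2, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_scale_consistency_and_range(self, x, ya, yb, yab, k):
        """Doubling all counts leaves the index unchanged; index is in [0, 1]
        and monotone in X."""
        c = DyadCounts(X=x, Ya=ya, Yb=yb, Yab=yab)
        if c.total == 0:
            return
        h = half_weight_index(c)
        assert 0.0 <= h <= 1.0
        scaled = DyadCounts(X=k * x, Ya=k * ya, Yb=k * yb, Yab=k * yab)
        assert half_weight_index(scaled) == pytest.approx(h)
        bumped = DyadCounts(X=x + 1, Ya=ya, Yb=yb, Yab=yab)
        assert half_weight_index(bumped) > h or h == 1.0


class TestTabulation:
    def test_hand_counts_on_fixture(self, small_samples, small_roster):
        counts = tabulate_dyad_counts(small_samples, small_roster)
        # A appears in s1,s2,s5; B in s1,s2,s3; D in s2,s4,s5; C in s4,s6
        assert counts[("A", "B")] == DyadCounts(X=2, Ya=1, Yb=1)
        assert counts[("A", "D")] == DyadCounts(X=2, Ya=1, Yb=1)
        assert counts[("C", "D")] == DyadCounts(X=1, Ya=1, Yb=2)
        assert counts[("B", "C")] == DyadCounts(X=0, Ya=3, Yb=2)

    def test_neighbor_neighbor_cooccurrence_counts(self, small_roster):
        sample = FocalSample("s1", "A", frozenset({"B", "C"}))
        counts = tabulate_dyad_counts([sample], small_roster)
        for dyad in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert counts[dyad].X == 1

    def test_focal_plus_empty_neighbor_sample(self, small_roster):
        samples = [
            FocalSample("s1", "A", frozenset({"B"})),
            FocalSample("s2", "B", frozenset()),
        ]
        counts = tabulate_dyad_counts(samples, small_roster)
        assert counts[("A", "B")] == DyadCounts(X=1, Ya=0, Yb=1)

    def test_empty_sample_set_rejected(self, small_roster):
        with pytest.raises(InvariantError):
            tabulate_dyad_counts([], small_roster)


class TestAssociationMatrix:
    def test_matches_per_dyad_oracle(self, rng):
        roster = [
            Individual(f"I{k}", "F", "adult", "G1", 2003) for k in range(5)
        ]
        ids = [r.id for r in roster]
        samples = []
        for s in range(40):
            focal, *nbrs = rng.permutation(ids)[: rng.integers(1, 5)]
            samples.append(FocalSample(f"s{s}", focal, frozenset(nbrs)))
        matrix = build_association_matrix(samples, roster)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                expected = half_weight_index(brute_force_counts(samples, a, b))
                assert matrix.value(a, b) == pytest.approx(expected)

    def test_sample_order_invariance(self, small_samples, small_roster):
        m1 = build_association_matrix(small_samples, small_roster)
        m2 = build_association_matrix(small_samples[::-1], small_roster)
        assert np.array_equal(m1.values, m2.values)

    def test_everyone_always_together_gives_all_ones(self, small_roster):
        ids = [r.id for r in small_roster]
        samples = [
            FocalSample(f"s{k}", ids[k % 4], frozenset(set(ids) - {ids[k % 4]}))
            for k in range(8)
        ]
        m = build_association_matrix(samples, small_roster)
        off = ~np.eye(m.n, dtype=bool)
        assert np.all(m.values[off] == 1.0)

    def test_never_observed_individual_flagged_undefined(self, small_roster):
        samples = [FocalSample("s1", "A", frozenset({"B"}))]
        m = build_association_matrix(samples, small_roster)
        undefined = set(m.undefined_dyads())
        # C and D never observed: every dyad involving them is undefined
        assert {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")} == undefined

    def test_relabeling_isomorphism(self, rng):
        """Renaming all individuals permutes the matrix but preserves values."""
        roster = [Individual(f"I{k}", "F", "adult", "G1", 2003) for k in range(4)]
        samples = []
        for s in range(30):
            ids = [r.id for r in roster]
            focal, *nbrs = rng.permutation(ids)[: rng.integers(1, 4)]
            samples.append(FocalSample(f"s{s}", focal, frozenset(nbrs)))
        mapping = {"I0": "Z9", "I1": "Z1", "I2": "Z5", "I3": "Z0"}
        roster2 = [
            Individual(mapping[r.id], r.sex, r.age_class, r.group_id, r.year)
            for r in roster
        ]
        samples2 = [
            FocalSample(s.sample_id, mapping[s.focal_id],
                        frozenset(mapping[n] for n in s.neighbor_ids))
            for s in samples
        ]
        m1 = build_association_matrix(samples, roster)
        m2 = build_association_matrix(samples2, roster2)
        for i, a in enumerate(m1.ids):
            for b in m1.ids[i + 1:]:
                assert m2.value(mapping[a], mapping[b]) == pytest.approx(
                    m1.value(a, b)
                )


class TestInteractionMatrix:
    def test_directed_groom_counts(self, small_roster):
        events = [InteractionEvent("A", "B", "groom")] * 3 + [
            InteractionEvent("B", "A", "groom")
        ]
        m = build_interaction_matrix(events, small_roster, "groom")
        assert m.value("A", "B") == 3
        assert m.value("B", "A") == 1

    def test_mutual_groom_increments_both_directions(self, small_roster):
        m = build_interaction_matrix(
            [InteractionEvent("A", "B", "mutual_groom")], small_roster, "groom"
        )
        assert m.value("A", "B") == 1
        assert m.value("B", "A") == 1

    def test_aggression_oriented_winner_to_loser(self, small_roster):
        events = [InteractionEvent("A", "B", "aggression", winner_id="B")]
        m = build_interaction_matrix(events, small_roster, "aggression")
        assert m.value("B", "A") == 1
        assert m.value("A", "B") == 0

    def test_empty_events_all_zero(self, small_roster):
        m = build_interaction_matrix([], small_roster, "groom")
        assert not m.values.any()


class TestStrengthCentrality:
    def test_row_and_column_sums(self):
        vals = np.zeros((3, 3))
        vals[0, 1], vals[0, 2] = 3, 2
        m = DyadicMatrix(["A", "B", "C"], vals, directed=True)
        out = strength_centrality(m, "out")
        ins = strength_centrality(m, "in")
        assert out["A"]["raw"] == 5
        assert ins["A"]["raw"] == 0
        assert out["A"]["normalized"] == pytest.approx(2.5)

    def test_in_and_out_totals_conserved(self, rng):
        vals = rng.integers(0, 5, (6, 6)).astype(float)
        m = DyadicMatrix([f"n{i}" for i in range(6)], vals, directed=True)
        ins = strength_centrality(m, "in")
        outs = strength_centrality(m, "out")
        assert sum(v["raw"] for v in ins.values()) == pytest.approx(
            sum(v["raw"] for v in outs.values())
        )

    def test_single_node_rejected(self):
        m = DyadicMatrix(["A"], np.zeros((1, 1)), directed=True)
        with pytest.raises(InvariantError):
            strength_centrality(m, "in")


class TestEigenvectorCentrality:
    def test_three_cycle_symmetry(self):
        vals = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        m = DyadicMatrix(["a", "b", "c"], vals, directed=False)
        cent = eigenvector_centrality(m)
        assert all(v == pytest.approx(1.0) for v in cent.values())

    def test_star_center_dominates(self):
        vals = np.zeros((4, 4))
        vals[0, 1:] = vals[1:, 0] = 1
        m = DyadicMatrix(["hub", "l1", "l2", "l3"], vals, directed=False)
        cent = eigenvector_centrality(m)
        oracle = power_iteration(vals)
        assert cent["hub"] == pytest.approx(1.0)
        assert cent["l1"] == cent["l2"] == cent["l3"]
        for node, val in zip(m.ids, oracle):
            assert cent[node] == pytest.approx(val, abs=1e-10)

    def test_agrees_with_power_iteration_on_random_matrices(self, rng):
        for _ in range(20):
            vals = rng.random((8, 8)) + 0.05  # strictly positive: connected
            m = DyadicMatrix([f"n{i}" for i in range(8)], vals, directed=True)
            cent = eigenvector_centrality(m)
            sym = (m.values + m.values.T) / 2
            np.fill_diagonal(sym, 0)
            oracle = power_iteration(sym)
            diff = max(abs(cent[f"n{i}"] - oracle[i]) for i in range(8))
            assert diff < 1e-8

    def test_disconnected_components_scored_separately(self):
        vals = np.zeros((5, 5))
        vals[0, 1] = vals[1, 0] = 2.0
        vals[2, 3] = vals[3, 2] = 1.0
        m = DyadicMatrix(list("abcde"), vals, directed=False)
        cent = eigenvector_centrality(m)
        assert cent["a"] == cent["b"] == pytest.approx(1.0)
        assert cent["c"] == cent["d"] == pytest.approx(1.0)
        assert cent["e"] == 0.0

    def test_negative_weights_rejected(self):
        vals = np.array([[0, -1, 0], [-1, 0, 0], [0, 0, 0]], dtype=float)
        m = DyadicMatrix(["a", "b", "c"], vals, directed=False)
        with pytest.raises(InvariantError):
            eigenvector_centrality(m)
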