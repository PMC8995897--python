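import numpy as np
import pytest

from infersentppi.annotation import WeightedAnnotationSet
from infersentppi.baselines import (
    aggregate,
    make_term_simfn,
    score_pairs,
    sim_lin,
    sim_pekar,
    sim_resnik,
    sim_wang,
)
from infersentppi.corpus import PairExample
from infersentppi.ontology import compute_ic

from conftest import make_graph, random_dag
import oracles

ROOT, A, B, C = "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"


def _random_annotations(rng, ids, n_proteins=6):
    return {
        f"P{i}": sorted(
            (ids[int(j)], 1) for j in rng.choice(len(ids), size=int(rng.integers(1, 4)), replace=False)
        )
        for i in range(n_proteins)
    }


@pytest.fixture
def annotated_chain(chain_graph):
    # every term annotated once so IC is defined everywhere
    ax = {f"P{i}": [(t, 1)] for i, t in enumerate([ROOT, A, B, C])}
    pgaa = WeightedAnnotationSet(axioms=ax)
    return chain_graph, compute_ic(chain_graph, pgaa)


class TestTermMeasures:
    def test_resnik_self_is_own_ic(self, annotated_chain):
        g, ic = annotated_chain
        assert sim_resnik(g, ic, B, B) == pytest.approx(ic[B])

    def test_resnik_root_only_common_ancestor(self):
        g = make_graph({ROOT: [], A: [(ROOT, "is_a")], B: [(ROOT, "is_a")]})
        ic = compute_ic(g, WeightedAnnotationSet(axioms={"P1": [(A, 1)], "P2": [(B, 1)]}))
        assert sim_resnik(g, ic, A, B) == 0.0

    def test_lin_self_similarity_is_one(self, annotated_chain):
        g, ic = annotated_chain
        assert sim_lin(g, ic, C, C) == pytest.approx(1.0)

    def test_lin_undefined_for_zero_ic(self, annotated_chain):
        g, ic = annotated_chain
        with pytest.raises(ValueError):
            sim_lin(g, ic, ROOT, ROOT)

    def test_pekar_self_below_root_is_one(self, chain_graph):
        assert sim_pekar(chain_graph, B, B) == 1.0

    def test_pekar_depth1_siblings_zero(self):
        g = make_graph({ROOT: [], A: [(ROOT, "is_a")], B: [(ROOT, "is_a")]})
        assert sim_pekar(g, A, B) == 0.0

    def test_pekar_chain_hand_value(self, chain_graph):
        # terms B (depth 2) and C (depth 3); best common ancestor is B:
        # root-to-B longest path 2, B-to-C path 1 -> 2/(2+0+1)
        assert sim_pekar(chain_graph, B, C) == pytest.approx(2 / 3)

    def test_wang_self_is_one(self, chain_graph):
        assert sim_wang(chain_graph, C, C) == pytest.approx(1.0)

    def test_wang_chain_hand_svalues(self):
        g = make_graph({ROOT: [], A: [(ROOT, "is_a")], B: [(A, "is_a")]})
        # S_B = {B:1, A:0.8, root:0.64}, SV=2.44; S_A = {A:1, root:0.8}, SV=1.8
        # shared {A, root}: (0.8+1)+(0.64+0.8) = 3.24; total 4.24
        assert sim_wang(g, B, A) == pytest.approx(3.24 / 4.24)

    def test_wang_disjoint_leaves_positive(self):
        g = make_graph({ROOT: [], A: [(ROOT, "is_a")], B: [(ROOT, "part_of")]})
        assert 0.0 < sim_wang(g, A, B) < 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(5)
        parents = random_dag(rng, 10)
        g = make_graph(parents)
        ids = sorted(parents)
        ax = _random_annotations(rng, ids)
        ic = compute_ic(g, WeightedAnnotationSet(axioms=ax))
        annotated = sorted(ic.ic)
        for _ in range(20):
            a1, a2 = (annotated[int(i)] for i in rng.choice(len(annotated), size=2))
            assert sim_resnik(g, ic, a1, a2) == pytest.approx(sim_resnik(g, ic, a2, a1))
            assert sim_resnik(g, ic, a1, a2) >= 0
            t1, t2 = (ids[int(i)] for i in rng.choice(len(ids), size=2))
            w = sim_wang(g, t1, t2)
            assert sim_wang(g, t2, t1) == pytest.approx(w)
            assert 0 <= w <= 1
            p = sim_pekar(g, t1, t2)
            assert sim_pekar(g, t2, t1) == pytest.approx(p)
            assert 0 <= p <= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_all_measures_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        parents = random_dag(rng, int(rng.integers(6, 13)))
        g = make_graph(parents)
        ids = sorted(parents)
        ax = {p: [t for t, _ in ts] for p, ts in _random_annotations(rng, ids).items()}
        pgaa = WeightedAnnotationSet(axioms={p: [(t, 1) for t in ts] for p, ts in ax.items()})
        ic = compute_ic(g, pgaa)
        oic = oracles.ic_table(parents, ax)
        annotated = sorted(oic)
        for _ in range(12):
            t1, t2 = (annotated[int(i)] for i in rng.choice(len(annotated), size=2))
            assert sim_resnik(g, ic, t1, t2) == pytest.approx(
                oracles.resnik(parents, oic, t1, t2), abs=1e-9
            )
            if oic[t1] + oic[t2] > 0:
                assert sim_lin(g, ic, t1, t2) == pytest.approx(
                    oracles.lin(parents, oic, t1, t2), abs=1e-9
                )
            assert sim_pekar(g, t1, t2) == pytest.approx(
                oracles.pekar(parents, t1, t2), abs=1e-9
            )
            assert sim_wang(g, t1, t2) == pytest.approx(
                oracles.wang(parents, t1, t2), abs=1e-9
            )


class TestAggregate:
    def test_singletons_all_modes_equal(self, annotated_chain):
        g, ic = annotated_chain
        fn = make_term_simfn("lin", g, ic)
        for mode in ("avg", "max", "bma"):
            assert aggregate(fn, [B], [C], mode) == pytest.approx(fn(B, C))

    def test_identical_sets_bma_is_one(self, annotated_chain):
        g, ic = annotated_chain
        fn = make_term_simfn("lin", g, ic)
        assert aggregate(fn, [A, B], [A, B], "bma") == pytest.approx(1.0)

    def test_empty_set_rejected(self, annotated_chain):
        g, ic = annotated_chain
        fn = make_term_simfn("lin", g, ic)
        with pytest.raises(ValueError):
            aggregate(fn, [], [A], "avg")

    @pytest.mark.parametrize("mode", ["avg", "max", "bma"])
    def test_matches_bruteforce_double_loop(self, mode):
        rng = np.random.default_rng(3)
        parents = random_dag(rng, 12)
        g = make_graph(parents)
        ids = sorted(parents)
        ax = {p: [t for t, _ in ts] for p, ts in _random_annotations(rng, ids, 8).items()}
        pgaa = WeightedAnnotationSet(axioms={p: [(t, 1) for t in ts] for p, ts in ax.items()})
        ic = compute_ic(g, pgaa)
        fn = make_term_simfn("wang", g)
        for _ in range(10):
            k1, k2 = rng.integers(1, 5), rng.integers(1, 5)
            T1 = sorted({ids[int(i)] for i in rng.choice(len(ids), size=k1)})
            T2 = sorted({ids[int(i)] for i in rng.choice(len(ids), size=k2)})
            assert aggregate(fn, T1, T2, mode) == pytest.approx(
                oracles.aggregate_bruteforce(fn, T1, T2, mode), abs=1e-9
            )

    def test_bma_literal_is_reweighted_avg(self, annotated_chain):
        g, ic = annotated_chain
        fn = make_term_simfn("lin", g, ic)
        T1, T2 = [A, B], [B, C]
        total = sum(fn(a, b) for a in T1 for b in T2)
        expected = 0.5 * (total / len(T1) + total / len(T2))
        assert aggregate(fn, T1, T2, "bma_literal") == pytest.approx(expected)


class TestScorePairs:
    def test_identical_annotation_sets_score_one(self, annotated_chain):
        g, ic = annotated_chain
        pgaa = WeightedAnnotationSet(axioms={"P1": [(B, 2)], "P2": [(B, 5)]})
        scores = score_pairs([PairExample("P1", "P2", 1)], pgaa, g, ic, "lin", "bma")
        assert scores == [pytest.approx(1.0)]

    def test_symmetric_under_swap(self, annotated_chain):
        g, ic = annotated_chain
        pgaa = WeightedAnnotationSet(axioms={"P1": [(A, 1), (B, 1)], "P2": [(C, 1)]})
        s1 = score_pairs([PairExample("P1", "P2", 1)], pgaa, g, ic, "wang", "bma")
        s2 = score_pairs([PairExample("P2", "P1", 1)], pgaa, g, ic, "wang", "bma")
        assert s1 == pytest.approx(s2)

    def test_unannotated_protein_raises(self, annotated_chain):
        g, ic = annotated_chain
        pgaa = WeightedAnnotationSet(axioms={"P1": [(A, 1)]})
        with pytest.raises(ValueError):
            score_pairs([PairExample("P1", "P9", 1)], pgaa, g, ic, "lin", "bma")
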