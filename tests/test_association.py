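"""MIS, enrichment vectors, cosine relatedness, MFS and core-gene selection."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from netprio.association import (
    CandidateRecord,
    EnrichmentVector,
    annotated_universe,
    cosine_relatedness,
    enrichment_vector,
    max_function_score,
    max_interaction_score,
    select_core_genes,
)
from netprio.network_io import AnnotationMap, SeedSet, WeightedNetwork


def exact_upper_tail(num_wdrawn: int, num_w: int, num_b: int, num_drawn: int) -> float:
    """Independent oracle: P(X >= num_wdrawn) by combinatorial enumeration."""
    total = num_w + num_b
    denom = math.comb(total, num_drawn)
    acc = Fraction(0)
    for i in range(num_wdrawn, min(num_w, num_drawn) + 1):
        acc += Fraction(math.comb(num_w, i) * math.comb(num_b, num_drawn - i), denom)
    return float(acc)


class TestMaxInteractionScore:
    def test_max_over_two_seed_edges(self):
        net = WeightedNetwork.from_edges(
            [("g", "s1", 700), ("g", "s2", 950), ("s1", "s2", 200)]
        )
        assert max_interaction_score("g", SeedSet(ids=["s1", "s2"]), net) == 950

    def test_no_seed_neighbor_gives_zero(self):
        net = WeightedNetwork.from_edges([("g", "x", 700), ("x", "s", 900)])
        assert max_interaction_score("g", SeedSet(ids=["s"]), net) == 0

    def test_absent_gene_is_error(self):
        net = WeightedNetwork.from_edges([("a", "b", 500)])
        with pytest.raises(KeyError):
            max_interaction_score("nope", SeedSet(ids=["a"]), net)

    def test_mis_is_an_incident_edge_score(self):
        from netprio.synthetic import SyntheticSpec, generate_network

        net, truth = generate_network(SyntheticSpec(rng_seed=2))
        seeds = SeedSet(ids=truth.module[:5])
        for g in sorted(net.nodes - set(seeds.ids))[:10]:
            mis = max_interaction_score(g, seeds, net)
            incident = {net.score(g, v) for v in net.neighbors(g)}
            assert mis == 0 or mis in incident


class TestEnrichmentVector:
    def _fixture(self):
        # universe of 20 genes: g plus u01..u19; g has 4 neighbors, 3 annotated
        edges = [("g", f"u{i:02d}", 500) for i in range(1, 5)]
        edges += [(f"u{i:02d}", f"u{i+1:02d}", 300) for i in range(5, 19)]
        edges += [("u05", "g2", 400)]
        net = WeightedNetwork.from_edges(edges)
        universe = {f"u{i:02d}" for i in range(1, 20)} | {"g"}
        ann = AnnotationMap(
            term_genes={"T": frozenset({"u01", "u02", "u03", "u10", "u11"})}
        )
        return net, ann, universe

    def test_hand_computed_tail_and_score(self):
        net, ann, universe = self._fixture()
        es = enrichment_vector("g", net, ann, universe)
        expected_tail = 155 / 4845  # (C(5,3)*C(15,1) + C(5,4)) / C(20,4)
        assert es.scores[0] == pytest.approx(-math.log10(expected_tail), abs=1e-4)
        assert es.scores[0] == pytest.approx(1.4950, abs=1e-4)

    def test_no_annotated_neighbor_scores_zero(self):
        net, _, universe = self._fixture()
        ann = AnnotationMap(term_genes={"T": frozenset({"u10", "u11"})})
        es = enrichment_vector("g", net, ann, universe)
        assert es.scores[0] == 0.0

    def test_term_outside_universe_scores_zero(self):
        net, _, universe = self._fixture()
        ann = AnnotationMap(term_genes={"T": frozenset({"zz1", "zz2"})})
        es = enrichment_vector("g", net, ann, universe)
        assert es.scores[0] == 0.0

    def test_gene_without_universe_neighbors_gives_zero_vector(self):
        net, ann, _ = self._fixture()
        es = enrichment_vector("g2", net, ann, universe={"g", "u01"})
        assert not es.scores.any()

    def test_scores_nonnegative_and_finite(self):
        net, ann, universe = self._fixture()
        es = enrichment_vector("g", net, ann, universe)
        assert (es.scores >= 0).all() and np.isfinite(es.scores).all()

    @given(
        total=st.integers(min_value=1, max_value=25),
        data=st.data(),
    )
    def test_tail_matches_enumeration_up_to_universe_25(self, total, data):
        """scipy's survival function equals the exact combinatorial tail."""
        num_w = data.draw(st.integers(0, total))
        num_drawn = data.draw(st.integers(0, total))
        lo = max(1, num_w + num_drawn - total)
        if lo > min(num_w, num_drawn):
            return  # no positive overlap possible
        num_wdrawn = data.draw(st.integers(lo, min(num_w, num_drawn)))
        exact = exact_upper_tail(num_wdrawn, num_w, total - num_w, num_drawn)
        lib = float(hypergeom.sf(num_wdrawn - 1, total, num_w, num_drawn))
        assert lib == pytest.approx(exact, rel=1e-10, abs=1e-300)


class TestCosineRelatedness:
    def _ev(self, *scores):
        terms = tuple(f"t{i}" for i in range(len(scores)))
        return EnrichmentVector(terms=terms, scores=np.array(scores, dtype=float))

    def test_identical_nonzero_vectors(self):
        a = self._ev(1.0, 2.0, 0.5)
        assert cosine_relatedness(a, a) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert cosine_relatedness(self._ev(1, 0), self._ev(0, 1)) == 0.0

    def test_hand_dot_product(self):
        got = cosine_relatedness(self._ev(1, 1, 0), self._ev(1, 0, 0))
        assert got == pytest.approx(1 / math.sqrt(2), abs=1e-5)

    def test_zero_vector_convention(self):
        assert cosine_relatedness(self._ev(0, 0), self._ev(1, 1)) == 0.0

    def test_mismatched_term_orderings_error(self):
        a = EnrichmentVector(terms=("x", "y"), scores=np.ones(2))
        b = EnrichmentVector(terms=("y", "x"), scores=np.ones(2))
        with pytest.raises(ValueError):
            cosine_relatedness(a, b)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = self._ev(*rng.uniform(0, 5, size=6))
            b = self._ev(*rng.uniform(0, 5, size=6))
            g1, g2 = cosine_relatedness(a, b), cosine_relatedness(b, a)
            assert g1 == g2
            assert 0.0 <= g1 <= 1.0 + 1e-12


class TestMaxFunctionScore:
    def _ev(self, *scores):
        terms = tuple(f"t{i}" for i in range(len(scores)))
        return EnrichmentVector(terms=terms, scores=np.array(scores, dtype=float))

    def test_max_of_two_cosines(self):
        cache = {
            "g": self._ev(1, 1, 0),
            "s1": self._ev(0, 1, 1),   # cosine 0.5
            "s2": self._ev(1, 1, 0.2), # cosine ~0.985
        }
        got = max_function_score("g", SeedSet(ids=["s1", "s2"]), cache)
        assert got == pytest.approx(
            cosine_relatedness(cache["g"], cache["s2"]), abs=1e-12
        )

    def test_identical_vector_reaches_one(self):
        cache = {"g": self._ev(2, 1), "s": self._ev(2, 1)}
        assert max_function_score("g", SeedSet(ids=["s"]), cache) == pytest.approx(1.0)

    def test_missing_cache_entry_is_error(self):
        cache = {"g": self._ev(1, 0)}
        with pytest.raises(KeyError):
            max_function_score("g", SeedSet(ids=["s"]), cache)


class TestSelectCoreGenes:
    def _rec(self, gene, mis, mfs, p=0.01, prob=0.1):
        return CandidateRecord(gene=gene, probability=prob, p_value=p, mis=mis, mfs=mfs)

    def test_threshold_semantics(self):
        recs = [
            self._rec("keep", 950, 0.85),
            self._rec("low_mfs", 950, 0.75),
            self._rec("low_mis", 850, 0.90),
            self._rec("boundary", 900, 0.80),  # MIS inclusive, MFS strict
        ]
        core = select_core_genes(recs)
        assert [r.gene for r in core] == ["keep"]
        assert core[0].is_core

    def test_mis_boundary_inclusive_mfs_strict(self):
        assert [r.gene for r in select_core_genes([self._rec("x", 900, 0.801)])] == ["x"]
        assert select_core_genes([self._rec("y", 899, 0.9)]) == []

    def test_output_subset_and_input_order_invariance(self):
        recs = [self._rec(f"g{i}", 900 + i, 0.81 + i / 100, p=i / 100) for i in range(5)]
        a = select_core_genes(list(recs))
        b = select_core_genes(list(reversed(recs)))
        assert [r.gene for r in a] == [r.gene for r in b]
        assert {r.gene for r in a} <= {r.gene for r in recs}

    def test_ordering_p_then_probability_then_id(self):
        recs = [
            self._rec("b", 950, 0.9, p=0.01, prob=0.2),
            self._rec("a", 950, 0.9, p=0.01, prob=0.2),
            self._rec("c", 950, 0.9, p=0.001, prob=0.1),
        ]
        assert [r.gene for r in select_core_genes(recs)] == ["c", "a", "b"]


def test_annotated_universe_is_annotated_network_nodes():
    net = WeightedNetwork.from_edges([("a", "b", 500), ("b", "c", 500)])
    ann = AnnotationMap(term_genes={"T": frozenset({"a", "c", "offnet"})})
    assert annotated_universe(net, ann) == {"a", "c"}
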