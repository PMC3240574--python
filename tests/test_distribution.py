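"""Component partition, multiset machinery and score distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontosim import (
    InstanceTooLargeError,
    TargetSet,
    corpus_ic,
    exact_score_distribution,
    multiset_coefficient,
    multiset_frequency,
    multiset_score,
    naive_distribution,
    preprocess_components,
    random_corpus,
    random_dag,
    sampled_score_distribution,
    target_set_similarity,
)


class TestMultisetCoefficient:
    def test_identities(self):
        assert multiset_coefficient(7, 1) == 7
        assert multiset_coefficient(1, 9) == 1
        assert multiset_coefficient(5, 0) == 1

    def test_closed_form_value(self):
        # C(42, 5) by direct product: 42*41*40*39*38/120
        assert multiset_coefficient(38, 5) == 42 * 41 * 40 * 39 * 38 // 120 == 850668

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            multiset_coefficient(-1, 2)
        with pytest.raises(ValueError):
            multiset_coefficient(2, -1)


class TestPreprocessComponents:
    def test_chain_toy_partition(self, chain_toy):
        g, ic, target = chain_toy
        part = preprocess_components(g, ic, target)
        assert {s: set(ns) for s, ns in part.components.items()} == {
            0.0: {"A"},
            2.0: {"B"},
            4.0: {"C", "D"},
        }
        assert part.sizes == {0.0: 1, 2.0: 1, 4.0: 2}
        assert part.n_raw_components == 3

    def test_root_target_collapses_everything(self, chain_toy):
        g, ic, _ = chain_toy
        part = preprocess_components(g, ic, TargetSet.of({"A"}))
        assert part.components == {0.0: frozenset(g.terms)}

    @pytest.mark.parametrize("seed", range(12))
    def test_partition_soundness_on_random_instances(self, seed, random_instance):
        """Raw component count equals the implicit-closure size, the
        components partition the universe, and each component's score
        equals the directly computed target-set similarity of its nodes."""
        g, corpus, ic, db = random_instance(seed)
        target = db[seed % len(db)]
        part = preprocess_components(g, ic, target)
        assert part.n_raw_components == len(g.implicit_closure(target.terms))
        seen = set()
        for s, nodes in part.components.items():
            assert not (seen & nodes)
            seen |= nodes
            for n in nodes:
                assert target_set_similarity(g, ic, n, target) == pytest.approx(
                    s, abs=1e-12
                )
        assert seen == g.terms

    @pytest.mark.parametrize("seed", range(6))
    def test_tie_choice_does_not_affect_sizes(self, seed, random_instance):
        """Relabeling terms permutes the arbitrary kept-edge choices among
        equal-weight parents; component sizes per score must not move."""
        g, corpus, ic, db = random_instance(seed)
        target = db[0]
        base = preprocess_components(g, ic, target).sizes

        rng = np.random.default_rng(seed)
        names = sorted(g.terms)
        relabel = dict(zip(names, rng.permutation(names)))
        from ontosim import ICTable, Ontology

        g2 = Ontology.from_edges(
            [(relabel[c], relabel[p]) for c, p, _ in g.iter_edges()]
        )
        ic2 = ICTable(ic={relabel[t]: v for t, v in ic.ic.items()})
        t2 = TargetSet.of({relabel[t] for t in target.terms})
        other = preprocess_components(g2, ic2, t2).sizes
        assert sorted(base.items()) == sorted(other.items())


class TestMultisetOps:
    def test_average_and_max_scores(self):
        assert multiset_score([(0.0, 1), (4.0, 1)], "avg") == 2.0
        assert multiset_score([(3.0, 4)], "avg") == 3.0
        assert multiset_score([(0.0, 1), (4.0, 1)], "max") == 4.0

    def test_empty_or_invalid_multiset_rejected(self):
        with pytest.raises(ValueError):
            multiset_score([], "avg")
        with pytest.raises(ValueError):
            multiset_score([(1.0, 0)], "avg")

    def test_frequency_product(self, chain_toy):
        g, ic, target = chain_toy
        part = preprocess_components(g, ic, target)
        assert multiset_frequency(part, [(0.0, 1), (4.0, 1)]) == 2
        assert multiset_frequency(part, [(4.0, 2)]) == 1
        assert multiset_frequency(part, [(2.0, 2)]) == 0  # m > |N_s|
        with pytest.raises(ValueError):
            multiset_frequency(part, [(7.0, 1)])


class TestNaiveDistribution:
    def test_chain_toy_q2_table(self, chain_toy):
        g, ic, target = chain_toy
        sd = naive_distribution(g, ic, target, 2, "avg")
        assert list(sd.items()) == [(1.0, 1), (2.0, 2), (3.0, 2), (4.0, 1)]
        assert sd.total == math.comb(4, 2)

    def test_q1_is_node_score_histogram(self, chain_toy):
        g, ic, target = chain_toy
        sd = naive_distribution(g, ic, target, 1, "avg")
        assert list(sd.items()) == [(0.0, 1), (2.0, 1), (4.0, 2)]

    def test_full_universe_query_is_single_entry(self, chain_toy):
        g, ic, target = chain_toy
        sd = naive_distribution(g, ic, target, 4, "avg")
        assert len(sd) == 1 and sd.freqs == (1,)

    def test_cap_refuses_large_instances(self, chain_toy):
        g, ic, target = chain_toy
        with pytest.raises(InstanceTooLargeError):
            naive_distribution(g, ic, target, 2, cap=3)


class TestExactDistribution:
    def test_q1_entries_are_component_sizes(self, chain_toy):
        g, ic, target = chain_toy
        part = preprocess_components(g, ic, target)
        sd = exact_score_distribution(part, 1)
        assert dict(sd.items()) == {0.0: 1, 2.0: 1, 4.0: 2}

    def test_single_component_gives_single_entry(self, chain_toy):
        g, ic, _ = chain_toy
        part = preprocess_components(g, ic, TargetSet.of({"A"}))
        sd = exact_score_distribution(part, 2)
        assert list(sd.items()) == [(0.0, math.comb(4, 2))]

    def test_oversized_query_rejected(self, chain_toy):
        g, ic, target = chain_toy
        part = preprocess_components(g, ic, target)
        with pytest.raises(ValueError):
            exact_score_distribution(part, 5)

    def test_support_bounded_by_multiset_count(self, random_instance):
        g, corpus, ic, db = random_instance(2)
        part = preprocess_components(g, ic, db[0])
        for q in (1, 2, 3):
            sd = exact_score_distribution(part, q)
            assert len(sd) <= multiset_coefficient(len(part.U), q)


class TestSampledDistribution:
    def test_seed_determinism(self, chain_toy):
        g, ic, target = chain_toy
        a = sampled_score_distribution(g, ic, target, 2, 500, seed=7)
        b = sampled_score_distribution(g, ic, target, 2, 500, seed=7)
        assert list(a.items()) == list(b.items())

    def test_single_rep(self, chain_toy):
        g, ic, target = chain_toy
        sd = sampled_score_distribution(g, ic, target, 2, 1, seed=0)
        assert sd.total == 1 and len(sd) == 1

    def test_invalid_reps(self, chain_toy):
        g, ic, target = chain_toy
        with pytest.raises(ValueError):
            sampled_score_distribution(g, ic, target, 2, 0, seed=0)

    def test_empirical_support_is_subset_of_exact(self, chain_toy):
        g, ic, target = chain_toy
        exact = naive_distribution(g, ic, target, 2)
        sampled = sampled_score_distribution(g, ic, target, 2, 2000, seed=1)
        for s, _ in sampled.items():
            assert any(abs(s - e) < 1e-9 for e, _ in exact.items())


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), q=st.integers(1, 3))
def test_normalization_exact_and_sampled(seed, q):
    """Exact frequencies always sum to C(|V|, q); sampled ones to reps."""
    g = random_dag(9, 0.2, seed=seed)
    corpus = random_corpus(g, 4, terms_per_item=(1, 3), seed=seed + 1)
    ic = corpus_ic(g, corpus)
    target = TargetSet.of(corpus.items[sorted(corpus.items)[0]])
    part = preprocess_components(g, ic, target)
    for measure in ("avg", "max"):
        sd = exact_score_distribution(part, q, measure)
        assert sd.total == math.comb(9, q)
        assert sd.complete
    sampled = sampled_score_distribution(g, ic, target, q, 321, seed=seed)
    assert sampled.total == 321
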