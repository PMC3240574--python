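"""Shared toy fixtures.

``chain_toy`` is a four-term chain A <- B <- C <- D with target {A, B, C}
and IC values A:0, B:2, C:4; its exact q=2 distribution and partition are
known in closed form and small enough to verify by hand.  ``six_toy`` is a
six-term DAG with target {B, C} and IC values B:2, C:2.5 whose best-match
average for the query {D, F} is (2 + 2.5)/2.
"""

import pytest

from ontosim import ICTable, Ontology, TargetSet


@pytest.fixture(scope="session")
def chain_toy():
    ontology = Ontology.from_edges([("D", "C"), ("C", "B"), ("B", "A")])
    ic = ICTable(ic={"A": 0.0, "B": 2.0, "C": 4.0})
    target = TargetSet.of({"A", "B", "C"}, label="chain-target")
    return ontology, ic, target


@pytest.fixture(scope="session")
def six_toy():
    ontology = Ontology.from_edges(
        [("B", "A"), ("C", "B"), ("D", "B"), ("F", "C"), ("E", "A")]
    )
    ic = ICTable(ic={"A": 0.0, "B": 2.0, "C": 2.5})
    target = TargetSet.of({"B", "C"}, label="six-target")
    return ontology, ic, target


@pytest.fixture(scope="session")
def diamond():
    """D below both B and C, which are both below root A."""
    return Ontology.from_edges([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


@pytest.fixture
def random_instance():
    """Factory: seeded random DAG + corpus + IC + database."""
    from ontosim import corpus_ic, random_corpus, random_dag
    from ontosim.simulate import corpus_database

    def make(seed, n_terms=10, n_items=5, extra_edge_prob=0.15, terms_per_item=(1, 3)):
        ontology = random_dag(n_terms, extra_edge_prob, seed=seed)
        corpus = random_corpus(
            ontology, n_items, terms_per_item=terms_per_item, seed=seed + 1
        )
        ic = corpus_ic(ontology, corpus)
        return ontology, corpus, ic, corpus_database(corpus)

    return make
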