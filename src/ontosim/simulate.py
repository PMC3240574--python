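"""Synthetic fixtures and the simulated-patient ranking experiment.

Random single-rooted DAGs stand in for an ontology, random annotation
corpora for a disease database.  Patient queries are derived from a
disease's own annotations and then corrupted to emulate real clinical
input: NOISE exchanges terms for random ones (a wrong observation),
IMPRECISION moves terms to a parent (a less specific observation), and the
combined scenario applies imprecision first, then noise.  The ranking
experiment measures how well each ranking method recovers the true disease
from its corrupted query.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ic import ICTable
from .ontology import AnnotationCorpus, Ontology, TermID
from .significance import SearchEngine
from .similarity import TargetSet

NONE = "NONE"
NOISE = "NOISE"
IMPRECISION = "IMPRECISION"
IMPRECISION_NOISE = "IMPRECISION_NOISE"
SCENARIOS = (NONE, NOISE, IMPRECISION, IMPRECISION_NOISE)


def _as_rng(seed) -> np.random.Generator:
    # anything exposing the Generator draw methods is accepted as-is
    return seed if hasattr(seed, "random") else np.random.default_rng(seed)


def random_dag(
    n_terms: int, extra_edge_prob: float = 0.1, seed: int | np.random.Generator = 0
) -> Ontology:
    """Random single-rooted DAG: a spanning tree toward term 0 plus extra
    forward edges added independently with probability ``extra_edge_prob``."""
    if n_terms < 1:
        raise ValueError(f"need at least one term, got {n_terms}")
    if not 0.0 <= extra_edge_prob <= 1.0:
        raise ValueError(f"extra_edge_prob must be in [0, 1], got {extra_edge_prob}")
    rng = _as_rng(seed)
    width = len(str(max(n_terms - 1, 1)))
    names = [f"T{i:0{width}d}" for i in range(n_terms)]
    edges: list[tuple[TermID, TermID]] = []
    for i in range(1, n_terms):
        parent = int(rng.integers(i))
        edges.append((names[i], names[parent]))
        for j in range(i):
            if j != parent and rng.random() < extra_edge_prob:
                edges.append((names[i], names[j]))
    return Ontology.from_edges(edges, extra_terms=names[:1])


def random_corpus(
    ontology: Ontology,
    n_items: int,
    terms_per_item: tuple[int, int] = (2, 5),
    seed: int | np.random.Generator = 0,
    popularity: float = 0.0,
) -> AnnotationCorpus:
    """Random annotation corpus: each item receives a random set of terms,
    with size uniform in ``terms_per_item`` (inclusive).

    With ``popularity = 0`` (default) terms are drawn uniformly.  A positive
    exponent draws them from a Zipf law over a seeded random permutation of
    the terms, so that a few "popular" terms recur across many items — the
    term-reuse structure real annotation corpora show, which is what makes
    different items compete for the same queries.

    Leaves left unannotated are then attached to items round-robin so that
    every term ends up with propagated count >= 1 (hence a finite IC).  If
    covering them forces an item past the requested maximum size, a warning
    documents it.
    """
    lo, hi = terms_per_item
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid terms_per_item range: {terms_per_item}")
    if popularity < 0:
        raise ValueError(f"popularity exponent must be >= 0, got {popularity}")
    rng = _as_rng(seed)
    terms = sorted(ontology.terms)
    weights = None
    if popularity > 0:
        ranked = 1.0 / np.arange(1, len(terms) + 1, dtype=float) ** popularity
        weights = np.empty(len(terms))
        weights[rng.permutation(len(terms))] = ranked
        weights /= weights.sum()
    items: dict[str, set[TermID]] = {}
    width = len(str(max(n_items - 1, 1)))
    for k in range(n_items):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(terms))
        chosen = rng.choice(len(terms), size=size, replace=False, p=weights)
        items[f"item{k:0{width}d}"] = {terms[i] for i in chosen}

    if items:
        covered: set[TermID] = set()
        for t in items.values():
            covered |= t
        missing = [leaf for leaf in ontology.leaves() if leaf not in covered]
        labels = sorted(items)
        for k, leaf in enumerate(missing):
            items[labels[k % len(labels)]].add(leaf)
        if any(len(v) > hi for v in items.values()):
            # coverage takes priority over the requested size range
            warnings.warn(
                f"covering {len(missing)} unannotated leaves pushed some item "
                f"annotation sets beyond the requested maximum of {hi}",
                stacklevel=2,
            )

    return AnnotationCorpus({k: frozenset(v) for k, v in items.items()})


def corpus_database(corpus: AnnotationCorpus) -> list[TargetSet]:
    """View a corpus as a database of target sets, one per item."""
    return [TargetSet.of(terms, label=item) for item, terms in sorted(corpus.items.items())]


def simulate_patient_query(
    ontology: Ontology,
    disease_terms: Iterable[TermID],
    scenario: str,
    seed: int | np.random.Generator = 0,
) -> frozenset[TermID]:
    """Derive a patient query from a disease's annotation set.

    NONE returns the terms unchanged.  IMPRECISION independently replaces
    each non-root term, with probability 0.5, by one of its parents chosen
    uniformly; the result is deduplicated.  NOISE exchanges k terms
    (k = 2 when the query has >= 5 terms, else k = 1) for terms drawn
    without replacement from the rest of the ontology, preserving the query
    size.  IMPRECISION_NOISE applies imprecision first, then noise.
    """
    terms = set(disease_terms)
    if not terms:
        raise ValueError("disease has no annotated terms")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario: {scenario!r} (expected one of {SCENARIOS})")
    rng = _as_rng(seed)

    if scenario in (IMPRECISION, IMPRECISION_NOISE):
        moved: set[TermID] = set()
        for t in sorted(terms):
            if t != ontology.root and rng.random() < 0.5:
                parents = ontology.parents(t)
                t = parents[int(rng.integers(len(parents)))]
            moved.add(t)
        terms = moved

    if scenario in (NOISE, IMPRECISION_NOISE):
        q = len(terms)
        k = 2 if q >= 5 else 1
        k = min(k, q)
        ordered = sorted(terms)
        victims = rng.choice(len(ordered), size=k, replace=False)
        pool = sorted(ontology.terms - terms)
        if len(pool) < k:
            raise ValueError("ontology too small to draw replacement terms")
        picks = rng.choice(len(pool), size=k, replace=False)
        for v, p in zip(victims, picks):
            terms.discard(ordered[int(v)])
            terms.add(pool[int(p)])

    return frozenset(terms)


def _parse_method(spec: str) -> tuple[str, int]:
    """``"score"`` / ``"exact"`` / ``"sampled:REPS"`` -> (method, reps)."""
    if spec.startswith("sampled"):
        _, _, reps = spec.partition(":")
        return "sampled", int(reps or 1000)
    if spec in ("score", "exact"):
        return spec, 0
    raise ValueError(f"unknown method spec: {spec!r}")


def diagnosis_experiment(
    ontology: Ontology,
    ic: ICTable,
    database: Sequence[TargetSet],
    scenarios: Sequence[str] = SCENARIOS,
    methods: Sequence[str] = ("score", "sampled:1000", "exact"),
    seed: int | np.random.Generator = 0,
    measure: str = "avg",
    engine: SearchEngine | None = None,
) -> pd.DataFrame:
    """Rank-recovery experiment over a database of annotated items.

    For every item and scenario one corrupted query is generated from the
    item's own annotations; every ranking method then searches the full
    database with that query and the rank assigned to the true item is
    recorded.  Within one run, Monte-Carlo distributions are sampled once
    per (item, query size, reps) and reused across queries, mirroring
    per-entry precomputation.

    Returns a long-format table with columns
    ``item, scenario, method, q, true_rank``.
    """
    rng = _as_rng(seed)
    engine = engine or SearchEngine(ontology, ic, database, measure=measure)
    sampled_cache: dict = {}
    rows = []
    for scenario in scenarios:
        for idx, target in enumerate(database):
            query = simulate_patient_query(ontology, target.terms, scenario, rng)
            for spec in methods:
                method, reps = _parse_method(spec)
                results = engine.rank(
                    query,
                    method=method,
                    reps=reps,
                    rng=rng,
                    sampled_cache=sampled_cache if method == "sampled" else None,
                )
                label = target.label or str(idx)
                true_rank = next(r.rank for r in results if r.item_id == label)
                rows.append(
                    {
                        "item": label,
                        "scenario": scenario,
                        "method": spec,
                        "q": len(query),
                        "true_rank": true_rank,
                    }
                )
    return pd.DataFrame(rows)
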