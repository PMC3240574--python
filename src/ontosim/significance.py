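"""Exact P-values and database-wide similarity search.

The P-value of an observed query score is the proportion, among all
C(|V|, q) equally likely q-term queries, of queries scoring at least as
high against the same target set.  A search ranks every database item
either by raw score or by P-value (exact or Monte-Carlo estimated), with
P-value ties broken by descending score and remaining ties receiving the
average of their positional ranks.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np

from .distribution import (
    SCORE_TOL,
    ScoreDistribution,
    _same_score,
    exact_score_distribution,
    preprocess_components,
    sample_scores,
)
from .ic import ICTable
from .ontology import Ontology, TermID
from .similarity import TargetSet


def pvalue(sd: ScoreDistribution, s_obs: float, tol: float = SCORE_TOL) -> float:
    """P-value of ``s_obs`` under a complete exact score distribution:
    the fraction of queries scoring at least ``s_obs`` (inclusive within
    the score tolerance)."""
    if not sd.complete:
        raise ValueError(
            "P-values require a complete exact distribution "
            f"(got kind={sd.kind!r}, total={sd.total})"
        )
    return float(sd.tail_probability(s_obs, tol))


def average_ranks(
    keys: Sequence, eq: Callable[[object, object], bool] | None = None
) -> list[float]:
    """Positional ranks (1-based) for an already-sorted key sequence, with
    tied blocks receiving the mean of their positions."""
    if eq is None:
        eq = lambda a, b: a == b  # noqa: E731
    ranks: list[float] = []
    i = 0
    n = len(keys)
    while i < n:
        j = i
        while j + 1 < n and eq(keys[j + 1], keys[i]):
            j += 1
        ranks.extend([(i + j + 2) / 2] * (j - i + 1))
        i = j + 1
    return ranks


@dataclass(frozen=True)
class SearchResult:
    item_id: str
    score: float
    pvalue: Fraction | None
    rank: float


class _TailTable:
    """Fast 'frequency of scores >= x' lookups for a score distribution."""

    def __init__(self, sd: ScoreDistribution):
        self.scores = list(sd.scores)
        suffix = [0] * (len(sd.freqs) + 1)
        for i in range(len(sd.freqs) - 1, -1, -1):
            suffix[i] = suffix[i + 1] + sd.freqs[i]
        self.suffix = suffix
        self.total = suffix[0]

    def tail_probability(self, s_obs: float, tol: float = SCORE_TOL) -> Fraction:
        threshold = s_obs - tol * max(1.0, abs(s_obs))
        idx = bisect.bisect_left(self.scores, threshold)
        return Fraction(self.suffix[idx], self.total)


class _SampledTail:
    """Empirical tail probabilities from Monte-Carlo query scores, with a
    pseudocount floor of 1/(reps+1) so an extreme score is never assigned
    probability zero."""

    def __init__(self, drawn: np.ndarray):
        self.sorted = np.sort(drawn)
        self.reps = drawn.size

    def tail_probability(self, s_obs: float, tol: float = SCORE_TOL) -> Fraction:
        threshold = s_obs - tol * max(1.0, abs(s_obs))
        tail = self.reps - int(np.searchsorted(self.sorted, threshold, side="left"))
        if tail == 0:
            return Fraction(1, self.reps + 1)
        return Fraction(tail, self.reps)


class SearchEngine:
    """Similarity search over a fixed database of target sets.

    The component partition (hence the per-term target-set similarity) of
    every item is computed once up front; exact score distributions are
    computed lazily and cached per (item, q, measure), mirroring the
    per-database-entry precomputation a production service would use.
    """

    def __init__(
        self,
        ontology: Ontology,
        ic: ICTable,
        database: Sequence[TargetSet],
        measure: str = "avg",
    ):
        if not database:
            raise ValueError("database of target sets is empty")
        self.ontology = ontology
        self.ic = ic
        self.database = list(database)
        self.measure = measure
        self._terms = sorted(ontology.terms)
        self._term_index = {t: i for i, t in enumerate(self._terms)}
        self._partitions = [
            preprocess_components(ontology, ic, t) for t in self.database
        ]
        # item x term matrix of target-set similarities
        self._values = np.array(
            [[p.node_score[t] for t in self._terms] for p in self._partitions]
        )
        self._exact_tails: dict[tuple[int, int], _TailTable] = {}

    @property
    def n_items(self) -> int:
        return len(self.database)

    def observed_scores(self, query: Iterable[TermID]) -> np.ndarray:
        """Score of the query against every database item."""
        idx = [self._term_index[t] for t in frozenset(query)]
        if not idx:
            raise ValueError("query set is empty")
        sub = self._values[:, idx]
        return sub.mean(axis=1) if self.measure == "avg" else sub.max(axis=1)

    def exact_tail(self, item: int, q: int) -> _TailTable:
        key = (item, q)
        if key not in self._exact_tails:
            sd = exact_score_distribution(self._partitions[item], q, self.measure)
            self._exact_tails[key] = _TailTable(sd)
        return self._exact_tails[key]

    def sampled_tail(
        self, item: int, q: int, reps: int, rng: np.random.Generator
    ) -> _SampledTail:
        drawn = sample_scores(self._values[item], q, reps, rng, self.measure)
        return _SampledTail(drawn)

    def rank(
        self,
        query: Iterable[TermID],
        method: str = "exact",
        reps: int = 1000,
        rng: np.random.Generator | None = None,
        sampled_cache: dict | None = None,
    ) -> list[SearchResult]:
        """Rank every database item against the query.

        ``method="score"`` orders by descending observed score;
        ``"exact"``/``"sampled"`` order by ascending P-value with ties
        broken by descending score.  Tied items share the average of their
        positional ranks.  ``sampled_cache`` lets one simulation run reuse
        a Monte-Carlo distribution across queries of the same size.
        """
        query = frozenset(query)
        q = len(query)
        scores = self.observed_scores(query)

        if method == "score":
            pvals: list[Fraction | None] = [None] * self.n_items
            order_keys = [(-s,) for s in scores]
            eq = lambda a, b: _same_score(-a[0], -b[0])  # noqa: E731
        elif method in ("exact", "sampled"):
            pvals = []
            for i in range(self.n_items):
                if method == "exact":
                    table = self.exact_tail(i, q)
                else:
                    if rng is None:
                        raise ValueError("sampled method needs an rng")
                    key = (i, q, reps)
                    if sampled_cache is not None and key in sampled_cache:
                        table = sampled_cache[key]
                    else:
                        table = self.sampled_tail(i, q, reps, rng)
                        if sampled_cache is not None:
                            sampled_cache[key] = table
                pvals.append(table.tail_probability(float(scores[i])))
            order_keys = [(p, -s) for p, s in zip(pvals, scores)]
            eq = lambda a, b: a[0] == b[0] and _same_score(-a[1], -b[1])  # noqa: E731
        else:
            raise ValueError(f"unknown method: {method!r}")

        order = sorted(range(self.n_items), key=lambda i: order_keys[i])
        ranks = average_ranks([order_keys[i] for i in order], eq=eq)
        results = [
            SearchResult(
                item_id=self.database[i].label or str(i),
                score=float(scores[i]),
                pvalue=pvals[i],
                rank=r,
            )
            for i, r in zip(order, ranks)
        ]
        return results


def search(
    ontology: Ontology,
    ic: ICTable,
    database: Sequence[TargetSet],
    query: Iterable[TermID],
    method: str = "exact",
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[SearchResult]:
    """One-shot search: rank ``database`` against ``query``.

    For repeated queries over the same database build a
    :class:`SearchEngine` instead, which caches per-item distributions.
    """
    engine = SearchEngine(ontology, ic, database)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return engine.rank(query, method=method, reps=reps, rng=rng)
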