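"""Null score distributions for similarity searches.

The null model treats every q-element subset of the term universe V as an
equally likely query.  The naive route enumerates all C(|V|, q) subsets and
scores each one.  The fast route exploits the fact that, for Resnik-based
measures, a term's contribution to any query score is fully determined by
its *target-set similarity* s — the IC of the best common-ancestor match
against the target — and that only |T_IMPL| distinct values of s exist
(T_IMPL being the implicit closure of the target set).  The ontology is
collapsed into components N_s of terms sharing s; the score distribution is
then assembled by enumerating multisets of s-values with multiplicities,
weighting each multiset by a product of binomial coefficients.  Both routes
produce identical distributions; the naive one is kept as the permanent
test oracle and behind ``--method naive``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .errors import InstanceTooLargeError
from .ic import ICTable
from .ontology import Ontology, TermID
from .similarity import TargetSet, target_set_similarity

#: Relative tolerance under which two floating-point scores are considered
#: the same score.  Scores are sums of IC values divided by small integers;
#: different summation orders can disagree in the last few bits, so exact
#: hashing alone would split one true score across several entries.
SCORE_TOL = 1e-9

#: Default cap on C(|V|, q) above which exhaustive enumeration is refused.
NAIVE_CAP = 10_000_000

MEASURES = ("avg", "max")


def multiset_coefficient(n: int, q: int) -> int:
    """Number of distinct multisets of cardinality ``q`` drawn from ``n``
    elements: C(n+q-1, q)."""
    if n < 0 or q < 0:
        raise ValueError(f"multiset coefficient needs nonnegative arguments, got ({n}, {q})")
    if n == 0:
        return 1 if q == 0 else 0
    return math.comb(n + q - 1, q)


def _same_score(a: float, b: float, tol: float = SCORE_TOL) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


def _merge_scores(acc: Mapping[float, int], tol: float) -> tuple[list[float], list[int]]:
    """Collapse accumulator keys that differ only by floating-point noise.

    Keys are sorted and grouped greedily; each group is represented by its
    first (smallest) key.
    """
    scores: list[float] = []
    freqs: list[int] = []
    for s in sorted(acc):
        if scores and _same_score(scores[-1], s, tol):
            freqs[-1] += acc[s]
        else:
            scores.append(s)
            freqs.append(acc[s])
    return scores, freqs


@dataclass(frozen=True)
class ScoreDistribution:
    """A score distribution: unique scores with integer frequencies.

    For an exact distribution the frequencies sum to C(|V|, q); for an
    empirical (sampled) one they sum to the number of repetitions.
    Frequencies are arbitrary-precision integers — C(10^4, 5) does not fit
    in 64 bits.
    """

    scores: tuple[float, ...]
    freqs: tuple[int, ...]
    q: int
    universe_size: int
    kind: str = "exact"  # "exact" | "sampled"

    @classmethod
    def from_accumulator(
        cls,
        acc: Mapping[float, int],
        q: int,
        universe_size: int,
        kind: str = "exact",
        tol: float = SCORE_TOL,
    ) -> "ScoreDistribution":
        scores, freqs = _merge_scores(acc, tol)
        return cls(tuple(scores), tuple(freqs), q, universe_size, kind)

    @property
    def total(self) -> int:
        return sum(self.freqs)

    @property
    def complete(self) -> bool:
        """True when the distribution covers every possible query."""
        return self.kind == "exact" and self.total == math.comb(self.universe_size, self.q)

    def __len__(self) -> int:
        return len(self.scores)

    def items(self) -> Iterable[tuple[float, int]]:
        return zip(self.scores, self.freqs)

    def tail_count(self, s_obs: float, tol: float = SCORE_TOL) -> int:
        """Number of queries scoring at least ``s_obs`` (inclusive within
        the score tolerance)."""
        threshold = s_obs - tol * max(1.0, abs(s_obs))
        return sum(f for s, f in zip(self.scores, self.freqs) if s >= threshold)

    def tail_probability(self, s_obs: float, tol: float = SCORE_TOL) -> Fraction:
        return Fraction(self.tail_count(s_obs, tol), self.total)

    def write_tsv(self, stream: TextIO, label: str = "", method: str = "") -> None:
        stream.write(
            f"# q={self.q}\tuniverse_size={self.universe_size}\t"
            f"target={label}\tmethod={method or self.kind}\n"
        )
        stream.write("score\tfrequency\tcumulative_ge_probability\n")
        total = self.total
        tail = 0
        rows = []
        for s, f in sorted(zip(self.scores, self.freqs), reverse=True):
            tail += f
            rows.append((s, f, Fraction(tail, total)))
        for s, f, p in reversed(rows):
            stream.write(f"{s:.15g}\t{f}\t{float(p):.15g}\n")


@dataclass(frozen=True)
class ComponentPartition:
    """Partition of the term universe into components N_s of equal
    target-set similarity ``s``.

    ``components`` maps each distinct score s to its node set; the score
    set U is ``components.keys()``, drawn from the IC values of the
    target's implicit closure.  ``node_score`` gives s per term and
    ``n_raw_components`` is the number of components before merging those
    with equal IC (one per implicit-closure term).
    """

    components: Mapping[float, frozenset[TermID]]
    node_score: Mapping[TermID, float]
    universe_size: int
    n_raw_components: int

    @property
    def U(self) -> tuple[float, ...]:
        """Distinct target-set similarity scores, ascending."""
        return tuple(sorted(self.components))

    @property
    def sizes(self) -> dict[float, int]:
        return {s: len(ns) for s, ns in self.components.items()}


def preprocess_components(
    ontology: Ontology, ic: ICTable, target: TargetSet, tol: float = SCORE_TOL
) -> ComponentPartition:
    """Collapse the DAG into components of equal target-set similarity.

    Working on the inverted-edge view (root toward leaves), each edge
    leaving a closure term carries that term's IC, and each edge leaving
    any other term carries the maximum weight entering it, assigned in
    topological order.  Keeping one maximum-weight incoming edge per
    non-root term (ties: lexicographically smallest parent) and cutting
    edges between two closure terms leaves exactly one component per
    closure term; components whose closure terms share an IC value are
    merged.  The surviving weight at each term equals its target-set
    similarity, so the component of score s is exactly N_s.
    """
    t_impl = ontology.implicit_closure(target.terms)
    ic_of = {n: ic[n] for n in t_impl}  # raises MissingICError if uncovered

    order = ontology.topological_order()  # root first, ancestors before descendants
    kept_parent: dict[TermID, TermID] = {}
    weight: dict[TermID, float] = {}
    for n in order:
        if n == ontology.root:
            continue
        best_p: TermID | None = None
        best_w = -math.inf
        for p in ontology.parents(n):  # sorted: ties pick the smallest id
            w = ic_of[p] if p in t_impl else weight[p]
            if w > best_w:
                best_p, best_w = p, w
        kept_parent[n] = best_p
        weight[n] = best_w

    # component leader = the unique closure term reached via kept edges;
    # a closure term's kept edge always comes from another closure term
    # (the closure is ancestor-closed) and is cut, so closure terms lead
    # their own components.
    leader: dict[TermID, TermID] = {}
    node_score: dict[TermID, float] = {}
    for n in order:
        if n in t_impl:
            leader[n] = n
            node_score[n] = ic_of[n]
        else:
            leader[n] = leader[kept_parent[n]]
            node_score[n] = weight[n]

    raw: dict[TermID, set[TermID]] = {t: set() for t in t_impl}
    for n in order:
        raw[leader[n]].add(n)

    # merge components whose leaders carry the same IC value
    groups: list[tuple[float, set[TermID]]] = []
    for lead in sorted(t_impl, key=lambda t: (ic_of[t], t)):
        s = ic_of[lead]
        if not (groups and _same_score(groups[-1][0], s, tol)):
            groups.append((s, set()))
        groups[-1][1].update(raw[lead])

    components = {s: frozenset(ns) for s, ns in groups}
    return ComponentPartition(
        components=components,
        node_score=node_score,
        universe_size=len(ontology),
        n_raw_components=len(t_impl),
    )


def multiset_score(pairs: Iterable[tuple[float, int]], measure: str = "avg") -> float:
    """Score of a multiset of target-set similarities with multiplicities:
    the multiplicity-weighted mean, or the largest member."""
    pairs = list(pairs)
    card = sum(m for _, m in pairs)
    if card < 1:
        raise ValueError("empty score multiset")
    if any(m < 1 for _, m in pairs):
        raise ValueError("multiplicities must be positive")
    if measure == "avg":
        return sum(m * s for s, m in pairs) / card
    if measure == "max":
        return max(s for s, _ in pairs)
    raise ValueError(f"unknown measure: {measure!r}")


def multiset_frequency(
    partition: ComponentPartition, pairs: Iterable[tuple[float, int]]
) -> int:
    """Number of node subsets realising a multiset of scores: the product
    of C(|N_s|, m) over its (score, multiplicity) pairs."""
    sizes = partition.sizes
    freq = 1
    for s, m in pairs:
        matches = [v for v in sizes if _same_score(v, s)]
        if not matches:
            raise ValueError(f"score {s!r} is not in the partition's score set")
        freq *= math.comb(sizes[matches[0]], m)
    return freq


def exact_score_distribution(
    partition: ComponentPartition,
    q: int,
    measure: str = "avg",
    tol: float = SCORE_TOL,
) -> ScoreDistribution:
    """Exact null distribution over all C(|V|, q) queries, via multiset
    enumeration over the component partition.

    Multisets are generated recursively over the ascending score set with
    remaining-capacity pruning; partial weighted sums are carried down the
    recursion so each multiset costs O(1) beyond its enumeration.
    """
    if q < 1:
        raise ValueError(f"query size must be >= 1, got {q}")
    if q > partition.universe_size:
        raise ValueError(
            f"query size {q} exceeds universe size {partition.universe_size}"
        )
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}")

    entries = sorted((s, len(ns)) for s, ns in partition.components.items())
    d = len(entries)
    # suffix_cap[i] = total node capacity of entries[i:]
    suffix_cap = [0] * (d + 1)
    for i in range(d - 1, -1, -1):
        suffix_cap[i] = suffix_cap[i + 1] + entries[i][1]

    acc: dict[float, int] = {}

    def recurse(i: int, remaining: int, weighted: float, freq: int, current_max: float):
        if remaining == 0:
            score = weighted / q if measure == "avg" else current_max
            acc[score] = acc.get(score, 0) + freq
            return
        if i == d or suffix_cap[i] < remaining:
            return
        s, n_s = entries[i]
        for m in range(min(n_s, remaining), -1, -1):
            recurse(
                i + 1,
                remaining - m,
                weighted + m * s,
                freq * math.comb(n_s, m),
                s if m > 0 else current_max,
            )

    recurse(0, q, 0.0, 1, -math.inf)
    return ScoreDistribution.from_accumulator(
        acc, q=q, universe_size=partition.universe_size, kind="exact", tol=tol
    )


def node_scores(
    ontology: Ontology, ic: ICTable, target: TargetSet
) -> dict[TermID, float]:
    """Target-set similarity of every term, computed directly from pairwise
    Resnik similarities (no graph collapsing) — the oracle route."""
    return {
        n: target_set_similarity(ontology, ic, n, target) for n in sorted(ontology.terms)
    }


def naive_distribution(
    ontology: Ontology,
    ic: ICTable,
    target: TargetSet,
    q: int,
    measure: str = "avg",
    cap: int = NAIVE_CAP,
) -> ScoreDistribution:
    """Exhaustive null distribution: score every q-subset of the universe.

    Intended for small instances and as the permanent correctness oracle;
    instances with more than ``cap`` candidate queries are refused.
    """
    n = len(ontology)
    if not 1 <= q <= n:
        raise ValueError(f"query size must be in [1, {n}], got {q}")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}")
    n_queries = math.comb(n, q)
    if n_queries > cap:
        raise InstanceTooLargeError(
            f"C({n}, {q}) = {n_queries} queries exceeds the cap of {cap}"
        )
    per_node = node_scores(ontology, ic, target)
    scores = [per_node[t] for t in sorted(ontology.terms)]
    acc: dict[float, int] = {}
    for combo in itertools.combinations(scores, q):
        value = sum(combo) / q if measure == "avg" else max(combo)
        acc[value] = acc.get(value, 0) + 1
    return ScoreDistribution.from_accumulator(acc, q=q, universe_size=n, kind="exact")


def sample_scores(
    score_values: Sequence[float],
    q: int,
    reps: int,
    rng: np.random.Generator,
    measure: str = "avg",
) -> np.ndarray:
    """Scores of ``reps`` queries drawn uniformly from the q-subsets of a
    universe whose per-term target-set similarities are ``score_values``.

    Uniformity over subsets comes from ranking i.i.d. uniforms per row and
    taking the q smallest ranks.
    """
    values = np.asarray(score_values, dtype=float)
    n = values.size
    if not 1 <= q <= n:
        raise ValueError(f"query size must be in [1, {n}], got {q}")
    out = np.empty(reps, dtype=float)
    pos = 0
    chunk = max(1, min(reps, 4_000_000 // max(n, 1)))
    while pos < reps:
        k = min(chunk, reps - pos)
        u = rng.random((k, n))
        idx = np.argpartition(u, q - 1, axis=1)[:, :q]
        picked = values[idx]
        out[pos : pos + k] = picked.mean(axis=1) if measure == "avg" else picked.max(axis=1)
        pos += k
    return out


def sampled_score_distribution(
    ontology: Ontology,
    ic: ICTable,
    target: TargetSet,
    q: int,
    reps: int,
    seed: int | np.random.Generator,
    measure: str = "avg",
) -> ScoreDistribution:
    """Empirical (Monte-Carlo) score distribution from ``reps`` uniformly
    drawn q-subsets of the universe.  Deterministic per seed."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_node = node_scores(ontology, ic, target)
    values = [per_node[t] for t in sorted(ontology.terms)]
    drawn = sample_scores(values, q, reps, rng, measure)
    uniq, counts = np.unique(drawn, return_counts=True)
    acc = {float(s): int(c) for s, c in zip(uniq, counts)}
    return ScoreDistribution.from_accumulator(
        acc, q=q, universe_size=len(ontology), kind="sampled"
    )
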