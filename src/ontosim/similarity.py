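"""Resnik pairwise similarity and the two group measures built on it.

``resnik(n1, n2)`` is the information content of the most informative common
ancestor of the two terms.  For a query set Q against a target set T we use
the asymmetric best-match average — each query term contributes the IC of
its best match in T, and the contributions are averaged — and the overall
maximum over all query/target pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import MissingICError
from .ic import ICTable
from .ontology import Ontology, TermID


@dataclass(frozen=True)
class TargetSet:
    """The annotation set of one database item (e.g. one disease)."""

    terms: frozenset[TermID]
    label: str = ""

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"target set {self.label!r} is empty")

    @classmethod
    def of(cls, terms: Iterable[TermID], label: str = "") -> "TargetSet":
        return cls(terms=frozenset(terms), label=label)


def resnik_pairwise(ontology: Ontology, ic: ICTable, n1: TermID, n2: TermID) -> float:
    """IC of the most informative common ancestor of ``n1`` and ``n2``.

    Every common ancestor must carry an IC entry; by IC monotonicity a
    missing entry could hide the true maximum, so it is an error.
    """
    common = ontology.ancestors(n1) & ontology.ancestors(n2)
    best = None
    for a in common:
        v = ic.get(a)
        if v is None:
            raise MissingICError(
                f"common ancestor {a!r} of {n1!r} and {n2!r} has no IC entry"
            )
        if best is None or v > best:
            best = v
    # a rooted DAG guarantees at least the root in common
    assert best is not None
    return best


def target_set_similarity(
    ontology: Ontology, ic: ICTable, n: TermID, target: TargetSet
) -> float:
    """Best Resnik similarity of a single term against any target term."""
    return max(resnik_pairwise(ontology, ic, n, t) for t in target.terms)


def sim_avg(
    ontology: Ontology, ic: ICTable, query: Iterable[TermID], target: TargetSet
) -> float:
    """Asymmetric best-match average of the query against the target.

    Duplicate query terms are collapsed: queries are sets of distinct terms,
    matching the universe over which the null distribution is defined.
    """
    q = frozenset(query)
    if not q:
        raise ValueError("query set is empty")
    return sum(target_set_similarity(ontology, ic, n, target) for n in sorted(q)) / len(q)


def sim_max(
    ontology: Ontology, ic: ICTable, query: Iterable[TermID], target: TargetSet
) -> float:
    """Maximum Resnik similarity over all query/target term pairs
    (symmetric in its two arguments)."""
    q = frozenset(query)
    if not q:
        raise ValueError("query set is empty")
    return max(target_set_similarity(ontology, ic, n, target) for n in q)
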