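"""Annotation frequencies and information content.

The information content of a term is ``IC(n) = -log p(n)``, where ``p(n)``
is the fraction of items annotated — after propagation along parent edges —
to ``n`` or any of its descendants.  IC is zero at the root (every item is
implicitly annotated there) and non-decreasing along every root-to-leaf
path, which is what makes the Resnik similarity well behaved.

Terms to which no item propagates are excluded from the tables rather than
being assigned infinite IC: every term that can occur inside a target set's
implicit closure is annotated by construction, so all IC values a similarity
computation needs are present, and asking for a missing one is a hard error.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping, TextIO

from .errors import EmptyCorpusError, MissingICError
from .ontology import AnnotationCorpus, Ontology, TermID


@dataclass(frozen=True)
class FrequencyTable:
    """Propagated annotation frequencies ``p(n)`` over a corpus."""

    p: Mapping[TermID, float]
    total_items: int

    def count(self, term: TermID) -> int:
        """Integer propagated annotation count behind ``p(term)``."""
        return round(self.p[term] * self.total_items)


@dataclass(frozen=True)
class ICTable:
    """Information content per term, ``ic(n) = -log_base p(n)``."""

    ic: Mapping[TermID, float]
    log_base: float = math.e

    def __contains__(self, term: TermID) -> bool:
        return term in self.ic

    def __getitem__(self, term: TermID) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise MissingICError(
                f"term {term!r} has no information-content entry "
                "(no item is annotated at or below it)"
            ) from None

    def get(self, term: TermID, default: float | None = None) -> float | None:
        return self.ic.get(term, default)


def annotation_frequencies(ontology: Ontology, corpus: AnnotationCorpus) -> FrequencyTable:
    """Propagated annotation frequency of every term with at least one
    (implicitly) annotated item.

    Each item contributes at most once to each term, however many of its
    annotations lie below that term.
    """
    if corpus.n_items == 0:
        raise EmptyCorpusError("annotation corpus has no items")
    counts: dict[TermID, int] = {}
    for _, terms in corpus:
        for t in ontology.implicit_closure(terms):
            counts[t] = counts.get(t, 0) + 1
    n = corpus.n_items
    return FrequencyTable(p={t: c / n for t, c in counts.items()}, total_items=n)


def information_content(freq: FrequencyTable, log_base: float = math.e) -> ICTable:
    """Turn frequencies into information content, ``-log_base p``."""
    if log_base <= 1:
        raise ValueError(f"log base must exceed 1, got {log_base}")
    ln_base = math.log(log_base)
    table: dict[TermID, float] = {}
    for term, p in freq.p.items():
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p({term!r}) = {p} outside (0, 1]")
        table[term] = -math.log(p) / ln_base
    return ICTable(ic=table, log_base=log_base)


def corpus_ic(
    ontology: Ontology, corpus: AnnotationCorpus, log_base: float = math.e
) -> ICTable:
    """Convenience: frequencies + IC in one call."""
    return information_content(annotation_frequencies(ontology, corpus), log_base)


def load_ic_table(source: TextIO | str, log_base: float = math.e) -> ICTable:
    """Read a two-column ``term_id<TAB>ic`` TSV (``#`` comments allowed)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    table: dict[TermID, float] = {}
    for line in source:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term, value = line.split("\t")[:2]
        ic = float(value)
        if ic < 0 or not math.isfinite(ic):
            raise ValueError(f"invalid information content for {term!r}: {value}")
        table[term] = ic
    return ICTable(ic=table, log_base=log_base)


def write_ic_table(table: ICTable, stream: TextIO) -> None:
    for term in sorted(table.ic):
        stream.write(f"{term}\t{table.ic[term]:.12g}\n")
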