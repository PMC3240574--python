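"""Exception hierarchy.

All data-level failures derive from :class:`OntosimError` so callers (and the
CLI) can distinguish bad input from programming errors.
"""


class OntosimError(Exception):
    """Base class for all data-level errors raised by ontosim."""


class MalformedOntologyError(OntosimError):
    """The ontology graph violates a structural requirement (e.g. a cycle)."""


class MissingTermError(OntosimError):
    """A term identifier does not exist in the ontology."""


class MissingICError(OntosimError):
    """A term required for a similarity computation has no information-content
    entry (typically because no item in the corpus is annotated at or below
    it)."""


class EmptyCorpusError(OntosimError):
    """An annotation corpus with zero items where at least one is required."""


class InstanceTooLargeError(OntosimError):
    """The exhaustive enumeration was refused because the number of candidate
    queries exceeds the configured cap."""
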