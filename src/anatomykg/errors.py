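"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`AnatomyKGError`
so callers can catch the library's own errors without masking bugs.
"""


class AnatomyKGError(Exception):
    """Base class for all errors raised by anatomykg."""


class ConfigurationError(AnatomyKGError):
    """Invalid configuration value (bad base IRI, bad fixture config, ...)."""


class TermCatalogError(AnatomyKGError):
    """A term or prefix is not present in the term catalog."""


class CatalogError(AnatomyKGError):
    """A named-graph class key is not registered in the catalog."""


class SchemeError(AnatomyKGError):
    """A builder input violates the data scheme of its named-graph class."""


class CollisionError(AnatomyKGError):
    """A graph IRI is already present in the store."""


class NotFoundError(AnatomyKGError):
    """A required resource could not be located."""


class AmbiguityError(AnatomyKGError):
    """A query that must return exactly one resource matched several."""


class DanglingReferenceError(AnatomyKGError):
    """A referenced graph IRI does not resolve in the store."""


class CycleError(AnatomyKGError):
    """A parthood or specimen-history structure contains a cycle."""


class MalformedPartonomyError(AnatomyKGError):
    """A partonomy has no root or more than one root."""


class HistoryError(AnatomyKGError):
    """A specimen history is not a valid DAG of processing steps."""


class IntegrityError(AnatomyKGError):
    """Cross-graph referential integrity violated at build time."""


class ParseError(AnatomyKGError):
    """Serialized quads could not be parsed."""


class RegistryError(AnatomyKGError):
    """A data-view name is already registered."""
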