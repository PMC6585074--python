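"""Core domain model for instance-based anatomy knowledge graphs.

Morphological descriptions are recorded as ABox graphs: every described part,
quality and process is an ontology *individual* with its own IRI that
instantiates a class from an existing ontology (HAO, PATO, OBI, IAO, UO, ...).
Because nothing is a blank node, a description can be fragmented into many
small named graphs — one descriptive statement per graph — and any subset can
be re-united by plain set union without losing information.

This module provides the building blocks shared by the rest of the package:

* immutable RDF-ish terms (:class:`Iri`, :class:`Literal`, :class:`Statement`,
  :class:`Quad`, :class:`NamedGraph`);
* ontology references (:class:`TermRef`) and individuals (:class:`Instance`);
* the bundled offline term catalog (:class:`TermCatalog`);
* the named-graph-class catalog mapping each graph class to its validation
  scheme (:class:`NamedGraphClassCatalog`);
* the configurable predicate table (:class:`PredicateTable`);
* deterministic IRI minting (:class:`IriMinter`).
"""

from __future__ import annotations

import csv
import math
import uuid
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Iterator, Optional, Union

from .errors import CatalogError, ConfigurationError, TermCatalogError

__all__ = [
    "Iri",
    "TermRef",
    "Instance",
    "Literal",
    "Statement",
    "Quad",
    "NamedGraph",
    "TermCatalog",
    "SchemeSpec",
    "NamedGraphClassCatalog",
    "PredicateTable",
    "IriMinter",
    "make_instance",
    "default_term_catalog",
    "default_ng_catalog",
    "XSD_STRING",
    "XSD_FLOAT",
    "XSD_DATE",
    "RDF_LANG_STRING",
    "NGO",
    "OBO",
]

OBO = "http://purl.obolibrary.org/obo/"
NGO = "https://example.org/anatomy-kg/ngo/"
_RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_RDFS = "http://www.w3.org/2000/01/rdf-schema#"
_XSD = "http://www.w3.org/2001/XMLSchema#"
_DCT = "http://purl.org/dc/terms/"


@dataclass(frozen=True, order=True)
class Iri:
    """An absolute IRI. The model admits no blank nodes anywhere."""

    value: str

    def __post_init__(self) -> None:
        v = self.value
        if not v:
            raise ConfigurationError("IRI must be non-empty")
        if any(c.isspace() for c in v):
            raise ConfigurationError(f"IRI contains whitespace: {v!r}")
        scheme, sep, rest = v.partition(":")
        if not sep or not scheme or not rest or not scheme[0].isalpha():
            raise ConfigurationError(f"IRI lacks a scheme: {v!r}")

    def __str__(self) -> str:
        return self.value


XSD_STRING = Iri(_XSD + "string")
XSD_FLOAT = Iri(_XSD + "float")
XSD_DATE = Iri(_XSD + "date")
RDF_LANG_STRING = Iri(_RDF + "langString")


@dataclass(frozen=True, order=True)
class TermRef:
    """A reference to an ontology class: IRI, human label, and the short name
    of the source ontology (``pato``, ``obi``, ``iao``, ``bfo``, ``uo``,
    ``hao``, or a user-registered namespace)."""

    iri: Iri
    label: str
    prefix: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigurationError("TermRef label must be non-empty")
        if not self.prefix:
            raise ConfigurationError("TermRef prefix must be non-empty")


@dataclass(frozen=True, order=True)
class Instance:
    """An ontology individual: an IRI that instantiates exactly one catalog
    class at creation time. The label is optional (the partonomy root's label
    is made mandatory by the parthood graph scheme, not here)."""

    iri: Iri
    class_ref: TermRef
    label: Optional[str] = None


@dataclass(frozen=True, order=True)
class Literal:
    """A typed literal value with an optional language tag."""

    lexical: str
    datatype: Iri = XSD_STRING
    lang: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lang is not None and self.datatype != RDF_LANG_STRING:
            raise ConfigurationError(
                "language-tagged literals must use the rdf:langString datatype"
            )
        if self.datatype == XSD_FLOAT:
            try:
                v = float(self.lexical)
            except ValueError as exc:
                raise ConfigurationError(
                    f"not a float lexical form: {self.lexical!r}"
                ) from exc
            if not math.isfinite(v):
                raise ConfigurationError("float literals must be finite")

    @staticmethod
    def of_float(value: float) -> "Literal":
        if not math.isfinite(value):
            raise ConfigurationError("float literals must be finite")
        return Literal(repr(float(value)), XSD_FLOAT)

    @staticmethod
    def of_date(iso: str) -> "Literal":
        return Literal(iso, XSD_DATE)


Node = Union[Iri, Literal]


def _node_key(o: Node) -> tuple:
    # IRIs sort before literals; gives every statement a total order.
    if isinstance(o, Iri):
        return (0, o.value, "", "")
    return (1, o.lexical, o.datatype.value, o.lang or "")


@dataclass(frozen=True)
class Statement:
    """A triple. Subject and predicate are always IRIs — no blank nodes —
    which is exactly what makes graph fragmentation lossless."""

    s: Iri
    p: Iri
    o: Node

    def sort_key(self) -> tuple:
        return (self.s.value, self.p.value) + _node_key(self.o)

    def __lt__(self, other: "Statement") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass(frozen=True)
class Quad:
    """A statement plus the IRI of the named graph containing it."""

    statement: Statement
    graph: Iri

    def sort_key(self) -> tuple:
        return (self.graph.value,) + self.statement.sort_key()


@dataclass(frozen=True)
class NamedGraph:
    """A non-empty set of statements identified by its own IRI and typed by a
    named-graph ontology class — the unit of fragmentation."""

    iri: Iri
    ng_class: TermRef
    statements: frozenset[Statement]

    def __post_init__(self) -> None:
        object.__setattr__(self, "statements", frozenset(self.statements))
        if not self.statements:
            raise ConfigurationError(f"named graph {self.iri} has no statements")

    def __len__(self) -> int:
        return len(self.statements)

    def sorted_statements(self) -> list[Statement]:
        return sorted(self.statements)

    def quads(self) -> Iterator[Quad]:
        for st in self.sorted_statements():
            yield Quad(st, self.iri)


# ---------------------------------------------------------------------------
# Term catalog


class TermCatalog:
    """Offline catalog of the ontology classes used by descriptions.

    Shipped as a small tab-separated file (prefix, IRI, label, source
    ontology); extensible at run time via :meth:`register`. Lookup is by
    ``(prefix, label)``; labels are unique within a prefix.
    """

    def __init__(self) -> None:
        self._terms: dict[tuple[str, str], TermRef] = {}
        self._by_iri: dict[Iri, TermRef] = {}
        self._prefixes: set[str] = set()

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "TermCatalog":
        cat = cls()
        for prefix, iri, label, _source in rows:
            cat.register(TermRef(Iri(iri), label, prefix))
        return cat

    @classmethod
    def bundled(cls) -> "TermCatalog":
        text = (
            resources.files("anatomykg").joinpath("data/term_catalog.tsv").read_text()
        )
        reader = csv.reader(text.splitlines(), delimiter="\t")
        rows = [tuple(r) for r in reader if r and not r[0].startswith("#")]
        return cls.from_rows(rows)  # type: ignore[arg-type]

    def register(self, term: TermRef) -> TermRef:
        key = (term.prefix, term.label)
        self._terms[key] = term
        self._by_iri[term.iri] = term
        self._prefixes.add(term.prefix)
        return term

    def get(self, prefix: str, label: str) -> TermRef:
        try:
            return self._terms[(prefix, label)]
        except KeyError:
            if prefix not in self._prefixes:
                raise TermCatalogError(f"unknown ontology prefix: {prefix!r}")
            raise TermCatalogError(f"unknown term {prefix}:{label!r}")

    def by_iri(self, iri: Iri) -> Optional[TermRef]:
        return self._by_iri.get(iri)

    def has_prefix(self, prefix: str) -> bool:
        return prefix in self._prefixes

    def terms_with_prefix(self, prefix: str) -> list[TermRef]:
        return sorted(t for t in self._terms.values() if t.prefix == prefix)

    def resolve_curie(self, curie: str) -> TermRef:
        """Resolve ``prefix:label`` (label may contain spaces) to a TermRef."""
        prefix, sep, label = curie.partition(":")
        if not sep:
            raise TermCatalogError(f"not a prefix:label reference: {curie!r}")
        return self.get(prefix.strip(), label.strip())


# ---------------------------------------------------------------------------
# Named-graph-class catalog


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of the data scheme a named-graph class
    enforces. ``kind`` selects the shape family the validator interprets;
    ``params`` parameterizes it (e.g. which quality family a quality category
    accepts), so users can register new classes without writing code."""

    kind: str
    params: tuple[tuple[str, str], ...] = ()

    def param(self, key: str, default: Optional[str] = None) -> Optional[str]:
        for k, v in self.params:
            if k == key:
                return v
        return default


SCHEME_KINDS = {
    "document",
    "assertions",
    "parthood",
    "quality",
    "measurement",
    "assay",
    "collection",
    "history",
    "unclassified",
}


class NamedGraphClassCatalog:
    """Registry of named-graph ontology classes.

    Each entry maps a short key (``parthood``, ``assay-data``, ...) to the
    class's :class:`TermRef` and exactly one :class:`SchemeSpec`. Keys are the
    currency of data views and of the validator.
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[TermRef, SchemeSpec]] = {}
        self._key_by_iri: dict[Iri, str] = {}

    def register(self, key: str, term: TermRef, scheme: SchemeSpec) -> None:
        if key in self._entries:
            raise CatalogError(f"named-graph class key already registered: {key!r}")
        if scheme.kind not in SCHEME_KINDS:
            raise CatalogError(f"unknown scheme kind: {scheme.kind!r}")
        self._entries[key] = (term, scheme)
        self._key_by_iri[term.iri] = key

    def term(self, key: str) -> TermRef:
        return self._lookup(key)[0]

    def scheme(self, key: str) -> SchemeSpec:
        return self._lookup(key)[1]

    def _lookup(self, key: str) -> tuple[TermRef, SchemeSpec]:
        try:
            return self._entries[key]
        except KeyError:
            raise CatalogError(f"unknown named-graph class key: {key!r}")

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def keys(self) -> list[str]:
        return sorted(self._entries)

    def key_for_class(self, class_iri: Iri) -> Optional[str]:
        return self._key_by_iri.get(class_iri)

    def keys_of_kind(self, *kinds: str) -> set[str]:
        return {k for k, (_t, s) in self._entries.items() if s.kind in kinds}


def _ng_term(local: str, label: str) -> TermRef:
    return TermRef(Iri(NGO + local), label, "ngo")


#: keys of the built-in named-graph classes; "instance-anatomy" is a plain
#: ontology class (the aggregate individual), not a named-graph class, and
#: therefore lives in the term catalog instead.
BUILTIN_NG_CLASSES: tuple[tuple[str, str, str, SchemeSpec], ...] = (
    ("document", "DocumentNamedGraph", "document named graph", SchemeSpec("document")),
    ("assertions", "AssertionsNamedGraph", "assertions named graph", SchemeSpec("assertions")),
    ("parthood", "ParthoodNamedGraph", "parthood named graph", SchemeSpec("parthood")),
    (
        "anatomical-surface-texture",
        "AnatomicalSurfaceTextureNamedGraph",
        "anatomical surface texture named graph",
        SchemeSpec("quality", (("quality_prefix", "pato"),)),
    ),
    (
        "anatomical-structure-volume",
        "AnatomicalStructureVolumeNamedGraph",
        "anatomical structure volume named graph",
        SchemeSpec("measurement", (("quality_prefix", "pato"), ("unit_prefix", "uo"))),
    ),
    (
        "anatomical-structure-length",
        "AnatomicalStructureLengthNamedGraph",
        "anatomical structure length named graph",
        SchemeSpec("measurement", (("quality_prefix", "pato"), ("unit_prefix", "uo"))),
    ),
    ("assay-data", "AssayDataNamedGraph", "assay data named graph", SchemeSpec("assay")),
    (
        "specimen-collection",
        "SpecimenCollectionNamedGraph",
        "specimen collection named graph",
        SchemeSpec("collection"),
    ),
    (
        "specimen-history",
        "SpecimenHistoryNamedGraph",
        "specimen history named graph",
        SchemeSpec("history"),
    ),
    ("unclassified", "UnclassifiedNamedGraph", "unclassified named graph", SchemeSpec("unclassified")),
)


def default_ng_catalog() -> NamedGraphClassCatalog:
    cat = NamedGraphClassCatalog()
    for key, local, label, scheme in BUILTIN_NG_CLASSES:
        cat.register(key, _ng_term(local, label), scheme)
    return cat


def default_term_catalog() -> TermCatalog:
    return TermCatalog.bundled()


# ---------------------------------------------------------------------------
# Predicate table


@dataclass(frozen=True)
class PredicateTable:
    """The predicate IRIs the builders emit.

    Only the parthood predicate is fixed by convention (BFO ``has part``); the
    rest default to OBO-style or local predicates and are configuration, never
    hard-coded into the builders.
    """

    has_part: Iri = Iri(OBO + "BFO_0000051")
    rdf_type: Iri = Iri(_RDF + "type")
    rdfs_label: Iri = Iri(_RDFS + "label")
    has_quality: Iri = Iri(OBO + "RO_0000086")
    has_value: Iri = Iri(OBO + "IAO_0000004")
    has_unit: Iri = Iri(OBO + "IAO_0000039")
    has_specified_input: Iri = Iri(OBO + "OBI_0000293")
    has_specified_output: Iri = Iri(OBO + "OBI_0000299")
    agent: Iri = Iri(NGO + "has_agent")
    device: Iri = Iri(NGO + "used_device")
    protocol: Iri = Iri(NGO + "followed_protocol")
    date: Iri = Iri(_DCT + "date")
    place: Iri = Iri(NGO + "located_in")
    has_text: Iri = Iri(NGO + "has_text_value")
    has_assertions_graph: Iri = Iri(NGO + "has_assertions_graph")

    def with_overrides(self, **kw: Iri) -> "PredicateTable":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# IRI minting


class IriMinter:
    """Deterministic, injective IRI minting.

    IRIs have the form ``{base}{kind}/{counter:05d}-{tag}`` where the tag is a
    truncated UUID5 over ``(seed, kind, counter)``. The counter guarantees
    injectivity within a run; the seeded tag makes fixture output reproducible
    across runs while keeping IRIs from different seeds distinct.
    """

    def __init__(self, base: Union[str, Iri] = "https://example.org/", seed: int = 0):
        base_s = str(base)
        Iri(base_s)  # raises ConfigurationError on an invalid base
        if not base_s.endswith(("/", "#")):
            base_s += "/"
        self._base = base_s
        self._seed = int(seed)
        self._counters: dict[str, int] = {}

    @property
    def base(self) -> str:
        return self._base

    def mint(self, kind: str = "instance") -> Iri:
        n = self._counters.get(kind, 0)
        self._counters[kind] = n + 1
        tag = uuid.uuid5(uuid.NAMESPACE_URL, f"{self._seed}:{kind}:{n}").hex[:10]
        return Iri(f"{self._base}{kind}/{n:05d}-{tag}")


def mint_iri(kind: str, minter: IriMinter) -> Iri:
    """Mint a fresh IRI of the given kind (catalog key or ``instance``)."""
    return minter.mint(kind)


def make_instance(
    class_ref: TermRef,
    label: Optional[str] = None,
    minter: Optional[IriMinter] = None,
    term_catalog: Optional[TermCatalog] = None,
) -> Instance:
    """Create a fresh ontology individual instantiating ``class_ref``.

    If a term catalog is supplied the class's prefix must be registered in it;
    this is the guard that keeps descriptions inside the shared vocabulary.
    """
    if term_catalog is not None and not term_catalog.has_prefix(class_ref.prefix):
        raise TermCatalogError(
            f"prefix {class_ref.prefix!r} is not registered in the term catalog"
        )
    minter = minter or IriMinter()
    return Instance(minter.mint("instance"), class_ref, label)
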