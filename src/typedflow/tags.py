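"""Tag algebra: declarations, implication rules, valued tags, and ontology terms.

Tags are declarative properties of a stage's output — file formats (``ToyBam``,
``ToyVcf``) or metadata (``Sorted``, ``DupsMarked``).  A :class:`TagAlgebra`
collects tag declarations together with implication rules (``DeDuped`` implies
``DupsMarked``) and, optionally, an ontology of format/data terms whose is-a
hierarchy is folded into the implication graph.  Tag checking happens purely at
the workflow-graph level, before execution; file contents are never inspected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class TagError(Exception):
    """Base class for tag-algebra errors."""


class UnknownTagError(TagError, KeyError):
    """A tag identifier was used without being declared."""


class RedeclarationError(TagError):
    """A tag identifier was declared twice."""


class OntologyError(Exception):
    """Malformed ontology: cycles or dangling parent references."""


@dataclass(frozen=True)
class Tag:
    """A declared tag.

    Parameters
    ----------
    id:
        Unique identifier within an algebra (e.g. ``"ToyBam"``).
    extension:
        File extension for format tags (``"bam"``); ``None`` for pure
        metadata tags such as ``Sorted``.
    valued:
        Whether the tag carries a value (e.g. a reference-genome path).
    propagating:
        Whether, once present on a node, the tag automatically holds on
        every downstream node (e.g. ``DeDuped``).
    """

    id: str
    extension: str | None = None
    valued: bool = False
    propagating: bool = False


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    label: str
    parents: tuple[str, ...] = ()


_SHORTNAME_SPLIT = re.compile(r"[^0-9A-Za-z]+")


def short_name(label: str) -> str:
    """Convert an ontology term label to a CamelCase tag identifier.

    ``"FASTQ-illumina"`` becomes ``"FastqIllumina"``.
    """
    parts = [p for p in _SHORTNAME_SPLIT.split(label) if p]
    return "".join(p[:1].upper() + p[1:].lower() for p in parts)


class Ontology:
    """An acyclic is-a hierarchy of terms (a small format/data subset)."""

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self._check()

    def _check(self) -> None:
        for term in self.terms.values():
            for p in term.parents:
                if p not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} references missing parent {p!r}"
                    )
        # DFS cycle check
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms}
        for start in self.terms:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, i = stack[-1]
                parents = self.terms[node].parents
                if i < len(parents):
                    stack[-1] = (node, i + 1)
                    nxt = parents[i]
                    if colour[nxt] == GREY:
                        raise OntologyError(f"cycle through term {nxt!r}")
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK
                    stack.pop()

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, name: str) -> OntologyTerm:
        """Look a term up by raw id (``format_1931``) or short name."""
        if name in self.terms:
            return self.terms[name]
        for term in self.terms.values():
            if short_name(term.label) == name:
                return term
        raise OntologyError(f"unknown ontology term {name!r}")

    def ancestors(self, term_id: str) -> set[str]:
        """All transitive is-a ancestors of *term_id* (excluding itself)."""
        term = self.resolve(term_id)
        seen: set[str] = set()
        frontier = list(term.parents)
        while frontier:
            t = frontier.pop()
            if t in seen:
                continue
            seen.add(t)
            frontier.extend(self.terms[t].parents)
        return seen

    def tag_name(self, term_id: str) -> str:
        return short_name(self.resolve(term_id).label)


def load_edam(path: str | Path) -> Ontology:
    """Load an ontology subset from a tabular fixture (or ``.obo`` file).

    The tabular dialect has one term per line::

        term_id<TAB>label<TAB>parent_id,parent_id

    Blank lines and ``#`` comments are ignored.  Files ending in ``.obo``
    are parsed with :mod:`obonet` instead, keeping only is-a links.
    """
    path = Path(path)
    if path.suffix == ".obo":
        return _load_obo(path)
    terms: dict[str, OntologyTerm] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise OntologyError(f"{path}:{lineno}: expected id<TAB>label[<TAB>parents]")
        term_id, label = cols[0].strip(), cols[1].strip()
        parents = tuple(
            p.strip() for p in (cols[2].split(",") if len(cols) > 2 and cols[2].strip() else []) if p.strip()
        )
        if term_id in terms:
            raise OntologyError(f"{path}:{lineno}: duplicate term {term_id!r}")
        terms[term_id] = OntologyTerm(term_id, label, parents)
    return Ontology(terms)


def _load_obo(path: Path) -> Ontology:
    import obonet

    graph = obonet.read_obo(str(path))
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        tid = node.rsplit("/", 1)[-1]
        parents = tuple(
            p.rsplit("/", 1)[-1]
            for _, p, key in graph.out_edges(node, keys=True)
            if key == "is_a"
        )
        terms[tid] = OntologyTerm(tid, data.get("name", tid), parents)
    # drop dangling parents (the subset may clip the hierarchy)
    for tid, term in list(terms.items()):
        kept = tuple(p for p in term.parents if p in terms)
        if kept != term.parents:
            terms[tid] = OntologyTerm(term.id, term.label, kept)
    return Ontology(terms)


def bundled_edam_path() -> Path:
    """Path of the ontology subset shipped with the package."""
    return Path(__file__).parent / "data" / "edam_subset.tsv"


@dataclass
class TagAlgebra:
    """Mutable registry of tags, implications, and an optional ontology.

    Mutating methods return ``self`` so declarations chain fluently.
    """

    tags: dict[str, Tag] = field(default_factory=dict)
    implications: set[tuple[str, str]] = field(default_factory=set)
    edam: Ontology | None = None

    # -- declarations ------------------------------------------------------

    def declare_tag(
        self,
        tag_id: str,
        extension: str | None = None,
        valued: bool = False,
        propagating: bool = False,
    ) -> "TagAlgebra":
        if tag_id in self.tags:
            raise RedeclarationError(f"tag {tag_id!r} already declared")
        if not tag_id or not tag_id.replace("_", "").isalnum():
            raise TagError(f"tag id {tag_id!r} is not a valid identifier")
        self.tags[tag_id] = Tag(tag_id, extension, valued, propagating)
        return self

    def add_implication(self, antecedent: str, consequent: str) -> "TagAlgebra":
        self._require(antecedent)
        self._require(consequent)
        self.implications.add((antecedent, consequent))
        return self

    def _require(self, tag_id: str) -> Tag:
        try:
            return self.tags[tag_id]
        except KeyError:
            raise UnknownTagError(f"tag {tag_id!r} not declared") from None

    def __contains__(self, tag_id: str) -> bool:
        return tag_id in self.tags

    def extension_for(self, tag_id: str) -> str | None:
        return self._require(tag_id).extension

    def is_propagating(self, tag_id: str) -> bool:
        return self._require(tag_id).propagating

    def is_valued(self, tag_id: str) -> bool:
        return self._require(tag_id).valued

    # -- closure -----------------------------------------------------------

    def close(self, tags: Iterable[str]) -> frozenset[str]:
        """Least fixpoint of the implication rules over *tags*.

        Extensive, monotone, and idempotent; ontology ancestry participates
        through the implications installed by :meth:`attach_edam`.
        """
        result = set()
        for t in tags:
            self._require(t)
            result.add(t)
        changed = True
        while changed:
            changed = False
            for a, c in self.implications:
                if a in result and c not in result:
                    result.add(c)
                    changed = True
        return frozenset(result)

    # -- ontology ----------------------------------------------------------

    def attach_ontology(self, ontology: Ontology) -> "TagAlgebra":
        self.edam = ontology
        return self

    def _ensure_term_tag(self, term_id: str) -> str:
        assert self.edam is not None
        term = self.edam.resolve(term_id)
        name = short_name(term.label)
        if name not in self.tags:
            self.declare_tag(name)
        for parent in term.parents:
            pname = self._ensure_term_tag(parent)
            self.implications.add((name, pname))
        return name

    def attach_edam(self, tag_id: str, term_id: str) -> "TagAlgebra":
        """Associate *tag_id* with an ontology term.

        Installs ``tag_id ⇒ term`` plus ``term ⇒ parent`` edges along the
        whole ancestry, so closure reaches every ancestor: a tag attached to
        FASTQ-illumina also matches a requirement stated at the FASTQ level.
        """
        if self.edam is None:
            raise OntologyError("no ontology attached to this algebra")
        self._require(tag_id)
        term_tag = self._ensure_term_tag(term_id)
        self.implications.add((tag_id, term_tag))
        return self

    # -- YAML manifest -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TagAlgebra":
        """Build an algebra from a YAML manifest.

        Schema::

            tags:
              ToyBam: {extension: bam}
              Sorted: {}
              DeDuped: {propagating: true}
              Referenced: {valued: true, propagating: true}
            implications:
              - [DeDuped, DupsMarked]
            edam: path/to/subset.tsv      # optional
            edam_bindings:
              ToyFastq: FastqIllumina     # optional
        """
        import yaml

        spec = yaml.safe_load(Path(path).read_text()) or {}
        algebra = cls()
        for tag_id, opts in (spec.get("tags") or {}).items():
            opts = opts or {}
            algebra.declare_tag(
                tag_id,
                extension=opts.get("extension"),
                valued=bool(opts.get("valued", False)),
                propagating=bool(opts.get("propagating", False)),
            )
        for ant, cons in spec.get("implications") or []:
            algebra.add_implication(ant, cons)
        if spec.get("edam"):
            edam_path = Path(spec["edam"])
            if not edam_path.is_absolute():
                edam_path = Path(path).parent / edam_path
            algebra.attach_ontology(load_edam(edam_path))
        for tag_id, term in (spec.get("edam_bindings") or {}).items():
            algebra.attach_edam(tag_id, term)
        return algebra


def close_tags(algebra: TagAlgebra, tags: Iterable[str]) -> frozenset[str]:
    """Functional alias for :meth:`TagAlgebra.close`."""
    return algebra.close(tags)
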