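"""The workflow algebra: stages, forward composition, paths and tag flow.

A pipeline is an immutable expression tree.  ``source(...)`` roots a tree in
user-named files; ``expr >> stage`` composes a stage onto it (left-associative,
like a Unix pipe); ``with_all([...])`` bundles several expressions so a
downstream stage sees all their outputs.  Composition never fails on tag
mismatches — expressions are checked as a whole by :func:`typedflow.compiler.
validate`, mirroring the write-then-compile separation of statically typed
workflow code.

Tag flow rules
--------------
* a Source carries the implication closure of its declared tags;
* a Compose carries its stage's output tags, plus every *propagating* tag of
  the upstream node, plus any *transient* tags of the stage that already hold
  upstream — all closed under implications;
* a bundle (AllOf) guarantees only the intersection of its members' tags;
* valued tags (e.g. the reference-genome path) carry their value downstream,
  nearest setter wins, conflicting values in a bundle are an error.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

from . import naming
from .tags import TagAlgebra, TagError, UnknownTagError


class ConstructionError(Exception):
    """A pipeline expression could not be built (structural fault)."""


class TagValueConflictError(TagError):
    """A bundle carries two different values for the same valued tag."""


class AbsentValueError(TagError):
    """A valued tag was queried but never set upstream."""


class DefinitionError(Exception):
    """A stage definition is invalid (e.g. extension-less first output tag)."""


# ---------------------------------------------------------------------------
# Active tag algebra
# ---------------------------------------------------------------------------

_active_algebra: TagAlgebra | None = None


def activate(algebra: TagAlgebra) -> TagAlgebra:
    """Make *algebra* the default for subsequently built expressions."""
    global _active_algebra
    _active_algebra = algebra
    return algebra


def active_algebra() -> TagAlgebra:
    if _active_algebra is None:
        raise ConstructionError(
            "no active TagAlgebra: call typedflow.activate(algebra) first"
        )
    return _active_algebra


@contextlib.contextmanager
def using_algebra(algebra: TagAlgebra) -> Iterator[TagAlgebra]:
    global _active_algebra
    previous = _active_algebra
    _active_algebra = algebra
    try:
        yield algebra
    finally:
        _active_algebra = previous


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

Builder = Callable[[list[str], list[str], "PipelineExpr", object], None]


@dataclass(frozen=True)
class Stage:
    """A named unit of computation.

    ``builder(inputs, outputs, expr, ctx)`` is invoked by the engine with the
    resolved input and output paths, the full expression node (so it can look
    back along the pipeline, e.g. for valued tags), and a build context whose
    ``run`` method is the only sanctioned way to spawn processes.
    """

    name: str
    required_tags: frozenset[str] = frozenset()
    output_tags: tuple[str, ...] = ()
    transient_tags: frozenset[str] = frozenset()
    params: tuple[tuple[str, object], ...] = ()
    set_values: tuple[tuple[str, str], ...] = ()
    n_outputs: int = 1
    threads: int = 1
    resources: tuple[tuple[str, object], ...] = ()
    builder: Builder | None = None

    def __post_init__(self) -> None:
        if not self.name or "/" in self.name or self.name != self.name.strip():
            raise ConstructionError(f"stage name {self.name!r} not filesystem-safe")
        if not self.output_tags:
            raise ConstructionError(f"stage {self.name!r} declares no output tags")
        if self.n_outputs < 1:
            raise ConstructionError(f"stage {self.name!r}: n_outputs must be >= 1")
        if self.threads < 1:
            raise ConstructionError(f"stage {self.name!r}: threads must be >= 1")

    def param(self, key: str, default: object = None) -> object:
        return dict(self.params).get(key, default)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        ps = ", ".join(f"{k}={v!r}" for k, v in self.params)
        return f"Stage({self.name}{', ' if ps else ''}{ps})"


# Scheduling knobs routed out of ``params`` so they stay out of digests.
_RESOURCE_KEYS = ("memory_mb", "walltime_s", "queue")


@dataclass(frozen=True)
class StageFactory:
    """A parameterizable stage constructor, as returned by :func:`define_stage`.

    Calling the factory with keyword parameters yields a concrete
    :class:`Stage`; ``threads`` and resource keys (``memory_mb``,
    ``walltime_s``, ``queue``) are routed to scheduling fields, everything
    else is a semantic parameter that participates in output naming.
    """

    name: str
    required_tags: frozenset[str]
    output_tags: tuple[str, ...]
    transient_tags: frozenset[str]
    builder: Builder | None
    defaults: tuple[tuple[str, object], ...] = ()
    n_outputs_param: str | None = None

    def __call__(self, **overrides: object) -> Stage:
        merged = dict(self.defaults)
        merged.update(overrides)
        threads = int(merged.pop("threads", 1))
        resources = tuple(
            (k, merged.pop(k)) for k in _RESOURCE_KEYS if k in merged
        )
        set_values = tuple(sorted(dict(merged.pop("set_values", {})).items()))  # type: ignore[arg-type]
        n_outputs = 1
        if self.n_outputs_param is not None:
            n_outputs = int(merged[self.n_outputs_param])  # semantic → stays in params
        params = tuple(sorted(merged.items()))
        return Stage(
            name=self.name,
            required_tags=self.required_tags,
            output_tags=self.output_tags,
            transient_tags=self.transient_tags,
            params=params,
            set_values=set_values,
            n_outputs=n_outputs,
            threads=threads,
            resources=resources,
            builder=self.builder,
        )


def define_stage(
    name: str,
    required_tags: Iterable[str],
    output_tags: Sequence[str],
    transient_tags: Iterable[str] = (),
    builder: Builder | None = None,
    defaults: Mapping[str, object] | None = None,
    n_outputs_param: str | None = None,
    algebra: TagAlgebra | None = None,
) -> StageFactory:
    """Define a stage family with hash naming and tag bookkeeping wired in.

    The first output tag must be registered with a file extension in the
    (active) tag algebra — it determines the extension of the stage's managed
    outputs.
    """
    algebra = algebra or active_algebra()
    output_tags = tuple(output_tags)
    if not output_tags:
        raise DefinitionError(f"stage {name!r}: output_tags must be non-empty")
    for t in (*required_tags, *output_tags, *transient_tags):
        if t not in algebra:
            raise UnknownTagError(f"stage {name!r} uses undeclared tag {t!r}")
    if not algebra.extension_for(output_tags[0]):
        raise DefinitionError(
            f"stage {name!r}: first output tag {output_tags[0]!r} has no "
            "registered file extension"
        )
    return StageFactory(
        name=name,
        required_tags=frozenset(required_tags),
        output_tags=output_tags,
        transient_tags=frozenset(transient_tags),
        builder=builder,
        defaults=tuple(sorted((defaults or {}).items())),
        n_outputs_param=n_outputs_param,
    )


# ---------------------------------------------------------------------------
# Pipeline expressions
# ---------------------------------------------------------------------------


class PipelineExpr:
    """Base class of the immutable workflow expression tree."""

    algebra: TagAlgebra

    def __rshift__(self, stage: "Stage | StageFactory") -> "Compose":
        return compose(self, stage)


@dataclass(frozen=True, eq=False)
class Source(PipelineExpr):
    paths: tuple[str, ...]
    tags: frozenset[str]
    values: tuple[tuple[str, str], ...] = ()
    algebra: TagAlgebra = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass(frozen=True, eq=False)
class Compose(PipelineExpr):
    upstream: PipelineExpr
    stage: Stage

    @property
    def algebra(self) -> TagAlgebra:  # type: ignore[override]
        return self.upstream.algebra


@dataclass(frozen=True, eq=False)
class AllOf(PipelineExpr):
    parts: tuple[PipelineExpr, ...]

    @property
    def algebra(self) -> TagAlgebra:  # type: ignore[override]
        return self.parts[0].algebra


@dataclass(frozen=True, eq=False)
class Select(PipelineExpr):
    """One output of a multi-output expression (see ``combinators.split``)."""

    parent: PipelineExpr
    index: int

    @property
    def algebra(self) -> TagAlgebra:  # type: ignore[override]
        return self.parent.algebra


@dataclass(frozen=True, eq=False)
class Named(PipelineExpr):
    """An expression whose managed outputs are copied to user-visible names."""

    inner: PipelineExpr
    names: tuple[str, ...]

    @property
    def algebra(self) -> TagAlgebra:  # type: ignore[override]
        return self.inner.algebra


def source(
    paths: Sequence[str],
    tags: Iterable[str] = (),
    values: Mapping[str, str] | None = None,
    algebra: TagAlgebra | None = None,
) -> Source:
    """Root a pipeline in user-named input files carrying the given tags.

    ``values`` assigns valued tags (e.g. ``{"Referenced": "ref.fa"}``); their
    keys are implicitly part of the tag set.
    """
    algebra = algebra or active_algebra()
    paths = tuple(str(p) for p in paths)
    if not paths:
        raise ConstructionError("source requires at least one input path")
    values = dict(values or {})
    tagset = set(tags) | set(values)
    for t in tagset:
        if t not in algebra:
            raise UnknownTagError(f"tag {t!r} not declared in the active algebra")
    for t, _ in values.items():
        if not algebra.is_valued(t):
            raise TagError(f"tag {t!r} is not valued; cannot assign it a value")
    return Source(
        paths=paths,
        tags=frozenset(tagset),
        values=tuple(sorted((k, str(v)) for k, v in values.items())),
        algebra=algebra,
    )


def compose(upstream: PipelineExpr, stage: Stage | StageFactory) -> Compose:
    """Forward-compose a stage onto an expression (never validates tags)."""
    if isinstance(stage, StageFactory):
        stage = stage()
    if not isinstance(stage, Stage):
        raise ConstructionError(f"cannot compose {stage!r}: not a Stage")
    if not isinstance(upstream, PipelineExpr):
        raise ConstructionError(f"cannot compose onto {upstream!r}")
    return Compose(upstream=upstream, stage=stage)


# ---------------------------------------------------------------------------
# Derived attributes: paths, tags, values
# ---------------------------------------------------------------------------


def output_paths(expr: PipelineExpr) -> list[str]:
    """File paths produced by *expr* — literal for sources, hash-named for
    composed stages, concatenated for bundles.  Pure and deterministic."""
    if isinstance(expr, Source):
        return list(expr.paths)
    if isinstance(expr, Compose):
        stage = expr.stage
        ext = expr.algebra.extension_for(stage.output_tags[0])
        return naming.intermediate_paths(
            output_paths(expr.upstream),
            stage.name,
            stage.params,
            stage.n_outputs,
            ext,
        )
    if isinstance(expr, AllOf):
        out: list[str] = []
        for part in expr.parts:
            out.extend(output_paths(part))
        return out
    if isinstance(expr, Select):
        return [output_paths(expr.parent)[expr.index]]
    if isinstance(expr, Named):
        return list(expr.names)
    raise TypeError(f"not a pipeline expression: {expr!r}")


def effective_tags(expr: PipelineExpr) -> frozenset[str]:
    """Tags guaranteed to hold on *expr*'s outputs (implication-closed)."""
    algebra = expr.algebra
    if isinstance(expr, Source):
        return algebra.close(expr.tags)
    if isinstance(expr, Compose):
        upstream = effective_tags(expr.upstream)
        stage = expr.stage
        carried = {t for t in upstream if algebra.is_propagating(t)}
        carried |= stage.transient_tags & upstream
        return algebra.close(set(stage.output_tags) | carried)
    if isinstance(expr, AllOf):
        tag_values(expr)  # surfaces valued-tag conflicts
        sets = [effective_tags(p) for p in expr.parts]
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out
    if isinstance(expr, Select):
        return effective_tags(expr.parent)
    if isinstance(expr, Named):
        return effective_tags(expr.inner)
    raise TypeError(f"not a pipeline expression: {expr!r}")


def tag_values(expr: PipelineExpr) -> dict[str, str]:
    """Values of valued tags in scope at *expr* (nearest setter wins)."""
    if isinstance(expr, Source):
        return dict(expr.values)
    if isinstance(expr, Compose):
        vals = tag_values(expr.upstream)
        vals.update(dict(expr.stage.set_values))
        return vals
    if isinstance(expr, AllOf):
        merged: dict[str, str] = {}
        for part in expr.parts:
            for key, value in tag_values(part).items():
                if key in merged and merged[key] != value:
                    raise TagValueConflictError(
                        f"valued tag {key!r} has conflicting values in bundle: "
                        f"{merged[key]!r} vs {value!r}"
                    )
                merged[key] = value
        return merged
    if isinstance(expr, Select):
        return tag_values(expr.parent)
    if isinstance(expr, Named):
        return tag_values(expr.inner)
    raise TypeError(f"not a pipeline expression: {expr!r}")


def get_valued(expr: PipelineExpr, tag_id: str) -> str:
    """Retrieve the value of a valued tag set anywhere upstream of *expr*.

    The value survives arbitrarily many compositions; the nearest upstream
    setter wins if it was re-set mid-pipeline.
    """
    values = tag_values(expr)
    if tag_id not in values:
        raise AbsentValueError(
            f"valued tag {tag_id!r} is not set on pipeline {stage_path(expr)!r}"
        )
    return values[tag_id]


def _walk_upstream(expr: PipelineExpr) -> Iterator[PipelineExpr]:
    """Nodes strictly upstream of *expr*, nearest first."""
    if isinstance(expr, Compose):
        yield expr.upstream
        yield from _walk_upstream(expr.upstream)
    elif isinstance(expr, AllOf):
        for part in expr.parts:
            yield part
            yield from _walk_upstream(part)
    elif isinstance(expr, Select):
        yield expr.parent
        yield from _walk_upstream(expr.parent)
    elif isinstance(expr, Named):
        yield expr.inner
        yield from _walk_upstream(expr.inner)


def upstream_products(expr: PipelineExpr, predicate: Iterable[str]) -> list[str]:
    """Paths of the nearest upstream node whose tags satisfy *predicate*.

    Lets a builder refer backwards along the pipeline, e.g. a variant
    annotator fetching the alignments used for calling.  An empty predicate
    matches the immediate upstream; no match yields an empty list.
    """
    wanted = frozenset(predicate)
    for node in _walk_upstream(expr):
        if wanted <= effective_tags(node):
            return output_paths(node)
    return []


def stage_path(expr: PipelineExpr) -> list[str]:
    """Stage names from source to *expr*, repeats disambiguated by index."""
    names: list[str] = []

    def walk(node: PipelineExpr) -> None:
        if isinstance(node, Compose):
            walk(node.upstream)
            names.append(node.stage.name)
        elif isinstance(node, (Select,)):
            walk(node.parent)
        elif isinstance(node, Named):
            walk(node.inner)
        # Source / AllOf contribute no names (bundles restart the path)

    walk(expr)
    counts: dict[str, int] = {}
    out = []
    for n in names:
        counts[n] = counts.get(n, 0) + 1
        out.append(n if counts[n] == 1 else f"{n}[{counts[n]}]")
    return out


def walk_nodes(expr: PipelineExpr) -> Iterator[PipelineExpr]:
    """Post-order traversal of every node in the expression tree."""
    if isinstance(expr, Compose):
        yield from walk_nodes(expr.upstream)
    elif isinstance(expr, AllOf):
        for part in expr.parts:
            yield from walk_nodes(part)
    elif isinstance(expr, Select):
        yield from walk_nodes(expr.parent)
    elif isinstance(expr, Named):
        yield from walk_nodes(expr.inner)
    yield expr


# ---------------------------------------------------------------------------
# Diagnostics (surface for pre-execution validation findings)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding.

    ``stage_path`` locates the offending node; error diagnostics carry the
    missing tags or a structural fault description in ``message``.
    """

    severity: str  # "error" | "warning"
    stage_path: tuple[str, ...]
    missing_tags: frozenset[str]
    message: str

    def __post_init__(self) -> None:
        if self.severity == "error" and not self.missing_tags and not self.message:
            raise ConstructionError("error diagnostic needs tags or a message")

    def render(self) -> str:
        where = " -> ".join(self.stage_path) or "<source>"
        tags = f" missing tags: {{{', '.join(sorted(self.missing_tags))}}}" if self.missing_tags else ""
        return f"{self.severity}: [{where}]{tags} {self.message}".rstrip()

    def to_json(self) -> dict:
        return {
            "severity": self.severity,
            "stage_path": list(self.stage_path),
            "missing_tags": sorted(self.missing_tags),
            "message": self.message,
        }
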