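"""Whole-pipeline validation and compilation to deduplicated build rules.

``validate`` is the pre-execution analogue of compile-time type checking: it
walks every composition in an expression forest and reports *all* stages whose
required tags are not guaranteed by their upstream, plus valued-tag conflicts
and managed-path collisions.  ``compile_rules`` refuses to compile while any
error diagnostic is outstanding — the library's contract is "well-tagged or no
rules".  Compilation is post-order, one rule per composed stage, with a seen
set keyed on the output-path sequence so shared prefixes across concurrent
workflows compile exactly once.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import (
    AllOf,
    Compose,
    Diagnostic,
    Named,
    PipelineExpr,
    Select,
    Source,
    TagValueConflictError,
    effective_tags,
    output_paths,
    stage_path,
    tag_values,
    walk_nodes,
)
from .engine import Rule, RuleSet
from .executors import Resources


class CompileError(Exception):
    """Compilation refused; carries the outstanding diagnostics."""

    def __init__(self, diagnostics: Sequence[Diagnostic]):
        self.diagnostics = list(diagnostics)
        lines = "\n".join(d.render() for d in self.diagnostics)
        super().__init__(f"workflow failed validation:\n{lines}")


@dataclass
class CompileState:
    """Dedup state shared across one compilation session.

    ``seen`` holds the output-path sequences already compiled; because managed
    names fold in stage identity and semantic parameters, identical sequences
    imply identical actions.
    """

    seen: set[tuple[str, ...]] = field(default_factory=set)


def _as_exprs(exprs: PipelineExpr | Iterable[PipelineExpr]) -> list[PipelineExpr]:
    if isinstance(exprs, PipelineExpr):
        return [exprs]
    return list(exprs)


def validate(exprs: PipelineExpr | Iterable[PipelineExpr]) -> list[Diagnostic]:
    """Check a workflow before any rule is compiled or run.

    Returns every violation (missing required tags, valued-tag conflicts in
    bundles, managed-path collisions); an empty list means the whole workflow
    is well-tagged.
    """
    diagnostics: list[Diagnostic] = []
    path_owner: dict[str, tuple] = {}
    for expr in _as_exprs(exprs):
        for node in walk_nodes(expr):
            if isinstance(node, Compose):
                try:
                    upstream_tags = effective_tags(node.upstream)
                except TagValueConflictError as exc:
                    diagnostics.append(
                        Diagnostic("error", tuple(stage_path(node)), frozenset(), str(exc))
                    )
                    continue
                missing = node.stage.required_tags - upstream_tags
                if missing:
                    diagnostics.append(
                        Diagnostic(
                            "error",
                            tuple(stage_path(node)),
                            frozenset(missing),
                            f"stage {node.stage.name!r} requires tags not "
                            "guaranteed by its upstream",
                        )
                    )
                # managed-path collision check
                key = (
                    node.stage.name,
                    node.stage.params,
                    tuple(output_paths(node.upstream)),
                )
                for p in output_paths(node):
                    owner = path_owner.setdefault(p, key)
                    if owner != key:
                        diagnostics.append(
                            Diagnostic(
                                "error",
                                tuple(stage_path(node)),
                                frozenset(),
                                f"managed path collision on {p!r}",
                            )
                        )
            elif isinstance(node, AllOf):
                try:
                    tag_values(node)
                except TagValueConflictError as exc:
                    diagnostics.append(
                        Diagnostic("error", tuple(stage_path(node)), frozenset(), str(exc))
                    )
            elif isinstance(node, Named):
                if len(node.names) != len(output_paths(node.inner)):
                    diagnostics.append(
                        Diagnostic(
                            "error",
                            tuple(stage_path(node)),
                            frozenset(),
                            f"out() got {len(node.names)} names for "
                            f"{len(output_paths(node.inner))} outputs",
                        )
                    )
    return diagnostics


def diagnostics_to_json(diagnostics: Sequence[Diagnostic]) -> str:
    return json.dumps([d.to_json() for d in diagnostics], indent=2)


def render_diagnostics(diagnostics: Sequence[Diagnostic]) -> str:
    if not diagnostics:
        return "workflow is well-tagged"
    return "\n".join(d.render() for d in diagnostics)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def _stage_action(node: Compose):
    inputs = list(output_paths(node.upstream))
    outputs = list(output_paths(node))

    def action(ctx) -> None:
        builder = node.stage.builder
        if builder is None:
            raise CompileError([])  # pragma: no cover - guarded at compile
        builder(inputs, outputs, node, ctx)

    return action


def _copy_action(src: str, dst: str):
    def action(ctx) -> None:
        shutil.copyfile(src, dst)

    return action


def _compile_node(node: PipelineExpr, ruleset: RuleSet, state: CompileState) -> None:
    if isinstance(node, Source):
        return
    if isinstance(node, Compose):
        _compile_node(node.upstream, ruleset, state)
        outs = tuple(output_paths(node))
        if outs in state.seen:
            return
        state.seen.add(outs)
        if node.stage.builder is None:
            raise CompileError(
                [
                    Diagnostic(
                        "error",
                        tuple(stage_path(node)),
                        frozenset(),
                        f"stage {node.stage.name!r} has no builder",
                    )
                ]
            )
        res = dict(node.stage.resources)
        ruleset.add_rule(
            Rule(
                outputs=outs,
                static_deps=tuple(output_paths(node.upstream)),
                action=_stage_action(node),
                name=".".join(["", *stage_path(node)])[1:] or node.stage.name,
                resources=Resources(
                    threads=node.stage.threads,
                    memory_mb=int(res.get("memory_mb", 1024)),
                    walltime_s=res.get("walltime_s"),
                    queue=res.get("queue"),
                ),
            )
        )
        return
    if isinstance(node, AllOf):
        for part in node.parts:
            _compile_node(part, ruleset, state)
        return
    if isinstance(node, Select):
        _compile_node(node.parent, ruleset, state)
        return
    if isinstance(node, Named):
        _compile_node(node.inner, ruleset, state)
        managed = output_paths(node.inner)
        for src, dst in zip(managed, node.names):
            key = (dst,)
            if key in state.seen:
                continue
            state.seen.add(key)
            ruleset.add_rule(
                Rule(
                    outputs=(dst,),
                    static_deps=(src,),
                    action=_copy_action(src, dst),
                    name=f"out:{dst}",
                )
            )
        return
    raise TypeError(f"not a pipeline expression: {node!r}")


def compile_rules(
    exprs: PipelineExpr | Iterable[PipelineExpr],
    state: CompileState | None = None,
) -> RuleSet:
    """Compile validated expressions to a deduplicated rule set.

    Raises :class:`CompileError` if validation reports any error — compiling
    an unvalidated workflow is itself an error.
    """
    exprs = _as_exprs(exprs)
    diagnostics = [d for d in validate(exprs) if d.severity == "error"]
    if diagnostics:
        raise CompileError(diagnostics)
    state = state or CompileState()
    ruleset = RuleSet()
    for expr in exprs:
        _compile_node(expr, ruleset, state)
    return ruleset


def compile_and_want(
    exprs: PipelineExpr | Iterable[PipelineExpr],
    state: CompileState | None = None,
) -> tuple[RuleSet, list[str]]:
    """Compile and mark every expression's final outputs as wanted targets."""
    exprs = _as_exprs(exprs)
    ruleset = compile_rules(exprs, state)
    targets: list[str] = []
    for expr in exprs:
        for p in output_paths(expr):
            if p not in targets:
                targets.append(p)
    ruleset.want(targets)
    return ruleset, targets
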