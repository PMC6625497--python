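"""Explicit output naming, scatter–gather, and two-phase dynamic workflows.

``out`` gives a pipeline's final managed files user-visible names (by copy, so
the hash-named originals stay valid for the build database).  ``split`` and
``with_all`` are mutual inverses for scatter–gather: ``split`` turns one
multi-output expression into per-shard expressions that can be processed
independently, ``with_all`` bundles expressions back together so a gather
stage sees all their outputs.  ``execute_workflow`` is the one-call
convenience (validate → compile → build) that, invoked repeatedly against the
same database, realizes dynamic workflows as two static builds with host
logic in between.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    AllOf,
    ConstructionError,
    Named,
    PipelineExpr,
    Select,
    output_paths,
)
from .compiler import CompileError, compile_and_want, validate
from .engine import BuildReport, build
from .executors import Executor
from . import naming


def out(expr: PipelineExpr, names: Sequence[str]) -> Named:
    """Name the outputs of *expr* with user-visible paths.

    Appends copy rules from the managed hash-named files to *names*; tags are
    unchanged (naming is tag-neutral).  The name count must match the
    expression's output arity.
    """
    names = tuple(str(n) for n in names)
    arity = len(output_paths(expr))
    if len(names) != arity:
        raise ConstructionError(
            f"out() got {len(names)} names for an expression with {arity} outputs"
        )
    return Named(inner=expr, names=names)


def split(expr: PipelineExpr) -> list[PipelineExpr]:
    """Split a multi-output expression into one expression per output path.

    Each part carries the parent's effective tags and a single path, in the
    parent's output order (so downstream gathers are deterministic).
    Composing further stages onto each part is independent.
    """
    paths = output_paths(expr)
    if len(paths) == 1:
        return [Select(parent=expr, index=0)]
    return [Select(parent=expr, index=i) for i in range(len(paths))]


def with_all(parts: Iterable[PipelineExpr]) -> PipelineExpr:
    """Bundle expressions so a downstream stage sees all their outputs.

    The inverse of :func:`split`: ``with_all(split(e))`` has exactly the
    paths and tags of ``e``.  A bundle guarantees only the tags every member
    guarantees (set intersection).
    """
    parts = tuple(parts)
    if not parts:
        raise ConstructionError("with_all requires at least one expression")
    return AllOf(parts=parts)


def execute_workflow(
    exprs: PipelineExpr | Iterable[PipelineExpr],
    jobs: int = 1,
    workdir: str | None = None,
    db_path: str | Path | None = None,
    executor: Executor | None = None,
    keep_going: bool = False,
) -> BuildReport:
    """Validate, compile, and build a workflow in one call.

    Safe to call repeatedly within a session against the same database: the
    second call rebuilds nothing that is still up to date.  Run phase one,
    inspect its outputs (e.g. count assembled contigs), construct phase two
    from what you find, and call again — that is the supported mechanism for
    workflows whose later shape depends on earlier results.
    """
    if workdir is not None:
        with naming.use_workdir(str(workdir)):
            return execute_workflow(
                exprs, jobs=jobs, db_path=db_path, executor=executor,
                keep_going=keep_going,
            )
    diagnostics = [d for d in validate(exprs) if d.severity == "error"]
    if diagnostics:
        raise CompileError(diagnostics)
    ruleset, targets = compile_and_want(exprs)
    managed = Path(naming.settings.workdir)
    managed.mkdir(parents=True, exist_ok=True)
    if db_path is None:
        db_path = managed / "build.db.jsonl"
    return build(
        ruleset,
        targets,
        jobs=jobs,
        db_path=db_path,
        executor=executor,
        keep_going=keep_going,
    )
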