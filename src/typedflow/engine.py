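"""Make-like incremental build engine with a content-digest database.

Rules pair output paths with an action and static input dependencies; actions
may declare additional dependencies mid-run via ``ctx.need`` (the make-style
dynamic dependency mechanism), and extrinsic *pattern rules* satisfy needed
paths by filename glob — e.g. an index side-product — without appearing in any
pipeline expression.

Up-to-date checks use SHA-1 content digests of files, not mtimes (mtime+size
is kept only as a fast path), so restored or copied trees rebuild correctly.
The database is JSON-lines, one entry per output path, rewritten atomically
after every completed rule: an interrupted build resumes from the last
completed rule, and a corrupt database degrades to a full rebuild, never to a
wrong reuse.  Ready rules are dispatched in lexicographic order of first
output path, and parallel execution (``jobs`` worker threads) is contracted
to produce byte-identical results to a serial run.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
import logging
import os
import re
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .executors import Executor, ExecutionError, Resources, local_executor, run as _exec_run

log = logging.getLogger("typedflow.engine")


class BuildError(Exception):
    """Base class for build failures."""


class CycleError(BuildError):
    """The dependency graph contains a cycle; carries the cycle's paths."""

    def __init__(self, cycle: Sequence[str]):
        super().__init__("dependency cycle: " + " -> ".join(cycle))
        self.cycle = list(cycle)


class MissingRuleError(BuildError):
    """A needed path has no rule, matches no pattern, and does not exist."""


class AmbiguousPatternError(BuildError):
    """Two pattern rules match one needed path."""


class DuplicateRuleError(BuildError):
    """Two rules claim the same output path."""


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

Action = Callable[["BuildContext"], None]


@dataclass(frozen=True)
class Rule:
    """A build unit: produce ``outputs`` from ``static_deps`` via ``action``."""

    outputs: tuple[str, ...]
    static_deps: tuple[str, ...]
    action: Action
    name: str = ""
    resources: Resources | None = None

    def __post_init__(self) -> None:
        if not self.outputs:
            raise BuildError("rule with no outputs")

    @property
    def rule_id(self) -> str:
        return self.name or self.outputs[0]

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(b"rule\x00")
        for p in self.outputs:
            h.update(p.encode() + b"\x00")
        h.update(b"deps\x00")
        for p in self.static_deps:
            h.update(p.encode() + b"\x00")
        h.update(self.name.encode())
        return h.hexdigest()


@dataclass(frozen=True)
class PatternRule:
    """Extrinsic rule: build any needed path matching a one-wildcard glob."""

    pattern: str
    action: Callable[["BuildContext", str, str], None]  # (ctx, stem, output)

    def __post_init__(self) -> None:
        if self.pattern.count("*") != 1:
            raise BuildError(
                f"pattern {self.pattern!r} must contain exactly one '*' stem"
            )

    def match(self, path: str) -> str | None:
        """Return the stem if *path* matches, else ``None``."""
        if not fnmatch.fnmatchcase(path, self.pattern):
            return None
        regex = re.escape(self.pattern).replace(r"\*", "(.*)")
        m = re.fullmatch(regex, path)
        return m.group(1) if m else None


class RuleSet:
    """Compiled build units plus pattern rules and wanted targets."""

    def __init__(self) -> None:
        self.rules: list[Rule] = []
        self.pattern_rules: list[PatternRule] = []
        self.wanted: list[str] = []
        self._outputs: dict[str, Rule] = {}

    def add_rule(self, rule: Rule) -> Rule:
        for out in rule.outputs:
            if out in self._outputs:
                raise DuplicateRuleError(f"two rules declare output {out!r}")
        for out in rule.outputs:
            self._outputs[out] = rule
        self.rules.append(rule)
        return rule

    def add_pattern_rule(
        self, pattern: str, action: Callable[["BuildContext", str, str], None]
    ) -> PatternRule:
        pr = PatternRule(pattern, action)
        self.pattern_rules.append(pr)
        return pr

    def rule_for(self, path: str) -> Rule | None:
        return self._outputs.get(path)

    def want(self, paths: Iterable[str]) -> None:
        for p in paths:
            if p not in self.wanted:
                self.wanted.append(p)

    def __len__(self) -> int:
        return len(self.rules)


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------


def file_digest(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class BuildDatabase:
    """Persisted per-file digests enabling minimal incremental rebuilds.

    JSON-lines; each line ``{"path":..., "digest":..., "fingerprint":...,
    "stat": [size, mtime_ns], "deps": {path: digest}}``.  Corrupt lines are
    dropped (degrading to rebuild of the affected outputs).
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.entries: dict[str, dict] = {}
        self._lock = threading.Lock()
        self._load()

    def _load(self) -> None:
        if not self.path.exists():
            return
        try:
            text = self.path.read_text()
        except OSError:
            return
        for line in text.splitlines():
            if not line.strip():
                continue
            try:
                entry = json.loads(line)
                self.entries[entry["path"]] = entry
            except (json.JSONDecodeError, KeyError, TypeError):
                continue  # corrupt line → treat as absent

    def record(self, path: str, fingerprint: str, deps: dict[str, str]) -> None:
        entry = {
            "path": path,
            "digest": file_digest(path),
            "fingerprint": fingerprint,
            "stat": _stat_sig(path),
            "deps": deps,
        }
        with self._lock:
            self.entries[path] = entry
            self._flush()

    def forget(self, path: str) -> None:
        with self._lock:
            if self.entries.pop(path, None) is not None:
                self._flush()

    def _flush(self) -> None:
        tmp = self.path.with_suffix(self.path.suffix + ".tmp")
        tmp.parent.mkdir(parents=True, exist_ok=True)
        with open(tmp, "w") as fh:
            for entry in self.entries.values():
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        os.replace(tmp, self.path)

    def unchanged(self, path: str, expected_digest: str) -> bool:
        """Has *path*'s content digest stayed *expected_digest*?"""
        if not os.path.exists(path):
            return False
        entry = self.entries.get(path)
        if entry is not None and entry.get("digest") == expected_digest:
            if entry.get("stat") == _stat_sig(path):
                return True  # fast path: size+mtime untouched
        return file_digest(path) == expected_digest


def _stat_sig(path: str) -> list[int]:
    st = os.stat(path)
    return [st.st_size, st.st_mtime_ns]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

BUILT, SKIPPED, FAILED = "built", "skipped-up-to-date", "failed"


@dataclass
class ReportEntry:
    rule: str
    outputs: list[str]
    status: str
    seconds: float
    deps: list[str]
    error: str | None = None


@dataclass
class BuildReport:
    """Per-rule outcome of one build invocation."""

    entries: list[ReportEntry] = field(default_factory=list)
    digest_algorithm: str = "sha1"

    def count(self, status: str) -> int:
        return sum(1 for e in self.entries if e.status == status)

    @property
    def ok(self) -> bool:
        return self.count(FAILED) == 0

    def to_json(self) -> dict:
        return {
            "digest_algorithm": self.digest_algorithm,
            "summary": {
                "built": self.count(BUILT),
                "skipped": self.count(SKIPPED),
                "failed": self.count(FAILED),
            },
            "rules": [
                {
                    "rule": e.rule,
                    "outputs": e.outputs,
                    "status": e.status,
                    "seconds": round(e.seconds, 4),
                    "deps": e.deps,
                    **({"error": e.error} if e.error else {}),
                }
                for e in self.entries
            ],
        }

    def render_text(self) -> str:
        lines = [
            f"build report ({self.digest_algorithm} digests): "
            f"{self.count(BUILT)} built, {self.count(SKIPPED)} up to date, "
            f"{self.count(FAILED)} failed"
        ]
        for e in sorted(self.entries, key=lambda e: e.rule):
            lines.append(f"  [{e.status:>18}] {e.rule} ({e.seconds:.3f}s)")
            if e.error:
                lines.append(f"      error: {e.error}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Build contexts
# ---------------------------------------------------------------------------


class BuildContext:
    """Handle passed to running actions: dynamic deps and command execution."""

    def __init__(self, build: "_Build", rule: Rule):
        self._build = build
        self._rule = rule
        self.dynamic_deps: list[str] = []
        self.executor: Executor = build.executor

    def need(self, paths: Iterable[str]) -> None:
        """Block until each path is up to date, building it if possible."""
        for p in [str(p) for p in paths]:
            self._build.bring_up_to_date(p)
            if p not in self.dynamic_deps:
                self.dynamic_deps.append(p)

    def run(self, tokens: Sequence[str], resources: Resources | None = None) -> None:
        """Execute a command through the configured executor."""
        _exec_run(
            self.executor,
            tokens,
            resources=resources or self._rule.resources,
            rule_id=self._rule.rule_id,
        )


def need(ctx: BuildContext, paths: Iterable[str]) -> None:
    """Functional alias for :meth:`BuildContext.need`."""
    ctx.need(paths)


# ---------------------------------------------------------------------------
# The build orchestrator
# ---------------------------------------------------------------------------

_PENDING, _RUNNING, _DONE, _FAILED = range(4)


class _RuleState:
    __slots__ = ("state", "event", "error", "status")

    def __init__(self) -> None:
        self.state = _PENDING
        self.event = threading.Event()
        self.error: BaseException | None = None
        self.status = ""


class _Build:
    def __init__(
        self,
        ruleset: RuleSet,
        targets: Sequence[str],
        jobs: int,
        db: BuildDatabase,
        executor: Executor,
        keep_going: bool,
    ):
        self.ruleset = ruleset
        self.targets = [str(t) for t in targets]
        self.jobs = max(1, int(jobs))
        self.db = db
        self.executor = executor
        self.keep_going = keep_going
        self.report = BuildReport()
        self._report_lock = threading.Lock()
        self._state_lock = threading.Lock()
        self._states: dict[int, _RuleState] = {}
        self._synth: dict[str, Rule] = {}  # pattern-instantiated rules by output
        self._stack = threading.local()  # per-thread rule stack (cycle detection)
        self.stop = threading.Event()

    # -- resolution --------------------------------------------------------

    def _resolve(self, path: str) -> Rule | None:
        rule = self.ruleset.rule_for(path)
        if rule is not None:
            return rule
        with self._state_lock:
            if path in self._synth:
                return self._synth[path]
        matches = [
            (pr, stem)
            for pr in self.ruleset.pattern_rules
            if (stem := pr.match(path)) is not None
        ]
        if len(matches) > 1:
            raise AmbiguousPatternError(
                f"patterns {[m[0].pattern for m in matches]!r} all match {path!r}"
            )
        if matches:
            pr, stem = matches[0]
            rule = Rule(
                outputs=(path,),
                static_deps=(),
                action=lambda ctx, pr=pr, stem=stem, path=path: pr.action(ctx, stem, path),
                name=f"pattern:{pr.pattern}:{path}",
            )
            with self._state_lock:
                rule = self._synth.setdefault(path, rule)
            return rule
        return None

    def bring_up_to_date(self, path: str) -> None:
        rule = self._resolve(path)
        if rule is None:
            if os.path.exists(path):
                return  # plain source file
            raise MissingRuleError(
                f"no rule builds {path!r} and the file does not exist"
            )
        self.run_rule(rule)

    # -- per-rule execution ------------------------------------------------

    def _state_for(self, rule: Rule) -> _RuleState:
        with self._state_lock:
            return self._states.setdefault(id(rule), _RuleState())

    def run_rule(self, rule: Rule) -> None:
        st = self._state_for(rule)
        stack: list[int] = getattr(self._stack, "rules", None) or []
        if id(rule) in stack:
            raise CycleError([*(self._id_to_output(i) for i in stack), rule.outputs[0]])
        while True:
            with self._state_lock:
                if st.state == _DONE:
                    return
                if st.state == _FAILED:
                    raise st.error  # type: ignore[misc]
                if st.state == _PENDING:
                    st.state = _RUNNING
                    break
            st.event.wait()
        self._stack.rules = [*stack, id(rule)]
        started = time.monotonic()
        try:
            for dep in rule.static_deps:
                self.bring_up_to_date(dep)
            if self._up_to_date(rule):
                status, error = SKIPPED, None
            else:
                self._execute(rule)
                status, error = BUILT, None
        except BaseException as exc:
            with self._state_lock:
                st.state = _FAILED
                st.error = exc
            if not self.keep_going:
                self.stop.set()
            self._record_report(rule, FAILED, time.monotonic() - started, str(exc))
            st.event.set()
            self._stack.rules = stack
            raise
        else:
            with self._state_lock:
                st.state = _DONE
                st.status = status
            self._record_report(rule, status, time.monotonic() - started, error)
            st.event.set()
            self._stack.rules = stack

    def _id_to_output(self, rid: int) -> str:
        for rule in self.ruleset.rules + list(self._synth.values()):
            if id(rule) == rid:
                return rule.outputs[0]
        return "?"

    def _up_to_date(self, rule: Rule) -> bool:
        fp = rule.fingerprint
        deps: dict[str, str] | None = None
        for out in rule.outputs:
            entry = self.db.entries.get(out)
            if entry is None or entry.get("fingerprint") != fp:
                return False
            if not os.path.exists(out):
                return False
            if entry.get("digest") != _entry_digest(out, entry):
                return False  # output itself was tampered with
            if deps is None:
                deps = dict(entry.get("deps") or {})
            elif dict(entry.get("deps") or {}) != deps:
                return False
        for dep, digest in (deps or {}).items():
            if not self.db.unchanged(dep, digest):
                return False
        return True

    def _execute(self, rule: Rule) -> None:
        log.info("building %s", rule.rule_id)
        for out in rule.outputs:
            parent = os.path.dirname(out)
            if parent:
                os.makedirs(parent, exist_ok=True)
            self.db.forget(out)  # never reuse an output mid-rebuild
        ctx = BuildContext(self, rule)
        rule.action(ctx)
        missing = [o for o in rule.outputs if not os.path.exists(o)]
        if missing:
            raise BuildError(
                f"rule {rule.rule_id!r} completed without producing {missing!r}"
            )
        deps = {}
        for dep in [*rule.static_deps, *ctx.dynamic_deps]:
            if dep not in deps and os.path.exists(dep):
                deps[dep] = file_digest(dep)
        for out in rule.outputs:
            self.db.record(out, rule.fingerprint, deps)
        log.info("finished %s", rule.rule_id)

    def _record_report(
        self, rule: Rule, status: str, seconds: float, error: str | None
    ) -> None:
        with self._report_lock:
            self.report.entries.append(
                ReportEntry(
                    rule=rule.rule_id,
                    outputs=list(rule.outputs),
                    status=status,
                    seconds=seconds,
                    deps=list(rule.static_deps),
                    error=error,
                )
            )

    # -- scheduling --------------------------------------------------------

    def _static_closure(self) -> list[Rule]:
        """Rules reachable from the targets via static deps, topo-checked."""
        needed: list[Rule] = []
        seen: set[int] = set()

        colour: dict[int, int] = {}
        order: list[Rule] = []

        def visit(rule: Rule, trail: list[str]) -> None:
            c = colour.get(id(rule), 0)
            if c == 1:
                cycle_start = trail.index(rule.outputs[0]) if rule.outputs[0] in trail else 0
                raise CycleError([*trail[cycle_start:], rule.outputs[0]])
            if c == 2:
                return
            colour[id(rule)] = 1
            for dep in rule.static_deps:
                dep_rule = self._resolve(dep)
                if dep_rule is not None:
                    visit(dep_rule, [*trail, rule.outputs[0]])
            colour[id(rule)] = 2
            order.append(rule)

        for target in self.targets:
            rule = self._resolve(target)
            if rule is None:
                if not os.path.exists(target):
                    raise MissingRuleError(
                        f"target {target!r}: no rule and file does not exist"
                    )
                continue
            if id(rule) not in seen:
                visit(rule, [])
            seen.add(id(rule))
        for rule in order:
            if id(rule) not in {id(r) for r in needed}:
                needed.append(rule)
        return needed

    def run(self) -> BuildReport:
        scheduled = self._static_closure()
        if self.jobs == 1 or len(scheduled) <= 1:
            first_error: BaseException | None = None
            for target in self.targets:
                if self.stop.is_set():
                    break
                try:
                    self.bring_up_to_date(target)
                except BaseException as exc:
                    first_error = first_error or exc
                    if not self.keep_going:
                        break
            if first_error is not None:
                raise first_error
            return self.report
        return self._run_parallel(scheduled)

    def _run_parallel(self, scheduled: list[Rule]) -> BuildReport:
        # classic counting scheduler over static deps; dynamic needs are
        # handled recursively inside workers via bring_up_to_date.
        by_id = {id(r): r for r in scheduled}
        dependents: dict[int, list[int]] = {id(r): [] for r in scheduled}
        remaining: dict[int, int] = {}
        for r in scheduled:
            n = 0
            for dep in r.static_deps:
                dep_rule = self._resolve(dep)
                if dep_rule is not None and id(dep_rule) in by_id:
                    dependents[id(dep_rule)].append(id(r))
                    n += 1
            remaining[id(r)] = n
        ready = sorted(
            (r.outputs[0], id(r)) for r in scheduled if remaining[id(r)] == 0
        )
        cond = threading.Condition()
        pending = {id(r) for r in scheduled}
        errors: list[BaseException] = []

        def worker() -> None:
            while True:
                with cond:
                    while not ready and pending and not self.stop.is_set():
                        cond.wait()
                    if not pending or (self.stop.is_set() and not self.keep_going):
                        cond.notify_all()
                        return
                    if not ready:
                        continue
                    _, rid = ready.pop(0)
                rule = by_id[rid]
                try:
                    self.run_rule(rule)
                except BaseException as exc:
                    with cond:
                        errors.append(exc)
                        pending.discard(rid)
                        if not self.keep_going:
                            self.stop.set()
                        cond.notify_all()
                    continue
                with cond:
                    pending.discard(rid)
                    for dep_id in dependents[rid]:
                        remaining[dep_id] -= 1
                        if remaining[dep_id] == 0:
                            item = (by_id[dep_id].outputs[0], dep_id)
                            ready.append(item)
                            ready.sort()
                    cond.notify_all()

        threads = [
            threading.Thread(target=worker, name=f"typedflow-worker-{i}")
            for i in range(self.jobs)
        ]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        if errors:
            raise errors[0]
        return self.report


def build(
    ruleset: RuleSet,
    targets: Sequence[str] | None = None,
    jobs: int = 1,
    db_path: str | Path = ".typedflow.db.jsonl",
    executor: Executor | None = None,
    keep_going: bool = False,
) -> BuildReport:
    """Bring *targets* (default: the rule set's wanted paths) up to date.

    Skips any rule whose outputs exist with matching fingerprint and whose
    recorded dependencies are content-unchanged; on failure, completed work is
    already persisted, so a rerun resumes where the build stopped.
    """
    targets = list(targets) if targets is not None else list(ruleset.wanted)
    db = BuildDatabase(db_path)
    b = _Build(
        ruleset,
        targets,
        jobs=jobs,
        db=db,
        executor=executor or local_executor(),
        keep_going=keep_going,
    )
    return b.run()


def _entry_digest(path: str, entry: dict) -> str:
    if entry.get("stat") == _stat_sig(path):
        return entry.get("digest", "")
    return file_digest(path)
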