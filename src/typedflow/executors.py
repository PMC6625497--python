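"""Pluggable command execution: run locally or via generated job scripts.

Builders never spawn processes themselves; they hand an argv token list to
:func:`run`, which either executes it directly (``local``) or renders it into
a POSIX shell job script with Torque-style ``#PBS`` resource headers
(``script``).  Script mode defaults to *dry* execution — the script is written
for inspection and then run locally — so the whole code path is exercisable
without a cluster; *submit* mode invokes a configured submission command and
polls a sentinel file the script touches on completion.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import time
from dataclasses import dataclass, field
from hashlib import sha1
from pathlib import Path
from typing import Sequence

log = logging.getLogger("typedflow.exec")


class ExecutionError(Exception):
    """A command failed; carries the rule identity when known."""

    def __init__(self, message: str, rule_id: str | None = None):
        super().__init__(f"[{rule_id}] {message}" if rule_id else message)
        self.rule_id = rule_id


@dataclass(frozen=True)
class Resources:
    """Per-command scheduling request (defaults from executor config)."""

    threads: int = 1
    memory_mb: int = 1024
    walltime_s: int | None = None
    queue: str | None = None

    def __post_init__(self) -> None:
        if self.threads < 1 or self.memory_mb < 1:
            raise ValueError("threads and memory_mb must be positive")


@dataclass
class Executor:
    """Execution platform handle.

    ``kind`` is ``"local"`` or ``"script"``.  Script-mode config keys:
    ``script_dir`` (where job scripts are written), ``mode`` (``"dry"`` |
    ``"submit"``), ``submit_cmd`` (argv prefix, submit mode only),
    ``poll_interval_s`` and ``timeout_s`` (sentinel polling), and
    ``default_resources``.
    """

    kind: str = "local"
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("local", "script"):
            raise ValueError(f"unknown executor kind {self.kind!r}")

    @property
    def default_resources(self) -> Resources:
        return self.config.get("default_resources") or Resources()


def local_executor() -> Executor:
    return Executor(kind="local")


def script_executor(
    script_dir: str | Path,
    mode: str = "dry",
    submit_cmd: Sequence[str] | None = None,
    poll_interval_s: float = 0.2,
    timeout_s: float = 600.0,
    default_resources: Resources | None = None,
) -> Executor:
    if mode not in ("dry", "submit"):
        raise ValueError(f"unknown script mode {mode!r}")
    return Executor(
        kind="script",
        config={
            "script_dir": str(script_dir),
            "mode": mode,
            "submit_cmd": list(submit_cmd or []),
            "poll_interval_s": poll_interval_s,
            "timeout_s": timeout_s,
            "default_resources": default_resources,
        },
    )


def render_pbs_headers(resources: Resources, job_name: str) -> list[str]:
    """Torque-dialect resource headers; the single substitution point for
    other dialects."""
    spec = f"nodes=1:ppn={resources.threads},mem={resources.memory_mb}mb"
    if resources.walltime_s is not None:
        spec += f",walltime={resources.walltime_s}"
    headers = [f"#PBS -N {job_name}", f"#PBS -l {spec}"]
    if resources.queue:
        headers.append(f"#PBS -q {resources.queue}")
    return headers


def run(
    executor: Executor,
    tokens: Sequence[str],
    resources: Resources | None = None,
    rule_id: str | None = None,
) -> None:
    """Execute *tokens* (one argv element each, no shell interpretation).

    Synchronous: returns only once the command has finished successfully.
    """
    tokens = [str(t) for t in tokens]
    if not tokens:
        raise ExecutionError("empty command", rule_id)
    resources = resources or executor.default_resources
    if executor.kind == "local":
        _run_local(tokens, rule_id)
    else:
        _run_script(executor, tokens, resources, rule_id)


def _run_local(tokens: list[str], rule_id: str | None) -> None:
    log.info("run%s: %s", f" [{rule_id}]" if rule_id else "", shlex.join(tokens))
    try:
        proc = subprocess.run(
            tokens, capture_output=True, text=True, check=False
        )
    except FileNotFoundError as exc:
        raise ExecutionError(f"executable not found: {tokens[0]}", rule_id) from exc
    if proc.stdout:
        log.debug("stdout: %s", proc.stdout.rstrip())
    if proc.stderr:
        log.debug("stderr: %s", proc.stderr.rstrip())
    if proc.returncode != 0:
        detail = (proc.stderr or proc.stdout or "").strip().splitlines()
        tail = detail[-1] if detail else ""
        raise ExecutionError(
            f"command failed (exit {proc.returncode}): {shlex.join(tokens)}"
            + (f" — {tail}" if tail else ""),
            rule_id,
        )


def _run_script(
    executor: Executor,
    tokens: list[str],
    resources: Resources,
    rule_id: str | None,
) -> None:
    cfg = executor.config
    script_dir = Path(cfg["script_dir"])
    script_dir.mkdir(parents=True, exist_ok=True)
    job_hash = sha1(" ".join(tokens).encode()).hexdigest()[:12]
    job_name = f"tf_{job_hash}"
    script = script_dir / f"{job_name}.sh"
    sentinel = script_dir / f"{job_name}.done"
    if sentinel.exists():
        sentinel.unlink()
    lines = ["#!/bin/sh"]
    lines += render_pbs_headers(resources, job_name)
    lines += ["set -e", shlex.join(tokens), f"touch {shlex.quote(str(sentinel))}", ""]
    script.write_text("\n".join(lines))
    script.chmod(0o755)
    log.info("job script%s: %s", f" [{rule_id}]" if rule_id else "", script)

    if cfg.get("mode", "dry") == "dry":
        _run_local(["sh", str(script)], rule_id)
        if not sentinel.exists():
            raise ExecutionError(f"job script {script} did not complete", rule_id)
        return

    submit_cmd = cfg.get("submit_cmd") or []
    if not submit_cmd:
        raise ExecutionError("submit mode requires a submit_cmd", rule_id)
    _run_local([*submit_cmd, str(script)], rule_id)
    deadline = time.monotonic() + float(cfg.get("timeout_s", 600.0))
    interval = float(cfg.get("poll_interval_s", 0.2))
    while not sentinel.exists():
        if time.monotonic() > deadline:
            raise ExecutionError(
                f"timed out waiting for job {job_name} sentinel {sentinel}", rule_id
            )
        time.sleep(interval)
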