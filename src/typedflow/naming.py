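"""Deterministic content-hash naming of managed intermediate files.

Every composed stage writes its outputs under a managed work directory, named
``<digest>.<stage>.<ext>``.  The digest is a SHA-1 over a canonical byte
serialization of the upstream paths, the stage name, and the stage's semantic
parameters — base32-encoded (lowercase) and truncated to 32 characters.
Scheduling knobs (threads, memory) are deliberately excluded: changing
parallelism must not invalidate existing outputs.  The digest depends on the
pipeline expression, never on file contents; content hashing belongs to the
build engine's up-to-date checks.
"""

from __future__ import annotations

import base64
import contextlib
import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import PurePosixPath
from typing import Iterable, Iterator, Sequence

DIGEST_ALGORITHM = "sha1"
DIGEST_LENGTH = 32
DEFAULT_WORKDIR = "_typedflow"


@dataclass
class Settings:
    """Process-wide naming configuration (managed work directory)."""

    workdir: str = DEFAULT_WORKDIR


settings = Settings()


@contextlib.contextmanager
def use_workdir(workdir: str) -> Iterator[None]:
    """Temporarily point managed paths at *workdir*."""
    previous = settings.workdir
    settings.workdir = str(workdir)
    try:
        yield
    finally:
        settings.workdir = previous


class NamingError(Exception):
    """A stage cannot be named (e.g. no registered extension)."""


def _canonical_path(path: str, workdir: str) -> str:
    # Managed inputs are hashed relative to the work directory so relocating
    # it changes path prefixes only, never digests.
    p = PurePosixPath(str(path).replace("\\", "/"))
    w = PurePosixPath(str(workdir).replace("\\", "/"))
    try:
        return str(p.relative_to(w))
    except ValueError:
        return str(p)


def digest(
    input_paths: Sequence[str],
    stage_name: str,
    params: Iterable[tuple[str, object]] = (),
    workdir: str | None = None,
) -> str:
    """32-character base32 SHA-1 digest of a stage application.

    Pure: depends only on the (canonicalized) input paths, the stage name,
    and the sorted semantic parameters.
    """
    workdir = settings.workdir if workdir is None else workdir
    h = hashlib.new(DIGEST_ALGORITHM)
    h.update(b"typedflow.naming.v1\x00")
    paths = [_canonical_path(p, workdir) for p in input_paths]
    h.update(struct.pack(">I", len(paths)))
    for p in paths:
        raw = p.encode("utf-8")
        h.update(struct.pack(">I", len(raw)))
        h.update(raw)
    name_raw = stage_name.encode("utf-8")
    h.update(struct.pack(">I", len(name_raw)))
    h.update(name_raw)
    for key, value in sorted((str(k), _canonical_value(v)) for k, v in params):
        item = f"{key}={value}".encode("utf-8")
        h.update(struct.pack(">I", len(item)))
        h.update(item)
    encoded = base64.b32encode(h.digest()).decode("ascii").rstrip("=").lower()
    return encoded[:DIGEST_LENGTH]


def _canonical_value(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def intermediate_paths(
    input_paths: Sequence[str],
    stage_name: str,
    params: Iterable[tuple[str, object]],
    n_outputs: int,
    extension: str | None,
    workdir: str | None = None,
) -> list[str]:
    """Managed output paths for one stage application.

    One output: ``<workdir>/<digest>.<stage>.<ext>``; *k* outputs:
    ``<workdir>/<digest>.<stage>.<i>.<ext>`` for ``i`` in ``1..k``.
    """
    if not extension:
        raise NamingError(
            f"stage {stage_name!r}: first output tag has no registered file extension"
        )
    workdir = settings.workdir if workdir is None else workdir
    d = digest(input_paths, stage_name, params, workdir=workdir)
    prefix = str(PurePosixPath(workdir) / f"{d}.{stage_name}")
    if n_outputs == 1:
        return [f"{prefix}.{extension}"]
    return [f"{prefix}.{i}.{extension}" for i in range(1, n_outputs + 1)]
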