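"""Synthetic data generator and the toy stage pack.

Everything needed to run and *check* whole example pipelines with no external
tools: a deterministic read simulator that plants known variants and
duplicates (and records the ground truth alongside), plus a pack of toy
stages — align, sort, mark duplicates, variant call, shard, k-mer search,
assemble — whose builders are pure text transformations executed through the
executor layer as subprocess entry points (``toytools.py``).  The toy tags
mirror the usual alignment-pipeline constraints: sorting requires the
alignment format, calling requires sorted and duplicate-marked input, and so
on, which is exactly what makes pre-execution validation meaningful.
"""

from __future__ import annotations

import json
import random
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    PipelineExpr,
    StageFactory,
    define_stage,
    effective_tags,
    get_valued,
    source,
)
from .combinators import out, split, with_all
from .tags import TagAlgebra

_TOYTOOLS = Path(__file__).with_name("toytools.py")


def _tool(*args: object) -> list[str]:
    # invoked by file path so the subprocess never imports this package
    return [sys.executable, str(_TOYTOOLS), *(str(a) for a in args)]


# ---------------------------------------------------------------------------
# Toy tag algebra
# ---------------------------------------------------------------------------


def toy_algebra() -> TagAlgebra:
    """Tags and implications used by the toy stage pack.

    ``DeDuped`` implies ``DupsMarked`` (removal is a stronger guarantee than
    marking) and both propagate downstream once established; ``Sorted`` does
    not propagate — stages that preserve it declare it transient instead.
    ``Referenced`` is a valued tag carrying the reference-genome path.
    """
    algebra = TagAlgebra()
    algebra.declare_tag("ToyFasta", extension="fa")
    algebra.declare_tag("ToyBam", extension="bam")
    algebra.declare_tag("ToyVcf", extension="vcf")
    algebra.declare_tag("ToyHits", extension="tsv")
    algebra.declare_tag("Sorted")
    algebra.declare_tag("DupsMarked", propagating=True)
    algebra.declare_tag("DeDuped", propagating=True)
    algebra.declare_tag("PairedEnd")
    algebra.declare_tag("Referenced", valued=True, propagating=True)
    algebra.add_implication("DeDuped", "DupsMarked")
    return algebra


# ---------------------------------------------------------------------------
# Builders (all process spawning goes through ctx.run)
# ---------------------------------------------------------------------------


def _align_builder(inputs, outputs, expr, ctx):
    ref = get_valued(expr, "Referenced")
    ctx.need([ref])
    ctx.run(
        _tool("align", *inputs, "--ref", ref, "-o", outputs[0], "-t", expr.stage.threads)
    )


def _fix_mates_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("fixmates", inputs[0], "-o", outputs[0]))


def _sort_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("sort", inputs[0], "-@", expr.stage.threads, "-o", outputs[0]))


def _mark_dups_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("markdups", inputs[0], "-o", outputs[0]))


def _dedup_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("dedup", inputs[0], "-o", outputs[0]))


def _call_builder(inputs, outputs, expr, ctx):
    ref = get_valued(expr, "Referenced")
    ctx.need([ref])
    ctx.run(
        _tool(
            "call", inputs[0], "--ref", ref,
            "--min-support", expr.stage.param("min_support", 2),
            "-o", outputs[0],
        )
    )


def _chunk_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("chunk", inputs[0], "-o", *outputs))


def _blast_builder(inputs, outputs, expr, ctx):
    subject = str(expr.stage.param("subject"))
    ctx.need([subject])
    ctx.run(
        _tool("blast", inputs[0], "--subject", subject,
              "-k", expr.stage.param("k", 8), "-o", outputs[0])
    )


def _extract_builder(inputs, outputs, expr, ctx):
    subject = str(expr.stage.param("subject"))
    ctx.need([subject])
    ctx.run(
        _tool("extract", inputs[0], "--subject", subject,
              "-m", expr.stage.param("m", 3), "-o", outputs[0])
    )


def _assemble_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("assemble", *inputs, "-o", outputs[0]))


def _process_contig_builder(inputs, outputs, expr, ctx):
    ctx.run(_tool("process-contig", inputs[0], "-o", outputs[0]))


def _concat_builder(inputs, outputs, expr, ctx):
    extra = ["--sort"] if expr.stage.param("sort", False) else []
    ctx.run(_tool("concat", *inputs, *extra, "-o", outputs[0]))


@dataclass(frozen=True)
class ToyStages:
    """The toy stage pack; each field is a parameterizable stage factory."""

    align: StageFactory
    fix_mates: StageFactory
    sort: StageFactory
    mark_dups: StageFactory
    dedup: StageFactory
    call: StageFactory
    chunk: StageFactory
    blast: StageFactory
    extract: StageFactory
    assemble: StageFactory
    process_contig: StageFactory
    concat: StageFactory

    def linear(self) -> list[StageFactory]:
        """The single-input stages used for random linear pipelines."""
        return [self.align, self.fix_mates, self.sort, self.mark_dups,
                self.dedup, self.call]


def toy_stages(algebra: TagAlgebra) -> ToyStages:
    """Build the stage pack against *algebra* (see :func:`toy_algebra`)."""

    def d(name, req, outs, transient=(), builder=None, defaults=None, **kw):
        return define_stage(
            name, req, outs, transient,
            builder=builder, defaults=defaults, algebra=algebra, **kw
        )

    return ToyStages(
        align=d("align", {"ToyFasta"}, ["ToyBam"], builder=_align_builder),
        fix_mates=d("fixmates", {"ToyBam"}, ["ToyBam"], {"Sorted"},
                    builder=_fix_mates_builder),
        sort=d("sort", {"ToyBam"}, ["ToyBam", "Sorted"], builder=_sort_builder),
        mark_dups=d("markdups", {"ToyBam", "Sorted"}, ["ToyBam", "DupsMarked"],
                    {"Sorted"}, builder=_mark_dups_builder),
        dedup=d("dedup", {"ToyBam", "Sorted"}, ["ToyBam", "DeDuped"],
                {"Sorted"}, builder=_dedup_builder),
        call=d("call", {"ToyBam", "Sorted", "DupsMarked"}, ["ToyVcf"],
               builder=_call_builder, defaults={"min_support": 2}),
        chunk=d("chunk", {"ToyFasta"}, ["ToyFasta"], builder=_chunk_builder,
                defaults={"n": 2}, n_outputs_param="n"),
        blast=d("blast", {"ToyFasta"}, ["ToyHits"], builder=_blast_builder,
                defaults={"k": 8}),
        extract=d("extract", {"ToyHits"}, ["ToyFasta"], builder=_extract_builder,
                  defaults={"m": 3}),
        assemble=d("assemble", {"ToyFasta"}, ["ToyFasta"],
                   builder=_assemble_builder),
        process_contig=d("processcontig", {"ToyFasta"}, ["ToyFasta"],
                         builder=_process_contig_builder),
        concat=d("concat", {"ToyFasta"}, ["ToyFasta"], builder=_concat_builder,
                 defaults={"sort": False}),
    )


# ---------------------------------------------------------------------------
# Synthetic data with recorded ground truth
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for use as a test oracle."""

    ref_path: str
    reads_path: str
    truth_path: str
    variants: tuple[tuple[str, int, str, str], ...]  # (contig, pos1, ref, alt)
    duplicates: frozenset[str]  # read ids that a duplicate-marker must flag
    read_origins: dict  # read id -> (contig, pos1)
    n_contigs: int

    def variant_sites(self) -> set[tuple[str, int, str, str]]:
        return set(self.variants)


def gen_reads(
    seed: int,
    n_reads: int = 200,
    n_contigs: int = 3,
    read_len: int = 40,
    outdir: str | Path = ".",
    contig_len: int = 300,
    dup_fraction: float = 0.2,
    variants_per_contig: int = 2,
) -> GroundTruth:
    """Write a reference FASTA, a reads FASTA, and a ground-truth table.

    Contigs are uniform random DNA; reads are error-free substrings of a
    sample genome that differs from the reference at ``variants_per_contig``
    planted SNPs per contig, each guaranteed two covering reads so a
    two-read-support caller recovers every variant exactly.  On top of the
    ``n_reads`` sampled reads, ``round(dup_fraction * n_reads)`` exact copies
    are appended; the truth table lists, per (contig, position) group, every
    read id after the lexicographically first as a duplicate — the same rule
    a position-based duplicate marker applies.  Byte-identical output for a
    given seed.
    """
    if min(n_reads, n_contigs, read_len, contig_len) < 1:
        raise ValueError("sizes must be positive")
    if contig_len < 2 * read_len + 2:
        raise ValueError("contig_len too small for planted-variant placement")
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    contigs = {
        f"c{i + 1}": "".join(rng.choice(BASES) for _ in range(contig_len))
        for i in range(n_contigs)
    }
    variants: list[tuple[str, int, str, str]] = []
    sample = dict(contigs)
    for cid in contigs:
        positions = rng.sample(range(read_len, contig_len - read_len), variants_per_contig)
        for pos0 in sorted(positions):
            refbase = contigs[cid][pos0]
            altbase = rng.choice([b for b in BASES if b != refbase])
            variants.append((cid, pos0 + 1, refbase, altbase))
            sample[cid] = sample[cid][:pos0] + altbase + sample[cid][pos0 + 1 :]

    # two guaranteed covering reads per variant, the rest sampled uniformly
    placements: list[tuple[str, int]] = []
    for cid, pos1, _, _ in variants:
        pos0 = pos1 - 1
        lo, hi = max(0, pos0 - read_len + 1), min(pos0, contig_len - read_len)
        for _ in range(2):
            placements.append((cid, rng.randint(lo, hi)))
    if n_reads < len(placements):
        raise ValueError("n_reads too small to cover the planted variants")
    cids = list(contigs)
    while len(placements) < n_reads:
        cid = rng.choice(cids)
        placements.append((cid, rng.randrange(contig_len - read_len + 1)))
    rng.shuffle(placements)

    n_dups = round(dup_fraction * n_reads)
    placements += [placements[i] for i in rng.sample(range(n_reads), n_dups)]

    width = len(str(len(placements)))
    reads = []
    origins: dict[str, tuple[str, int]] = {}
    for i, (cid, off0) in enumerate(placements):
        rid = f"r{i:0{width}d}"
        reads.append((rid, cid, off0, sample[cid][off0 : off0 + read_len]))
        origins[rid] = (cid, off0 + 1)

    groups: dict[tuple[str, int], list[str]] = {}
    for rid, cid, off0, _ in reads:
        groups.setdefault((cid, off0), []).append(rid)
    duplicates = frozenset(
        rid for members in groups.values() for rid in sorted(members)[1:]
    )

    ref_path = outdir / "ref.fa"
    reads_path = outdir / "reads.fa"
    truth_path = outdir / "truth.json"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()],
        str(ref_path), "fasta",
    )
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=rid, description=f"origin={cid}:{off0 + 1}")
            for rid, cid, off0, seq in reads
        ],
        str(reads_path), "fasta",
    )
    truth_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "variants": [list(v) for v in variants],
                "duplicates": sorted(duplicates),
                "read_origins": {k: list(v) for k, v in origins.items()},
                "n_contigs": n_contigs,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return GroundTruth(
        ref_path=str(ref_path),
        reads_path=str(reads_path),
        truth_path=str(truth_path),
        variants=tuple(variants),
        duplicates=duplicates,
        read_origins=origins,
        n_contigs=n_contigs,
    )


def read_vcf_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Parse the toy VCF dialect into {(contig, pos, ref, alt)} for oracles."""
    sites = set()
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        for alt in cols[4].split(","):
            sites.add((cols[0], int(cols[1]), cols[3], alt))
    return sites


# ---------------------------------------------------------------------------
# Example pipelines and random workflows
# ---------------------------------------------------------------------------


def example1(
    stages: ToyStages,
    reads_paths: Sequence[str],
    ref_path: str,
    out_vcf: str,
    threads: int = 1,
    algebra: TagAlgebra | None = None,
) -> PipelineExpr:
    """The linear demo workflow: align, fix mates, sort, mark dups, call."""
    src = source(
        list(reads_paths), tags={"ToyFasta"}, values={"Referenced": ref_path},
        algebra=algebra,
    )
    expr = (
        src
        >> stages.align(threads=threads)
        >> stages.fix_mates()
        >> stages.sort(threads=threads)
        >> stages.mark_dups()
        >> stages.call()
    )
    return out(expr, [out_vcf])


def example2(
    stages: ToyStages,
    query_path: str,
    subject_path: str,
    out_txt: str,
    n_chunks: int = 2,
    top: int = 3,
    algebra: TagAlgebra | None = None,
) -> PipelineExpr:
    """The scatter–gather demo: shard, search, extract, gather.

    The gather is a sort-merge concat, so the result is invariant to the
    shard count.
    """
    src = source([query_path], tags={"ToyFasta"}, algebra=algebra)
    chunks = split(src >> stages.chunk(n=n_chunks))
    parts = [
        c >> stages.blast(subject=subject_path) >> stages.extract(subject=subject_path, m=top)
        for c in chunks
    ]
    gathered = with_all(parts) >> stages.concat(sort=True)
    return out(gathered, [out_txt])


def random_linear_pipeline(
    rng: random.Random,
    stages: ToyStages,
    src: PipelineExpr,
    max_len: int = 5,
    corrupt: bool = False,
) -> PipelineExpr:
    """Sample a linear pipeline over the single-input toy stages.

    With ``corrupt=False`` stages are chosen among those whose requirements
    hold, so the pipeline validates; with ``corrupt=True`` the order is
    unconstrained and usually (but not always) ill-tagged.  Callers must
    classify by running ``validate`` — construction never checks.
    """
    pool = stages.linear()
    expr = src
    length = rng.randint(1, max_len)
    if corrupt:
        for _ in range(length):
            expr = expr >> rng.choice(pool)()
        return expr
    for _ in range(length):
        tags = effective_tags(expr)
        applicable = [f for f in pool if f.required_tags <= tags]
        if not applicable:
            break
        expr = expr >> rng.choice(applicable)()
    return expr
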