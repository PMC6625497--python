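"""Synthetic data generator and toy stage semantics."""

import subprocess
import sys
from pathlib import Path

import pytest
from hypothesis import given, settings, strategies as st

from typedflow import execute_workflow, use_workdir
from typedflow.fixtures import example1, gen_reads, read_vcf_sites
from typedflow import toytools

TOY = str(Path(toytools.__file__))


def _tool(*args):
    res = subprocess.run([sys.executable, TOY, *map(str, args)],
                         capture_output=True, text=True)
    return res


def test_generator_is_seed_deterministic(tmp_path):
    a = gen_reads(seed=5, outdir=tmp_path / "a")
    b = gen_reads(seed=5, outdir=tmp_path / "b")
    for x, y in ((a.ref_path, b.ref_path), (a.reads_path, b.reads_path)):
        assert Path(x).read_bytes() == Path(y).read_bytes()
    c = gen_reads(seed=6, outdir=tmp_path / "c")
    assert Path(a.ref_path).read_bytes() != Path(c.ref_path).read_bytes()


def test_reference_has_requested_contig_count(tmp_path):
    t = gen_reads(seed=1, n_contigs=5, outdir=tmp_path)
    assert Path(t.ref_path).read_text().count(">") == 5


def test_duplicate_truth_matches_position_rule(tmp_path):
    t = gen_reads(seed=2, n_reads=100, dup_fraction=0.2, outdir=tmp_path)
    # at least the appended copies are duplicates
    assert len(t.duplicates) >= round(0.2 * 100)
    # oracle: group recorded origins, all but lexicographically-first are dups
    groups = {}
    for rid, origin in t.read_origins.items():
        groups.setdefault(tuple(origin), []).append(rid)
    oracle = {r for g in groups.values() for r in sorted(g)[1:]}
    assert t.duplicates == oracle


def test_markdups_flags_exactly_the_recorded_duplicates(tmp_path):
    t = gen_reads(seed=3, n_reads=80, outdir=tmp_path)
    aln = tmp_path / "a.bam"
    marked = tmp_path / "m.bam"
    assert _tool("align", t.reads_path, "--ref", t.ref_path, "-o", aln).returncode == 0
    assert _tool("sort", aln, "-o", aln).returncode == 0
    assert _tool("markdups", aln, "-o", marked).returncode == 0
    flagged = {
        line.split("\t")[0]
        for line in marked.read_text().splitlines()[1:]
        if int(line.split("\t")[3]) & 1
    }
    assert flagged == set(t.duplicates)


def test_sort_output_is_ordered(tmp_path):
    t = gen_reads(seed=4, n_reads=60, outdir=tmp_path)
    aln = tmp_path / "a.bam"
    srt = tmp_path / "s.bam"
    _tool("align", t.reads_path, "--ref", t.ref_path, "-o", aln)
    assert _tool("sort", aln, "-o", srt).returncode == 0
    recs = [l.split("\t") for l in srt.read_text().splitlines()[1:]]
    keys = [(r[1], int(r[2]), r[0]) for r in recs]
    assert keys == sorted(keys)


def test_chunk_round_robin_sizes(tmp_path):
    fa = tmp_path / "q.fa"
    fa.write_text("".join(f">s{i}\nACGTACGTAC\n" for i in range(10)))
    outs = [tmp_path / f"c{i}.fa" for i in range(3)]
    assert _tool("chunk", fa, "-o", *outs).returncode == 0
    sizes = sorted(o.read_text().count(">") for o in outs)
    assert sizes == [3, 3, 4]


def test_builders_reject_wrong_dialect(tmp_path):
    fa = tmp_path / "q.fa"
    fa.write_text(">s1\nACGT\n")
    res = _tool("sort", fa, "-o", tmp_path / "out.bam")
    assert res.returncode != 0
    assert "not a toy alignment file" in res.stderr
    notfa = tmp_path / "x.bam"
    notfa.write_text("#TOYALN\t1\nr1\tc1\t1\t0\tACGT\n")
    res = _tool("align", notfa, "--ref", notfa, "-o", tmp_path / "y.bam")
    assert res.returncode != 0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    records=st.lists(
        st.tuples(
            st.from_regex(r"r[0-9]{1,4}", fullmatch=True),
            st.from_regex(r"c[0-9]{1,2}", fullmatch=True),
            st.integers(1, 10_000),
            st.integers(0, 1),
            st.text(alphabet="ACGTN", min_size=1, max_size=30),
        ),
        max_size=20,
    )
)
def test_alignment_dialect_roundtrips(tmp_path_factory, records):
    tmp = tmp_path_factory.mktemp("aln")
    path = tmp / "x.bam"
    toytools.write_aln(str(path), [list(r) for r in records])
    assert toytools.read_aln(str(path)) == [list(r) for r in records]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    records=st.lists(
        st.tuples(
            st.from_regex(r"[A-Za-z0-9_.|-]{1,12}", fullmatch=True),
            st.text(alphabet="ACGT", min_size=0, max_size=200),
        ),
        max_size=10,
    )
)
def test_fasta_roundtrips_through_toytools(tmp_path_factory, records):
    tmp = tmp_path_factory.mktemp("fa")
    path = tmp / "x.fa"
    recs = [(rid, "", seq) for rid, seq in records]
    toytools.write_fasta(str(path), recs)
    assert toytools.read_fasta(str(path)) == recs


@pytest.mark.parametrize("seed", [7, 8])
def test_linear_pipeline_recovers_planted_variants(algebra, stages, tmp_path, seed):
    t = gen_reads(seed=seed, n_reads=150, outdir=tmp_path / f"d{seed}")
    target = tmp_path / f"out{seed}.vcf"
    expr = example1(stages, [t.reads_path], t.ref_path, str(target))
    with use_workdir(str(tmp_path / f"_wd{seed}")):
        assert execute_workflow([expr]).ok
    assert read_vcf_sites(target) == set(t.variants)
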