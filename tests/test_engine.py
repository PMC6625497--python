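"""Incremental build engine: minimal rebuilds, resumption, patterns, parallelism."""

import hashlib
import random
from pathlib import Path

import networkx as nx
import pytest

from typedflow import (
    AmbiguousPatternError,
    BuildError,
    CycleError,
    MissingRuleError,
    Rule,
    RuleSet,
    build,
)
from typedflow.engine import BUILT, FAILED, SKIPPED, BuildDatabase


def _hash_action(deps, out_path, tag):
    """Write a digest of the dependency contents, so changes propagate."""

    def action(ctx):
        h = hashlib.sha1(tag.encode())
        for d in deps:
            h.update(Path(d).read_bytes())
        Path(out_path).write_text(h.hexdigest() + "\n")

    return action


def random_dag_ruleset(tmp, rng, n_rules=12, n_sources=3):
    """A random DAG of content-hashing rules over a few source files."""
    tmp.mkdir(parents=True, exist_ok=True)
    sources = []
    for i in range(n_sources):
        p = tmp / f"src_{i}.txt"
        p.write_text(f"source {i}\n")
        sources.append(str(p))
    rs = RuleSet()
    outputs = []
    for j in range(n_rules):
        pool = sources + outputs
        k = rng.randint(1, min(3, len(pool)))
        deps = tuple(sorted(rng.sample(pool, k)))
        out = str(tmp / f"node_{j:02d}.txt")
        rs.add_rule(Rule(outputs=(out,), static_deps=deps,
                         action=_hash_action(deps, out, f"n{j}")))
        outputs.append(out)
    return rs, sources


def _edges(ruleset):
    g = nx.DiGraph()
    for r in ruleset.rules:
        g.add_node(r.outputs[0])
        for d in r.static_deps:
            g.add_edge(d, r.outputs[0])
    return g


def _descendants(graph, node):
    return nx.descendants(graph, node) if graph.has_node(node) else set()


def test_rebuild_is_noop_when_nothing_changed(tmp_path):
    rs, _ = random_dag_ruleset(tmp_path, random.Random(0))
    targets = [r.outputs[0] for r in rs.rules]
    db = tmp_path / "db.jsonl"
    first = build(rs, targets, db_path=db)
    second = build(rs, targets, db_path=db)
    assert first.count(BUILT) == len(rs.rules)
    assert second.count(BUILT) == 0
    assert second.count(SKIPPED) == len(rs.rules)


@pytest.mark.parametrize("seed", range(8))
def test_minimal_rebuild_equals_descendant_oracle(tmp_path, seed):
    """Perturbing one input rebuilds exactly its DAG descendants."""
    rng = random.Random(seed)
    rs, sources = random_dag_ruleset(tmp_path, rng, n_rules=rng.randint(5, 20))
    targets = [r.outputs[0] for r in rs.rules]
    db = tmp_path / "db.jsonl"
    build(rs, targets, db_path=db)
    victim = rng.choice(sources)
    Path(victim).write_text("perturbed\n")
    report = build(rs, targets, db_path=db)
    rebuilt = {e.outputs[0] for e in report.entries if e.status == BUILT}
    oracle = _descendants(_edges(rs), victim) - set(sources)
    assert rebuilt == oracle


def test_deleted_intermediate_rebuilds_with_early_cutoff(tmp_path):
    """A deleted file's own rule reruns; identical content cuts the cascade."""
    rs, _ = random_dag_ruleset(tmp_path, random.Random(3), n_rules=8)
    targets = [r.outputs[0] for r in rs.rules]
    db = tmp_path / "db.jsonl"
    build(rs, targets, db_path=db)
    victim = rs.rules[2].outputs[0]
    Path(victim).unlink()
    report = build(rs, targets, db_path=db)
    rebuilt = {e.outputs[0] for e in report.entries if e.status == BUILT}
    assert rebuilt == {victim}  # restored byte-identically, downstream skips


def test_crash_resumption_builds_only_the_remainder(tmp_path):
    chain = []
    prev = tmp_path / "input.txt"
    prev.write_text("x\n")
    rs = RuleSet()
    boom = {"armed": True}

    def make_action(src, dst, explode=False):
        def action(ctx):
            if explode and boom["armed"]:
                raise RuntimeError("injected failure")
            Path(dst).write_text(Path(src).read_text() + str(dst) + "\n")
        return action

    for i in range(5):
        dst = tmp_path / f"step_{i}.txt"
        rs.add_rule(Rule(outputs=(str(dst),), static_deps=(str(prev),),
                         action=make_action(prev, dst, explode=(i == 2))))
        chain.append(dst)
        prev = dst
    db = tmp_path / "db.jsonl"
    with pytest.raises(RuntimeError):
        build(rs, [str(chain[-1])], db_path=db)
    boom["armed"] = False
    report = build(rs, [str(chain[-1])], db_path=db)
    assert report.count(SKIPPED) == 2  # steps 0 and 1 survived the crash
    assert report.count(BUILT) == 3


@pytest.mark.parametrize("jobs", [1, 2, 8])
def test_parallel_output_identical_to_serial(tmp_path, jobs):
    rs, _ = random_dag_ruleset(tmp_path / f"j{jobs}", random.Random(5), n_rules=15)
    targets = [r.outputs[0] for r in rs.rules]
    build(rs, targets, jobs=jobs, db_path=tmp_path / f"db{jobs}.jsonl")
    contents = {Path(t).name: Path(t).read_bytes() for t in targets}
    if not hasattr(test_parallel_output_identical_to_serial, "_baseline"):
        test_parallel_output_identical_to_serial._baseline = contents
    assert contents == test_parallel_output_identical_to_serial._baseline


def test_cycle_detected_with_paths(tmp_path):
    rs = RuleSet()
    a, b = str(tmp_path / "a"), str(tmp_path / "b")
    rs.add_rule(Rule(outputs=(a,), static_deps=(b,), action=lambda c: None))
    rs.add_rule(Rule(outputs=(b,), static_deps=(a,), action=lambda c: None))
    with pytest.raises(CycleError) as err:
        build(rs, [a], db_path=tmp_path / "db.jsonl")
    assert set(err.value.cycle) & {a, b}


def test_missing_rule_and_absent_file_is_an_error(tmp_path):
    rs = RuleSet()
    with pytest.raises(MissingRuleError):
        build(rs, [str(tmp_path / "ghost.txt")], db_path=tmp_path / "db.jsonl")


def test_pattern_rule_builds_needed_side_products(tmp_path):
    rs = RuleSet()
    data = tmp_path / "x.bam"
    data.write_text("records\n")
    out = tmp_path / "result.txt"

    def action(ctx):
        ctx.need([str(data) + ".bai"])
        out.write_text(Path(str(data) + ".bai").read_text() + "done\n")

    rs.add_rule(Rule(outputs=(str(out),), static_deps=(str(data),), action=action))
    rs.add_pattern_rule(
        str(tmp_path / "*.bai"),
        lambda ctx, stem, path: Path(path).write_text(f"index of {stem}\n"),
    )
    build(rs, [str(out)], db_path=tmp_path / "db.jsonl")
    assert out.read_text().startswith("index of x.bam")


def test_explicit_rule_beats_pattern(tmp_path):
    rs = RuleSet()
    target = str(tmp_path / "x.idx")
    rs.add_rule(Rule(outputs=(target,), static_deps=(),
                     action=lambda ctx: Path(target).write_text("explicit\n")))
    rs.add_pattern_rule(str(tmp_path / "*.idx"),
                        lambda ctx, stem, path: Path(path).write_text("pattern\n"))
    build(rs, [target], db_path=tmp_path / "db.jsonl")
    assert Path(target).read_text() == "explicit\n"


def test_ambiguous_patterns_error_at_need_time(tmp_path):
    rs = RuleSet()
    rs.add_pattern_rule(str(tmp_path / "*.bai"), lambda c, s, p: None)
    rs.add_pattern_rule(str(tmp_path) + "/x*i", lambda c, s, p: None)
    with pytest.raises(AmbiguousPatternError):
        build(rs, [str(tmp_path / "x.bai")], db_path=tmp_path / "db.jsonl")


def test_needing_existing_source_records_its_digest(tmp_path):
    src = tmp_path / "ref.fa"
    src.write_text(">c1\nACGT\n")
    out = tmp_path / "o.txt"
    rs = RuleSet()

    def action(ctx):
        ctx.need([str(src)])
        out.write_text("ok\n")

    rs.add_rule(Rule(outputs=(str(out),), static_deps=(), action=action))
    db_path = tmp_path / "db.jsonl"
    build(rs, [str(out)], db_path=db_path)
    entry = BuildDatabase(db_path).entries[str(out)]
    assert str(src) in entry["deps"]


def test_corrupt_database_degrades_to_full_rebuild(tmp_path):
    rs, _ = random_dag_ruleset(tmp_path, random.Random(1), n_rules=6)
    targets = [r.outputs[0] for r in rs.rules]
    db = tmp_path / "db.jsonl"
    build(rs, targets, db_path=db)
    db.write_text("garbage not json\n{half an entry\n")
    report = build(rs, targets, db_path=db)
    assert report.count(BUILT) == len(rs.rules)  # rebuilt, never wrongly reused


def test_unproduced_output_is_a_build_error(tmp_path):
    rs = RuleSet()
    rs.add_rule(Rule(outputs=(str(tmp_path / "never.txt"),), static_deps=(),
                     action=lambda ctx: None))
    with pytest.raises(BuildError):
        build(rs, [str(tmp_path / "never.txt")], db_path=tmp_path / "db.jsonl")
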