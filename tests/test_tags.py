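"""Tag algebra: declarations, implication closure, ontology hierarchy."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from typedflow import (
    OntologyError,
    RedeclarationError,
    TagAlgebra,
    UnknownTagError,
    bundled_edam_path,
    close_tags,
    load_edam,
)
from typedflow.tags import short_name


def test_declare_and_extension():
    alg = TagAlgebra().declare_tag("IsBam", extension="bam").declare_tag("Sorted")
    assert alg.extension_for("IsBam") == "bam"
    assert alg.extension_for("Sorted") is None


def test_redeclaration_rejected():
    alg = TagAlgebra().declare_tag("IsBam", extension="bam")
    with pytest.raises(RedeclarationError):
        alg.declare_tag("IsBam")


def test_implication_requires_declared_tags():
    alg = TagAlgebra().declare_tag("A")
    with pytest.raises(UnknownTagError):
        alg.add_implication("A", "B")
    with pytest.raises(UnknownTagError):
        alg.close({"Nope"})


def test_dedup_implies_dupsmarked():
    alg = (
        TagAlgebra()
        .declare_tag("DeDuped")
        .declare_tag("DupsMarked")
    )
    alg.add_implication("DeDuped", "DupsMarked")
    assert "DupsMarked" in alg.close({"DeDuped"})
    assert alg.close(set()) == frozenset()


def _random_algebra(rng, n_tags=12, n_edges=15):
    alg = TagAlgebra()
    names = [f"t{i}" for i in range(n_tags)]
    for n in names:
        alg.declare_tag(n)
    for _ in range(n_edges):
        alg.add_implication(rng.choice(names), rng.choice(names))
    return alg, names


@pytest.mark.parametrize("seed", range(10))
def test_closure_equals_bfs_oracle(seed):
    """Fixpoint closure must agree with brute-force graph reachability."""
    rng = random.Random(seed)
    alg, names = _random_algebra(rng)
    graph = nx.DiGraph(alg.implications)
    graph.add_nodes_from(names)
    start = set(rng.sample(names, rng.randint(0, len(names))))
    oracle = set(start)
    for s in start:
        oracle |= nx.descendants(graph, s)
    assert alg.close(start) == oracle


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    edges=st.lists(
        st.tuples(st.integers(0, 9), st.integers(0, 9)), max_size=20
    ),
    base=st.sets(st.integers(0, 9), max_size=10),
    extra=st.sets(st.integers(0, 9), max_size=10),
)
def test_closure_operator_laws(edges, base, extra):
    """close is extensive, monotone, and idempotent on random algebras."""
    alg = TagAlgebra()
    for i in range(10):
        alg.declare_tag(f"t{i}")
    for a, b in edges:
        alg.add_implication(f"t{a}", f"t{b}")
    s = {f"t{i}" for i in base}
    t = s | {f"t{i}" for i in extra}
    cs, ct = alg.close(s), alg.close(t)
    assert cs >= frozenset(s)  # extensive
    assert cs <= ct  # monotone
    assert alg.close(cs) == cs  # idempotent
    assert close_tags(alg, s) == cs


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


def test_short_name_convention():
    assert short_name("FASTQ-illumina") == "FastqIllumina"
    assert short_name("Sequence record format (text)") == "SequenceRecordFormatText"


def test_bundled_subset_loads_with_fastq_hierarchy():
    ont = load_edam(bundled_edam_path())
    assert "format_1931" in ont
    assert "format_1930" in ont.ancestors("format_1931")
    assert ont.tag_name("format_1931") == "FastqIllumina"


def test_empty_file_is_empty_ontology(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert len(load_edam(p)) == 0


def test_self_parent_is_a_cycle(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("x1\tThing\tx1\n")
    with pytest.raises(OntologyError):
        load_edam(p)


def test_dangling_parent_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("x1\tThing\tmissing\n")
    with pytest.raises(OntologyError):
        load_edam(p)


def test_attach_edam_reaches_every_ancestor():
    """Closure after attach equals graph reachability over the ontology."""
    ont = load_edam(bundled_edam_path())
    alg = TagAlgebra().attach_ontology(ont)
    alg.declare_tag("MyType")
    alg.attach_edam("MyType", "FastqIllumina")
    closed = alg.close({"MyType"})
    assert "Fastq" in closed  # one level up
    oracle = {ont.tag_name(a) for a in ont.ancestors("format_1931")}
    assert closed == frozenset({"MyType", "FastqIllumina"} | oracle)


def test_attach_to_root_adds_only_that_term():
    ont = load_edam(bundled_edam_path())
    alg = TagAlgebra().attach_ontology(ont)
    alg.declare_tag("Root")
    alg.attach_edam("Root", "data_0006")
    assert alg.close({"Root"}) == frozenset({"Root", "Data"})


def test_attach_unknown_term_rejected():
    ont = load_edam(bundled_edam_path())
    alg = TagAlgebra().attach_ontology(ont).declare_tag("X")
    with pytest.raises(OntologyError):
        alg.attach_edam("X", "format_9999")


def test_yaml_manifest_roundtrip(tmp_path):
    manifest = tmp_path / "tags.yaml"
    manifest.write_text(
        "tags:\n"
        "  IsBam: {extension: bam}\n"
        "  Sorted: {}\n"
        "  DeDuped: {propagating: true}\n"
        "  DupsMarked: {}\n"
        "  Referenced: {valued: true, propagating: true}\n"
        "implications:\n"
        "  - [DeDuped, DupsMarked]\n"
    )
    alg = TagAlgebra.from_yaml(manifest)
    assert alg.extension_for("IsBam") == "bam"
    assert alg.is_valued("Referenced")
    assert "DupsMarked" in alg.close({"DeDuped"})
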