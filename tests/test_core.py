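"""Core DSL: sources, composition, path/tag derivation, stage factory."""

import pytest

from typedflow import (
    AbsentValueError,
    ConstructionError,
    DefinitionError,
    TagValueConflictError,
    UnknownTagError,
    compose,
    define_stage,
    effective_tags,
    get_valued,
    output_paths,
    source,
    stage_path,
    upstream_products,
    with_all,
)
from typedflow.core import tag_values


def test_source_carries_paths_and_closed_tags(algebra):
    src = source(["r1.fa", "r2.fa"], tags={"ToyFasta", "PairedEnd"})
    assert output_paths(src) == ["r1.fa", "r2.fa"]
    assert effective_tags(src) >= {"ToyFasta", "PairedEnd"}


def test_source_rejects_empty_paths_and_unknown_tags(algebra):
    with pytest.raises(ConstructionError):
        source([], tags={"ToyFasta"})
    with pytest.raises(UnknownTagError):
        source(["a.fa"], tags={"NoSuchTag"})


def test_source_tags_close_under_implications(algebra):
    src = source(["a.bam"], tags={"ToyBam", "DeDuped"})
    assert "DupsMarked" in effective_tags(src)


def test_composition_is_left_associative(algebra, stages):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    chained = src >> stages.align() >> stages.sort()
    explicit = compose(compose(src, stages.align()), stages.sort())
    assert stage_path(chained) == ["align", "sort"]
    assert output_paths(chained) == output_paths(explicit)


def test_construction_never_checks_tags(algebra, stages):
    # a FASTA source composed straight into sort is ill-tagged but buildable
    bad = source(["r.fa"], tags={"ToyFasta"}) >> stages.sort()
    assert stage_path(bad) == ["sort"]


def test_compose_arity_matches_stage(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"})
    sharded = src >> stages.chunk(n=3)
    assert len(output_paths(sharded)) == 3


def test_param_change_changes_managed_paths(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"})
    a = src >> stages.chunk(n=2)
    b = src >> stages.chunk(n=3)
    assert output_paths(a)[0] != output_paths(b)[0]


def test_threads_do_not_change_managed_paths(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    one = src >> stages.align() >> stages.sort(threads=1)
    four = src >> stages.align() >> stages.sort(threads=4)
    assert output_paths(one) == output_paths(four)


def test_extension_comes_from_first_output_tag(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    sorted_bam = src >> stages.align() >> stages.sort()
    (path,) = output_paths(sorted_bam)
    assert path.endswith(".sort.bam")


def test_define_stage_requires_extension_on_first_output_tag(algebra):
    with pytest.raises(DefinitionError):
        define_stage("oops", set(), ["Sorted"], builder=lambda *a: None)


def test_propagating_and_transient_tag_flow(algebra, stages):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    deduped = src >> stages.align() >> stages.sort() >> stages.dedup()
    tags = effective_tags(deduped)
    assert {"DeDuped", "DupsMarked", "Sorted"} <= tags  # transient keeps Sorted
    downstream = deduped >> stages.call()
    assert "DeDuped" in effective_tags(downstream)  # propagates past call


def test_sortedness_not_claimed_before_sorting(algebra, stages):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    unsorted = src >> stages.align()
    assert "Sorted" not in effective_tags(unsorted)


def test_bundle_tags_are_intersection(algebra, stages, workdir):
    ref = {"Referenced": "ref.fa"}
    sorted_bam = source(["r.fa"], tags={"ToyFasta"}, values=ref) \
        >> stages.align() >> stages.sort()
    plain_bam = source(["s.fa"], tags={"ToyFasta"}, values=ref) >> stages.align()
    bundle = with_all([sorted_bam, plain_bam])
    assert "ToyBam" in effective_tags(bundle)
    assert "Sorted" not in effective_tags(bundle)


def test_valued_tag_survives_compositions(algebra, stages):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    expr = src >> stages.align() >> stages.sort() >> stages.mark_dups()
    assert get_valued(expr, "Referenced") == "ref.fa"


def test_valued_tag_absent_is_an_error(algebra, stages):
    expr = source(["r.fa"], tags={"ToyFasta"}) >> stages.align()
    with pytest.raises(AbsentValueError):
        get_valued(expr, "Referenced")


def test_valued_tag_conflict_in_bundle(algebra):
    a = source(["a.fa"], tags={"ToyFasta"}, values={"Referenced": "ref1.fa"})
    b = source(["b.fa"], tags={"ToyFasta"}, values={"Referenced": "ref2.fa"})
    with pytest.raises(TagValueConflictError):
        tag_values(with_all([a, b]))
    agree = with_all([a, source(["c.fa"], tags={"ToyFasta"},
                                values={"Referenced": "ref1.fa"})])
    assert tag_values(agree)["Referenced"] == "ref1.fa"


def test_upstream_products_finds_nearest_match(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    aligned = src >> stages.align()
    sorted_bam = aligned >> stages.sort()
    called = sorted_bam >> stages.mark_dups() >> stages.call()
    assert upstream_products(called, {"ToyBam", "Sorted", "DupsMarked"}) == \
        output_paths(sorted_bam >> stages.mark_dups())
    assert upstream_products(called, {"ToyFasta"}) == ["r.fa"]
    # vacuous predicate matches the immediate upstream
    assert upstream_products(sorted_bam, set()) == output_paths(aligned)
    assert upstream_products(called, {"ToyVcf"}) == []


def test_derived_attributes_are_pure(algebra, stages, workdir):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    expr = src >> stages.align() >> stages.sort()
    assert output_paths(expr) == output_paths(expr)
    assert effective_tags(expr) == effective_tags(expr)


def test_stage_path_disambiguates_repeats(algebra, stages):
    src = source(["r.fa"], tags={"ToyFasta"}, values={"Referenced": "ref.fa"})
    expr = src >> stages.align() >> stages.sort() >> stages.sort()
    assert stage_path(expr) == ["align", "sort", "sort[2]"]
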