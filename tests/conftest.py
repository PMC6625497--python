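import pytest

from typedflow import use_workdir, using_algebra
from typedflow.fixtures import gen_reads, toy_algebra, toy_stages


@pytest.fixture
def algebra():
    alg = toy_algebra()
    with using_algebra(alg):
        yield alg


@pytest.fixture
def stages(algebra):
    return toy_stages(algebra)


@pytest.fixture
def workdir(tmp_path):
    wd = tmp_path / "_managed"
    with use_workdir(str(wd)):
        yield wd


@pytest.fixture
def reads(tmp_path):
    """Small simulated dataset with recorded ground truth."""
    return gen_reads(seed=7, n_reads=120, n_contigs=3, read_len=40,
                     outdir=tmp_path / "data")
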