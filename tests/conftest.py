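import pytest

from defenscan import fixtures
from defenscan.model_db import ModelDatabase
from defenscan.pipeline import run_pipeline


@pytest.fixture(scope="session")
def fixture_root(tmp_path_factory):
    """Demo DB + every shipped planted genome, generated once per session."""
    root = tmp_path_factory.mktemp("fixtures")
    db_dir, sets = fixtures.make_all(root, seed=1)
    return root, db_dir, sets


@pytest.fixture(scope="session")
def db_dir(fixture_root):
    return fixture_root[1]


@pytest.fixture(scope="session")
def fixture_sets(fixture_root):
    return fixture_root[2]


@pytest.fixture(scope="session")
def model_db(db_dir):
    return ModelDatabase.load(db_dir)


@pytest.fixture
def run_plan(db_dir, tmp_path):
    """Run the standard pipeline (precomputed hit table path) on one plan."""

    def _run(fs, substitute=True, **kwargs):
        kwargs.setdefault("domtbl", fs.domtbl)
        kwargs.setdefault("crispr", fs.crispr_gff)
        kwargs.setdefault("ncrna", fs.cmsearch)
        if substitute:
            kwargs.setdefault("pseudo_proteins", fs.protein_lookup)
        return run_pipeline(
            [fs.gff, fs.faa], db_dir, tmp_path / f"out_{fs.plan.assembly_id}", **kwargs
        )

    return _run
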