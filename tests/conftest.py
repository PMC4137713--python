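import warnings

import pytest
from hypothesis import settings

from plastid_rnaproc.pipeline import RunConfig, run_analysis

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic pipeline run (seed 1), shared across the suite."""
    out = tmp_path_factory.mktemp("run_seed1")
    return run_analysis(RunConfig(synthetic=True, seed=1, out_dir=str(out)))


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run["truth"]


@pytest.fixture(scope="session")
def annotations_by_id(default_run):
    return {a.gene_id: a for a in default_run["annotations"]}
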