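import pytest

from invscan.pipeline import run_all
from invscan.simgenome import build_truth, default_desk_config


@pytest.fixture(scope="session")
def desk_config():
    """SNP-free desk-scale study configuration with forced breakpoint cuts."""
    cfg = default_desk_config(seed=1, snp_rate=0.0)
    cfg.breakpoint_fragmentation_prob = 1.0
    return cfg


@pytest.fixture(scope="session")
def desk_run(desk_config, tmp_path_factory):
    """One full pipeline run on the desk-scale config, shared by tests."""
    outdir = tmp_path_factory.mktemp("desk_run")
    result = run_all(desk_config, outdir)
    return result, build_truth(desk_config), outdir
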