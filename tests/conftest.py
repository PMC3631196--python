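import pytest

from esimir.pipeline import PipelineConfig, run_pipeline
from esimir.simulate import default_config, make_reference_bundle, simulate_libraries


@pytest.fixture(scope="session")
def small_bundle():
    return make_reference_bundle(
        n_known=8, n_kc=3, n_novel_loci=4, n_contaminants=6,
        seed=11, genome_len=12_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_bundle):
    cfg = default_config(small_bundle, depth=20_000, seed=12)
    return cfg, simulate_libraries(small_bundle, cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    cfg = PipelineConfig(
        outdir=str(tmp_path_factory.mktemp("run")), seed=5, depth=30_000,
    )
    return run_pipeline(cfg)
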