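import pytest

from follimir.pipeline import PipelineConfig, run_pipeline
from follimir.simulate import SimConfig


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full error-free synthetic study (demo seed 7), shared by all tests."""
    cfg = PipelineConfig(
        sim=SimConfig(seed=7, seq_error_rate=0.0),
        outdir=tmp_path_factory.mktemp("study") / "run",
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """A small reference bundle for generator-level tests."""
    from follimir.simulate import generate_reference

    cfg = SimConfig(
        seed=11,
        n_known=4,
        n_conserved=2,
        n_novel=2,
        n_decoy=2,
        genome_length=20_000,
        reads_per_sample=4_000,
        seq_error_rate=0.0,
    )
    return cfg, generate_reference(cfg)
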