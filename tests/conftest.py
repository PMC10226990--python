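import pytest

from methylout import synthetic_cohort as sc
from methylout.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def study_bundle():
    """A small cohort with planted allele-specific events and cis variants."""
    config = sc.make_study_config(
        seed=7, n_samples=20, n_families=4, n_cpgs=6000, genome_bp=300_000,
        n_events=8, effect_delta=0.5, cis_variant_distance=500,
        heritable_fraction=0.5)
    return sc.generate_cohort(config)


@pytest.fixture(scope="session")
def study_result(study_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    config = RunConfig(output_dir=str(out), n_perm=200, n_background=1000,
                       seed=7)
    return run_pipeline(config, bundle=study_bundle)
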