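import pytest

from clonotrace import simdata


@pytest.fixture(scope="session")
def small_truth():
    """A 5-clone cohort (1 sample per clone) on a small genome."""
    cfg = simdata.small_config(seed=1)
    return simdata.simulate_clonal_lineage(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """The full default cohort: 13 clones x 3 samples, seed 7."""
    cfg = simdata.SimConfig(seed=7)
    return simdata.simulate_clonal_lineage(cfg)


@pytest.fixture(scope="session")
def emitted_default(default_truth, tmp_path_factory):
    out = tmp_path_factory.mktemp("emitted_default")
    paths = simdata.emit_candidate_vcf(default_truth, default_truth.config, out)
    return paths


@pytest.fixture(scope="session")
def emitted_clean(small_truth, tmp_path_factory):
    """Noise-free, artifact-free emission of the small cohort."""
    out = tmp_path_factory.mktemp("emitted_clean")
    return simdata.emit_candidate_vcf(small_truth, small_truth.config, out,
                                      noise=False, artifacts=False)


@pytest.fixture(scope="session")
def default_lineage(default_truth):
    from clonotrace import pipeline
    return pipeline.reconstruct_lineages(default_truth.genotype_matrix())
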