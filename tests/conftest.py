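import numpy as np
import pytest

from micromet import synthgen


@pytest.fixture(scope="session")
def small_bundle():
    return synthgen.gen_feature_bundle(80, 6, 25, 8, seed=7)


@pytest.fixture(scope="session")
def small_metabolites(small_bundle):
    plan = {
        "sig_micro": synthgen.MetaboliteSignal(microbiome=0.4, n_active=3),
        "sig_clin": synthgen.MetaboliteSignal(clinical=0.4, n_active=3),
        "noise": synthgen.MetaboliteSignal(),
    }
    metab, truth = synthgen.gen_metabolite_matrix(small_bundle, plan, seed=8)
    return metab, truth


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """Two full demo-pipeline runs (shared by the determinism and the
    attribution local-accuracy checks)."""
    from micromet import experiments

    workdir = tmp_path_factory.mktemp("demo")
    return experiments.demo_determinism(seed=1, workdir=str(workdir))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
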