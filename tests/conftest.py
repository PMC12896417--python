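import pytest
from hypothesis import HealthCheck, settings

import karyonorm as kn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """300-gene design, 100 genes per subgenome, defaults otherwise."""
    return kn.SimConfig(n_genes={"S": 100, "L1": 100, "L2": 100}, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genes, truth, wgs, rna = kn.simulate_dataset(small_config)
    return {"config": small_config, "genes": genes, "truth": truth, "wgs": wgs, "rna": rna}


@pytest.fixture(scope="session")
def noise_free(small_config):
    """Expected-count (deterministic) matrices for closed-form checks."""
    genes, truth = kn.make_genome(small_config)
    wgs = kn.simulate_wgs(genes, small_config.karyotypes, small_config, noise=False)
    rna = kn.simulate_rnaseq(genes, small_config.karyotypes, small_config, noise=False)
    return {"config": small_config, "genes": genes, "truth": truth, "wgs": wgs, "rna": rna}


@pytest.fixture(scope="session")
def clean_config():
    """Purely dosage-proportional design (no special genes), 300 genes."""
    return kn.SimConfig(
        n_genes={"S": 100, "L1": 100, "L2": 100},
        frac_trans_de=0.0,
        frac_compensated=0.0,
        frac_collapsed=0.0,
        frac_low_coverage=0.0,
        seed=19,
    )


@pytest.fixture(scope="session")
def clean_noise_free(clean_config):
    genes, truth = kn.make_genome(clean_config)
    wgs = kn.simulate_wgs(genes, clean_config.karyotypes, clean_config, noise=False)
    rna = kn.simulate_rnaseq(genes, clean_config.karyotypes, clean_config, noise=False)
    return {"config": clean_config, "genes": genes, "truth": truth, "wgs": wgs, "rna": rna}


def l_truth_index(truth):
    return truth.index[truth["subgenome"].isin(["L1", "L2"])]
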