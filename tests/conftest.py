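import pytest

from olsp.pipeline import run_pipeline
from olsp.simulate import simulate_run, small_config
from olsp.taxonomy import ReferenceDB, TaxonPath


def reference_db(run):
    """In-memory ReferenceDB for a SyntheticRun."""
    return ReferenceDB(
        {t.ref_id: t.template for t in run.reference},
        {t.ref_id: TaxonPath.from_names(*t.path) for t in run.reference},
    )


def habitat_map(run):
    return {t.species: set(t.habitats) for t in run.reference}


@pytest.fixture(scope="session")
def noisy_run():
    """A small synthetic study with default noise processes enabled."""
    return simulate_run(small_config(seed=11))


@pytest.fixture(scope="session")
def noisy_result(noisy_run):
    return run_pipeline(
        noisy_run.designs, noisy_run.reads, reference_db(noisy_run), habitat_map(noisy_run)
    )


@pytest.fixture(scope="session")
def noiseless_run():
    return simulate_run(
        small_config(seed=12, sub_rate=0.0, tag_switch_rate=0.0,
                     neg_contam_mean=0.0, contaminant_rate=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_result(noiseless_run):
    return run_pipeline(
        noiseless_run.designs, noiseless_run.reads, reference_db(noiseless_run), None
    )
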