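import pytest

from prognosig import SimulationConfig, generate_dataset

#: a scaled-down study: fast enough for per-test regeneration, big enough
#: that planted structure dominates noise
SMALL = dict(
    n_pairs=12,
    n_candidate_probes=80,
    n_normalization_probes=40,
    n_panel_probes=10,
    n_de_genes=30,
    n_prognosis_genes=10,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=123, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(matrix, annotation, truth) for the small study; treat as read-only."""
    return generate_dataset(small_config)


@pytest.fixture()
def tumor_ids():
    def _tumors(annotation):
        return annotation.loc[annotation["lesion"] == "malignant", "sample_id"].tolist()

    return _tumors
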