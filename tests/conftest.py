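import numpy as np
import pandas as pd
import pytest

from tcrkit.simulate import GeneratorConfig, SyntheticCohort, generate_cohort, write_cohort


def small_generator_config(seed: int = 11) -> GeneratorConfig:
    """Desk-scale cohort: 10 patients / 17 datasets, a few hundred clones each."""
    return GeneratorConfig(
        n_patients=(4, 4, 2),
        richness_range=(200, 800),
        n_clusters=300,
        cluster_size=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    return generate_cohort(small_generator_config())


@pytest.fixture(scope="session")
def written_cohort(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, out)
    return out


@pytest.fixture()
def toy_tsv(tmp_path):
    """Three-row rearrangement file: CASSF (5 + 2 templates) and CASTF (1)."""
    path = tmp_path / "toy.tsv"
    pd.DataFrame(
        {
            "amino_acid": ["CASSF", "CASSF", "CASTF"],
            "templates": [5, 2, 1],
            "seq_reads": [50, 20, 10],
            "frame_type": ["In", "In", "In"],
            "v_resolved": ["TRBV1", "TRBV2", "TRBV3"],
            "j_resolved": ["TRBJ1", "TRBJ1", "TRBJ2"],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
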