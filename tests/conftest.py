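import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rows):
    """Build a records DataFrame from (individual_id, group_id, sex, rs, exposure) tuples."""
    return pd.DataFrame(rows, columns=["individual_id", "group_id", "sex", "rs", "exposure"])


@pytest.fixture
def tiny_records():
    return make_records([
        ("a", "g1", "male", 3, 1.0),
        ("b", "g1", "male", 0, 1.0),
        ("c", "g1", "female", 2, 2.0),
    ])


@pytest.fixture
def study_metadata():
    """Metadata shaped like a comparative study: humans laid out over the
    marriage-by-subsistence table, plus mammal species."""
    from repskew.synth import default_study_spec, gen_meta_dataset

    _, metadata, _ = gen_meta_dataset(default_study_spec(seed=7))
    return metadata


@pytest.fixture(scope="session")
def two_class_dataset():
    """A synthetic two-class meta-dataset with a known male-M* contrast of 0.5."""
    from repskew.synth import ClassSpec, SyntheticSpec, gen_meta_dataset

    spec = SyntheticSpec(
        classes=(
            ClassSpec("hum", 40, mstar_male=0.7, mstar_female=0.4, taxon="human",
                      marriage_system="normative_monogamy", subsistence="market"),
            ClassSpec("mam", 40, mstar_male=0.2, mstar_female=0.4,
                      taxon="nonhuman_mammal", mating_system="polygynous"),
        ),
        residual_sd=0.3,
        seed=11,
    )
    estimates, metadata, truths = gen_meta_dataset(spec)
    return estimates, metadata, truths
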