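import numpy as np
import pandas as pd
import pytest

import imputome as im


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic cohort (113 samples, planted fold-8 effects)."""
    return im.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def norm(bundle):
    return im.normalize_copy_number(bundle.otu_table, bundle.copy_numbers)


@pytest.fixture(scope="session")
def gene_profile(norm, bundle):
    return im.predict_metagenome(norm, bundle.gene_content)


@pytest.fixture(scope="session")
def l3_profile(gene_profile, bundle):
    return im.collapse_to_level(gene_profile, bundle.hierarchy, "L3")


@pytest.fixture
def tiny_table():
    """2 samples x 3 OTUs with easy hand arithmetic."""
    return pd.DataFrame(
        [[10.0, 4.0, 8.0], [2.0, 6.0, 0.0]],
        index=["S1", "S2"], columns=["OTU_A", "OTU_B", "OTU_C"])


def random_groups(n, rng, labels=("Vata", "Pitta", "Kapha")):
    return pd.Series(rng.choice(labels, size=n),
                     index=[f"S{i}" for i in range(n)])
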