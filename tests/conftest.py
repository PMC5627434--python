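import numpy as np
import pytest

from tissuenorm import make_experiment


@pytest.fixture
def small_experiment():
    """10 genes x 6 samples with mixed chromosomes/biotypes, two groups."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=(10, 6)).astype(float)
    return make_experiment(
        counts,
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(6)],
        chromosomes=["1", "2", "X", "X", "Y", "Y", "MT", "MT", "3", "4"],
        biotypes=["protein_coding"] * 6 + ["pseudogene"] + ["other"] * 3,
        sex=["male", "female"] * 3,
        major_site=["siteA"] * 6,
        sub_site=["sub1"] * 3 + ["sub2"] * 3,
    )
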