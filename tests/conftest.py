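import numpy as np
import pandas as pd
import pytest

from radstage.images import ImageVolume, TumorMask
from radstage.radiomics.discretize import DiscretizedVolume
from radstage.synthetic import CohortConfig, generate_cohort


def make_disc(levels, n_levels=None, mask=None):
    """Wrap an integer array as a DiscretizedVolume (0 = outside mask)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[None, :, :]
    if mask is None:
        mask = levels > 0
    if n_levels is None:
        n_levels = int(levels.max())
    return DiscretizedVolume(levels=levels, n_levels=n_levels, mask=np.asarray(mask, bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4 + 4 textured cohort reused by extraction-level tests."""
    cfg = CohortConfig(
        n_intra=4, n_extra=4, n_genes=300, n_de_genes=12, log2fc=2.0,
        n_gene_sets=10, set_size=8, seed=12345,
    )
    return generate_cohort(cfg)


@pytest.fixture
def random_volume(rng):
    data = rng.normal(size=(6, 8, 8))
    mask = np.zeros((6, 8, 8), bool)
    mask[1:5, 2:7, 2:7] = True
    return ImageVolume(data, spacing=(2.0, 1.0, 1.0)), TumorMask(mask)


@pytest.fixture
def feature_labels():
    def _make(n_intra, n_extra, prefix="case"):
        ids = [f"{prefix}_{i:03d}" for i in range(n_intra + n_extra)]
        return pd.Series(["intra"] * n_intra + ["extra"] * n_extra, index=ids)

    return _make
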