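import numpy as np
import pytest

from sbkit import simdata as sd


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded introgression dataset with planted artifacts, shared by
    read-only tests (20 genes keeps the suite fast)."""
    cfg = sd.preset_introgression(
        seed=42, n_genes=20, n_supergene=6,
        n_diploid_contaminants=2, n_collapsed_repeat_regions=1,
    )
    return sd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("simulated")
    small_dataset.write(out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sample_labels(alignments):
    return {l: tuple(l.split("_")[:2]) for l in alignments[0].labels}
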