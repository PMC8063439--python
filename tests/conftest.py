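import numpy as np
import pytest

from methscreen.io import align_cohort
from methscreen.screen import SilencingScreen
from methscreen.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study (fewer genes) that keeps the default cohort sizes."""
    return SimulationConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_screen(small_study):
    """Fitted screen on the scaled-down synthetic cell-line cohort."""
    cohort = align_cohort(
        small_study.beta_cellline,
        small_study.expr_cellline,
        small_study.probes,
        samples=small_study.annot_cellline.analysis_samples(),
    )
    return SilencingScreen(cohort).fit()


def write_tsv_matrix(path, feature_ids, sample_ids, rows):
    """Write a features-on-rows TSV matrix fixture."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sample_ids) + "\n")
        for fid, row in zip(feature_ids, rows):
            fh.write(fid + "\t" + "\t".join("" if v is None else str(v) for v in row) + "\n")
    return path
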