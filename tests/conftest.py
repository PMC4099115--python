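import numpy as np
import pytest

from minmet.io import IntensityMatrix, StudyDesign
from minmet.preprocess import preprocess_tissue
from minmet.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 11), shared across tests."""
    return simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def preprocessed_cohort(default_cohort):
    """Default cohort plus its preprocessed (regularized) plasma matrix."""
    pla = default_cohort.design.subset_tissue("PLA")
    reg, filt = preprocess_tissue(default_cohort.intensity["PLA"], pla)
    return default_cohort, pla, reg, filt


@pytest.fixture(scope="session")
def null_config():
    """Study conditions with no planted effects anywhere."""
    return SimConfig(p_metabolites=201, n_genotype=0, n_diet=0,
                     n_interaction=0, beta_gdy=0.0)


@pytest.fixture
def balanced_design_8():
    """Minimal 2x2 design with two mice per cell (plasma only)."""
    return StudyDesign(
        [f"s{i}" for i in range(8)],
        [f"m{i}" for i in range(8)],
        ["WT", "WT", "WT", "WT", "MU", "MU", "MU", "MU"],
        ["LF", "LF", "HF", "HF", "LF", "LF", "HF", "HF"],
        ["PLA"] * 8,
    )


def make_matrix(values, mask=None, scale_tag="regularized", sample_ids=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    p, n = values.shape
    return IntensityMatrix(
        values, mask,
        [f"M{j}" for j in range(p)],
        sample_ids or [f"s{i}" for i in range(n)],
        scale_tag=scale_tag,
    )


def design_two_groups(n, tissue="PLA"):
    """n samples split into two equal WT/MU groups, one diet."""
    half = n // 2
    return StudyDesign(
        [f"s{i}" for i in range(n)],
        [f"m{i}" for i in range(n)],
        ["WT"] * half + ["MU"] * (n - half),
        ["LF"] * n,
        [tissue] * n,
    )
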