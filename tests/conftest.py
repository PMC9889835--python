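import warnings

import numpy as np
import pandas as pd
import pytest

from strawcue.community import AsvTable
from strawcue.synthetic import (
    CommunityTruth,
    ExperimentDesign,
    default_truth,
    generate_asv_tables,
    generate_isotope_samples,
)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign(seed=7)


@pytest.fixture(scope="session")
def clean_truth(design):
    """Noise-free ground truth: the analysis chain must recover it exactly."""
    return default_truth(design, noise_sd_delta=0.0, noise_cv_pools=0.0)


@pytest.fixture(scope="session")
def noisy_truth(design):
    return default_truth(design, noise_sd_delta=1.0, noise_cv_pools=0.05)


@pytest.fixture(scope="session")
def clean_samples(design, clean_truth):
    return generate_isotope_samples(design, clean_truth)


@pytest.fixture(scope="session")
def noisy_samples(design, noisy_truth):
    return generate_isotope_samples(design, noisy_truth)


@pytest.fixture(scope="session")
def asv_pair(design, noisy_truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_asv_tables(design, noisy_truth)


@pytest.fixture(scope="session")
def module_truth():
    """Community truth with strong planted modules and no treatment effects."""
    return CommunityTruth(
        n_asvs_bacterial=60,
        n_asvs_fungal=30,
        latent_loading=0.8,
        effect_sizes={},
    )


@pytest.fixture
def toy_table():
    """Six-sample toy ASV table with hand-checkable abundances."""
    counts = pd.DataFrame(
        {
            # mean relative abundance and prevalence both controllable
            "asv_common": [50, 60, 40, 55, 45, 50],
            "asv_rare": [1, 0, 1, 0, 0, 0],
            "asv_halfprev": [30, 30, 30, 0, 0, 0],
            "asv_abundant": [100, 90, 110, 120, 80, 100],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    taxonomy = pd.DataFrame(
        {"phylum": ["Proteobacteria"] * 4},
        index=pd.Index(counts.columns, name="asv_id"),
    )
    meta = pd.DataFrame(
        {
            "treatment": ["Ctrl", "Ctrl", "Ctrl", "CM", "CM", "CM"],
            "timepoint_days": [7] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=counts.index,
    )
    return AsvTable(counts, taxonomy, "bacterial", meta)


def brute_force_bh(p_values):
    """Independent step-up BH oracle: literal definition, O(m^2)-naive."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted
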