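import warnings

import numpy as np
import pandas as pd
import pytest

from tepseq.synthetic_data import (DesignTable, SimConfig, balanced_design,
                                   build_confounded_design, simulate_counts)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact balanced cohort: 200 genes needed nowhere near QC scale.

    60-gene platelet-activation module, 40-gene biomarker module, two marker
    modules; 4 hospitals x (15 cases + 15 controls).
    """
    table = balanced_design(n_hospitals=4, cases_per_hospital=15, controls_per_hospital=15)
    meta = build_confounded_design(table, seed=10)
    cfg = SimConfig(n_genes=200, seed=10, hospital_effect_sd=0.5, case_effect_sd=0.5,
                    gene_modules={
                        "platelet_activation": np.arange(0, 60),
                        "biomarker": np.arange(60, 100),
                        "haemoglobin_markers": np.arange(100, 110),
                        "lymphocyte_markers": np.arange(110, 120),
                    })
    counts = simulate_counts(meta, cfg, seed=11)
    return counts, meta, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def skewed_design():
    return DesignTable(rows=(("H1", 50, 5), ("H2", 5, 50)))
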