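import numpy as np
import pytest

from fetalcentiles import make_cohort, study_config, table2_truth
from fetalcentiles.synthetic import CohortConfig

# Printed growth-table anchors used as paper-derived expectations.
TABLE2_GA = np.array([22.0, 26.0, 30.0, 34.0, 38.0])
TABLE2_VOLUMES = {
    "supratentorial": [43.26, 92.26, 153.31, 226.39, 311.52],
    "ventricles_total": [2.51, 3.29, 3.99, 4.60, 5.14],
    "cortex": [10.19, 17.38, 29.63, 50.51, 86.12],
    "cerebellum": [1.57, 3.77, 7.38, 12.38, 18.78],
    "ecsf": [26.90, 60.85, 84.43, 97.63, 100.45],
}
TABLE2_ABS_RATES = {
    "supratentorial": [10.75, 13.76, 16.77, 19.78, 22.79],
    "ventricles_total": [0.20, 0.18, 0.16, 0.14, 0.12],
    "cortex": [1.36, 2.32, 3.95, 6.74, 11.49],
    "cerebellum": [0.38, 0.73, 1.08, 1.43, 1.78],
    "ecsf": [9.78, 7.19, 4.60, 2.00, -0.59],
}


@pytest.fixture(scope="session")
def truth():
    return table2_truth()


@pytest.fixture(scope="session")
def study_cohort(truth):
    """Full synthetic study: 128 evaluated subjects with exclusion annotations."""
    return make_cohort(study_config(seed=1), truth)


@pytest.fixture(scope="session")
def big_cohort(truth):
    """Large cross-sectional cohort for Monte-Carlo fidelity checks."""
    config = CohortConfig(
        n_subjects=5000,
        n_twice_scanned=0,
        n_thrice_scanned=0,
        sex_counts=(2500, 2500),
        seed=7,
    )
    return make_cohort(config, truth)
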