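import numpy as np
import pytest

import serostab


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down cohort: 60 subjects, 5 modules, causal proteins planted."""
    causal_spec = {
        "causal_modules": {
            "TTSTAND_velocity": {"M01": 3, "M02": 2},
            "6MWT": {"M02": 2, "M03": 3},
        },
    }
    profile, series, truth = serostab.generate_cohort(
        n_subjects=60,
        n_proteins=260,
        module_sizes=(60, 50, 40, 30, 20),
        causal_spec=causal_spec,
        seed=11,
    )
    return serostab.log_transform(profile), series, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
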