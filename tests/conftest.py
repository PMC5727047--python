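import dataclasses

import pytest

from immunosig import panels, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The reference 11 control + 17 immunized cohort with default effects."""
    return synthetic.generate_cohort(synthetic.default_config(seed=1234))


@pytest.fixture(scope="session")
def null_cohort():
    """Same cohort sizes with every immunization effect removed."""
    return synthetic.generate_cohort(synthetic.null_config(seed=1234))


@pytest.fixture(scope="session")
def spl_std(default_cohort):
    return panels.standardize(
        panels.build_feature_matrix(default_cohort, "SPL", "ann_markers")
    )


@pytest.fixture(scope="session")
def big_null_cohort():
    """A 100 + 100 effect-free cohort restricted to SPL, for estimator checks."""
    cfg = dataclasses.replace(
        synthetic.null_config(seed=77),
        n_control=100,
        n_immunized=100,
        tissues=("SPL",),
        tissue_availability={"SPL": 1.0},
        effect_map={},
        count_model={"SPL": (5.0e5, 5.0)},
        cd45_level={"SPL": (0.60, 20.0)},
    )
    return synthetic.generate_cohort(cfg)
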