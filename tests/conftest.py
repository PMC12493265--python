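import numpy as np
import pandas as pd
import pytest

import soilheat as sh
from soilheat.design import DesignSpec


@pytest.fixture(scope="session")
def study_scale_study():
    """Study-scale synthetic dataset with the default planted effects."""
    cp = sh.default_collembola_params()
    fp = sh.default_fungal_params()
    ap = sh.default_association_params(cp, fp)
    return sh.simulate_study(cp, fp, ap, seed=11)


@pytest.fixture(scope="session")
def small_spec():
    return DesignSpec(
        n_blocks=2,
        elevations=("high", "low"),
        seasons=("spring", "summer"),
        plots_per_site_season=3,
        harvests=("H1", "H2"),
    )


@pytest.fixture(scope="session")
def h2_frame(study_scale_study):
    units = study_scale_study.units
    return units[units["harvest"] == "H2"]
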