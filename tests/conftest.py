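import numpy as np
import pytest

from albistat.cohort import assign_groups_frame, filter_frame
from albistat.simulate import DiseaseModelConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration simulated cohort (204 cases / 20,350
    controls), classified and filtered — shared across tests."""
    cfg = DiseaseModelConfig(seed=42)
    cohort = simulate_cohort(cfg, with_traits=True)
    classified = assign_groups_frame(cohort.frame)
    kept, exclusions = filter_frame(classified)
    return {"config": cfg, "raw": cohort.frame, "classified": classified,
            "kept": kept, "exclusions": exclusions}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
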