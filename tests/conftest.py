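import numpy as np
import pytest

import cohortcal as cc
from cohortcal.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def small_study():
    """A small confounded study with a true HR of 1.5 and 25 controls."""
    cfg = SimConfig(seed=42, n_target=1500, n_comparator=1500,
                    n_covariates=120, n_confounders=10,
                    true_log_hr=float(np.log(1.5)), n_negative_controls=25)
    return cc.generate_study(cfg)


@pytest.fixture(scope="session")
def small_result(small_study):
    """Full pipeline output on the small study (shared across tests)."""
    return cc.run_analysis(small_study, cc.AnalysisSettings(seed=42))
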