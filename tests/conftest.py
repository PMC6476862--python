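import numpy as np
import pytest

import onsetmod as om


@pytest.fixture(scope="session")
def emulation_cohort():
    """Default study-emulation cohort (n=78, 65 markers), shared read-only."""
    return om.simulate_cohort(om.default_emulation_config(seed=101))


@pytest.fixture(scope="session")
def small_pedigree_kinship():
    """n=100 pedigree kinship reused by calibration tests."""
    cfg = om.SimConfig(n_samples=100, n_markers=5, founder_count=12,
                       pedigree_depth=3, seed=7)
    ped, K = om.simulate_pedigree(cfg)
    return cfg, ped, K


@pytest.fixture(scope="session")
def qc_fixtures():
    return om.fixture_suite(seed=42)
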