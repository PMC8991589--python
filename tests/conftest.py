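import numpy as np
import pytest
from hypothesis import settings

import prsforge as pf
from prsforge.synthdata import SimulationConfig, SNPSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_panel():
    """24 SNPs, MAF 0.3, no effects."""
    return [SNPSpec(f"rs{k}", 0.3, 0.0) for k in range(24)]


@pytest.fixture(scope="session")
def effect_panel():
    """24 SNPs with realistic MAFs and log-ORs, no LD."""
    return pf.default_panel(24, seed=7, n_ld_blocks=0)


@pytest.fixture(scope="session")
def small_cohort(effect_panel):
    """1000-sample case-control cohort with genetic signal."""
    cfg = SimulationConfig(n_cases=500, n_controls=500, snps=effect_panel, seed=42)
    g, t = pf.simulate_cohort(cfg)
    return g, t


@pytest.fixture(scope="session")
def scored_cohort(effect_panel):
    """Cohort plus its true-liability score (well-specified case)."""
    cfg = SimulationConfig(n_cases=2500, n_controls=2500, snps=effect_panel, seed=21)
    g, t = pf.simulate_cohort(cfg)
    betas = np.array([s.log_or for s in effect_panel])
    scores = g.dosages @ betas
    return scores, pf.status_to_binary(t)
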