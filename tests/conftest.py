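import numpy as np
import pytest
from hypothesis import settings

import ascnassoc as aa

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def spec_both():
    """A mid-grid scenario: both CNV types, common allele."""
    return aa.ScenarioSpec(f_norm=0.5, cnv_type="both", f_b=0.35)


@pytest.fixture
def spec_del():
    return aa.ScenarioSpec(f_norm=0.8, cnv_type="del", f_b=0.5)


@pytest.fixture
def null_risk():
    return aa.RiskModel(1.0, 1.0)


def mc_control_frequencies(spec, n_draws, rng):
    """Brute-force oracle for the control state distribution.

    Draws two chromosomes carrying 0/1/2 copies, then an independent allele
    per copy — deliberately independent of the analytic binomial formula.
    """
    f_del, f_norm, f_dup = aa.chromosome_frequencies(spec)
    copies = rng.choice([0, 1, 2], p=[f_del, f_norm, f_dup], size=(n_draws, 2))
    cn = copies.sum(axis=1)
    b = rng.binomial(cn, spec.f_b)
    counts = np.zeros(len(aa.STATES))
    for i, s in enumerate(aa.STATES):
        counts[i] = np.sum((cn == s.cn) & (b == s.b_count))
    return counts / n_draws
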