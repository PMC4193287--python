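import numpy as np
import pytest

from netsig.trial_model import (
    GenericEffectTrial,
    MetaAnalysisData,
    TrialNetwork,
    TwoArmBinaryTrial,
    TwoArmContinuousTrial,
)


@pytest.fixture
def binary_ma():
    """Three binary trials of one comparison, mixed sizes and effects."""
    return MetaAnalysisData(
        comparison=("drug", "placebo"),
        trials=(
            TwoArmBinaryTrial(x_E=12, n_E=40, x_C=20, n_C=40, trial_id="b1"),
            TwoArmBinaryTrial(x_E=30, n_E=100, x_C=45, n_C=100, trial_id="b2"),
            TwoArmBinaryTrial(x_E=8, n_E=25, x_C=11, n_C=25, trial_id="b3"),
        ))


@pytest.fixture
def continuous_ma():
    return MetaAnalysisData(
        comparison=("drug", "placebo"),
        trials=(
            TwoArmContinuousTrial(m_E=-0.8, s_E=2.0, n_E=30,
                                  m_C=0.0, s_C=2.1, n_C=30, trial_id="c1"),
            TwoArmContinuousTrial(m_E=-0.3, s_E=1.5, n_E=80,
                                  m_C=0.1, s_C=1.6, n_C=75, trial_id="c2"),
        ))


@pytest.fixture
def generic_ma():
    return MetaAnalysisData(
        comparison=("drug", "placebo"),
        trials=(
            GenericEffectTrial(estimate=-0.45, se=0.15, scale_tag="smd", trial_id="g1"),
            GenericEffectTrial(estimate=-0.10, se=0.20, scale_tag="smd", trial_id="g2"),
            GenericEffectTrial(estimate=-0.30, se=0.09, scale_tag="smd", trial_id="g3"),
        ))


@pytest.fixture
def small_network(binary_ma):
    other = MetaAnalysisData(
        comparison=("otherdrug", "placebo"),
        trials=(
            TwoArmBinaryTrial(x_E=5, n_E=30, x_C=9, n_C=32, trial_id="o1"),
            TwoArmBinaryTrial(x_E=22, n_E=60, x_C=35, n_C=58, trial_id="o2"),
        ))
    return TrialNetwork(meta_analyses=(binary_ma, other))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
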