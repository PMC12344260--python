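import numpy as np
import pytest

from eegpress import concordance, synth
from eegpress.edf_io import EpochMatrix


@pytest.fixture(scope="session")
def schema():
    return concordance.default_schema()


@pytest.fixture(scope="session")
def toy_schema():
    """A 3-level toy template for brute-force scoring checks."""
    text = """
numeric_threshold: 0.20
categories:
  - name: hyperexcitability
    majors:
      - id: t.major
        label: toy major
        response: binary
        penalty: 6
        children:
          - id: t.q1
            label: toy nominal qualifier
            response: nominal
            levels: [a, b, c]
            penalty: 2
            children:
              - {id: t.q1.sub, label: nested numeric, response: numeric, penalty: 1}
          - {id: t.q2, label: toy numeric qualifier, response: numeric, penalty: 2}
"""
    return concordance.load_schema(text, require_standard=False)


@pytest.fixture(scope="session")
def diffuse_recording():
    """20 s of seeded diffuse slowing, 21 channels at 256 Hz."""
    return synth.generate(
        synth.ScenarioSpec(scenario="diffuse_slowing", duration_s=20.0, seed=11)
    )


@pytest.fixture(scope="session")
def smooth_epoch(diffuse_recording):
    """One 10-s low-rank, low-frequency epoch."""
    from eegpress.edf_io import segment_epochs

    return segment_epochs(diffuse_recording, 10.0)[0]


def make_epoch(data, fs=256.0, index=0):
    return EpochMatrix(data=np.asarray(data, dtype=float), fs=fs, epoch_index=index)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
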