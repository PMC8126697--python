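import datetime as dt

import numpy as np
import pytest

from ictalnet.io import SAMPLES_PER_EPOCH, IEEGEpoch, OnsetAnnotation, quantize_adc
from ictalnet.synthetic import make_patient_profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def profile():
    return make_patient_profile(0, master_seed=42)


@pytest.fixture
def background_epoch(rng):
    """A plain non-ictal epoch with quantized low-amplitude noise."""
    samples = quantize_adc(rng.normal(0.0, 20.0, size=(4, SAMPLES_PER_EPOCH)))
    epoch = IEEGEpoch(
        samples=samples,
        patient_id="P00",
        recorded_at=dt.datetime(2021, 3, 1, 12, 0, 0),
        trigger="scheduled",
    )
    return epoch, OnsetAnnotation(s=0)


@pytest.fixture
def ictal_epoch(profile, rng):
    from ictalnet.synthetic import generate_ictal_epoch

    epoch, ann = generate_ictal_epoch(profile, 45.0, rng)
    epoch.samples = quantize_adc(epoch.samples)
    return epoch, ann


class ForcedRng:
    """Generator stub returning scripted values for integers()/uniform()."""

    def __init__(self, integers=None, uniforms=None):
        self._integers = list(integers or [])
        self._uniforms = list(uniforms or [])

    def integers(self, low, high=None, **kw):
        return self._integers.pop(0)

    def uniform(self, low=0.0, high=1.0, **kw):
        if self._uniforms:
            return self._uniforms.pop(0)
        return (low + high) / 2.0


@pytest.fixture
def forced_rng_factory():
    return ForcedRng
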