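import numpy as np
import pytest

import habmpm as h


@pytest.fixture(scope="session")
def default_spec() -> h.PhantomSpec:
    return h.PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> h.PhantomSpec:
    """Reduced grid for fast unit tests; all structures still fit."""
    return h.PhantomSpec(grid_dims=(32, 44, 32), cohort_size=4)


@pytest.fixture(scope="session")
def template(default_spec) -> h.SubjectTruth:
    return h.build_template(default_spec)


@pytest.fixture(scope="session")
def small_template(small_spec) -> h.SubjectTruth:
    return h.build_template(small_spec)


@pytest.fixture(scope="session")
def protocol() -> h.AcquisitionProtocol:
    return h.default_protocol()


@pytest.fixture(scope="session")
def subject1(small_template, small_spec) -> h.SubjectTruth:
    return h.sample_subject(small_template, small_spec, 1)


@pytest.fixture(scope="session")
def noisy_echoes(subject1, small_spec, protocol) -> h.EchoVolumeSet:
    clean = h.simulate_flash(subject1, protocol)
    return h.add_noise(clean, small_spec, seed=424242)


@pytest.fixture(scope="session")
def clean_echoes(subject1, protocol) -> h.EchoVolumeSet:
    return h.simulate_flash(subject1, protocol)


@pytest.fixture(scope="session")
def fitted_maps(noisy_echoes, subject1) -> h.QuantMaps:
    return h.fit_maps(
        noisy_echoes,
        wm_mask=subject1.tissue_probs["wm"] > 0.5,
        mask=subject1.brain_mask,
    )
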