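"""Shared fixtures: phantoms and simulated acquisitions reused across modules.

The expensive objects (96-grid brain phantom, noiseless orthogonal
acquisitions, a full SR build) are session-scoped; tests must not mutate
them.
"""

import dataclasses

import numpy as np
import pytest

from srqt2 import (GridSpec, make_brain_phantom, make_nist_like_phantom,
                   multi_orientation_protocols, simulate_acquisition)
from srqt2.registration import build_sr_template

GRID_96 = GridSpec((96, 96, 96), (1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def brain_phantom():
    return make_brain_phantom(GRID_96, seed=1)


@pytest.fixture(scope="session")
def nist_phantom():
    return make_nist_like_phantom(GRID_96, seed=1)


@pytest.fixture(scope="session")
def noiseless_acqs(brain_phantom):
    """Noiseless axial/sagittal/coronal acquisitions at the three TEs."""
    protos = multi_orientation_protocols(noise_sigma=0.0)
    return protos, [simulate_acquisition(brain_phantom, p, seed=i)
                    for i, p in enumerate(protos)]


@pytest.fixture(scope="session")
def noiseless_single_te_acqs(brain_phantom):
    """Three orthogonal noiseless acquisitions sharing one TE (122.8 ms)."""
    protos = [dataclasses.replace(p, te=122.8)
              for p in multi_orientation_protocols(noise_sigma=0.0)]
    return protos, [simulate_acquisition(brain_phantom, p, seed=i)
                    for i, p in enumerate(protos)]


@pytest.fixture(scope="session")
def sr_single_te(noiseless_single_te_acqs):
    _, acqs = noiseless_single_te_acqs
    return build_sr_template(acqs, target_spacing=1.5, n_iterations=3)


@pytest.fixture(scope="session")
def sr_multi_te(noiseless_acqs):
    _, acqs = noiseless_acqs
    return build_sr_template(acqs, target_spacing=1.5, n_iterations=3)
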