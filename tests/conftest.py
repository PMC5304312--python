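import numpy as np
import pytest

from oculopulse import (
    SyntheticTruth,
    decompose_response,
    deformation_profile,
    extract_contours,
    render_deformation_sequence,
)


@pytest.fixture(scope="session")
def default_truth():
    return SyntheticTruth(seed=5)


@pytest.fixture(scope="session")
def rendered(default_truth):
    """Default-noise render of the default ground truth."""
    seq, truth = render_deformation_sequence(default_truth)
    return seq, truth


@pytest.fixture(scope="session")
def noiseless_rendered(default_truth):
    seq, truth = render_deformation_sequence(default_truth, noise_sd=0.0)
    return seq, truth


@pytest.fixture(scope="session")
def extracted(rendered):
    """Contours, decomposition and profile of the default-noise render."""
    seq, truth = rendered
    contours = extract_contours(seq)
    decomp = decompose_response(contours)
    profile = deformation_profile(contours, decomp)
    return contours, decomp, profile, truth


@pytest.fixture(scope="session")
def noiseless_extracted(noiseless_rendered):
    seq, truth = noiseless_rendered
    contours = extract_contours(seq)
    decomp = decompose_response(contours)
    profile = deformation_profile(contours, decomp)
    return contours, decomp, profile, truth
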