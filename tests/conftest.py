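import numpy as np
import pytest

import hepzone as hz

#: Coarser-than-native calibration used by unit tests to keep rasters small.
COARSE_PS = 200.0 / 256.0  # um / px


@pytest.fixture(scope="session")
def d2_section():
    """One PHx+Gln day-2 half-millimetre section with ground truth."""
    profile = hz.get_profile("PHx+Gln", 2)
    return hz.generate_section(profile, 0.5, 0.5, COARSE_PS, seed=11)


@pytest.fixture(scope="session")
def d2_analysis(d2_section):
    image, _ = d2_section
    return hz.analyze_section(image)


@pytest.fixture(scope="session")
def quiet_section():
    """A sham baseline section: no steatosis, sparse collagen, two PT + one CV."""
    profile = hz.get_profile("sham+Gln", 0)
    return hz.generate_section(
        profile, 0.5, 0.5, COARSE_PS, seed=5, pt_count=2, cv_count=1
    )


def brute_force_otsu(hist):
    """Independent exhaustive-search oracle for the 256-bin Otsu threshold."""
    hist = np.asarray(hist, dtype=np.int64)
    levels = np.arange(256, dtype=np.float64)
    n_total = float(hist.sum())
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        n0 = float(hist[:t].sum())
        n1 = n_total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = float((levels[:t] * hist[:t]).sum()) / n0
        mu1 = float((levels[t:] * hist[t:]).sum()) / n1
        var = (n0 / n_total) * (1.0 - n0 / n_total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t, best_var
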