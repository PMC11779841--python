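import numpy as np
import pytest

from biofilmnmr.spectra import Spectrum1D
from biofilmnmr.synthetic import build_scenario


@pytest.fixture(scope="session")
def default_scenario():
    return build_scenario(seed=7)


@pytest.fixture(scope="session")
def two_phase_scenario():
    """Single-component scenario with a known 0.91 mobile fraction and a
    0.5 s / 20 s mobile/rigid T1 split."""
    cfg = {
        "components": {
            "matrix": {
                "peaks": [(90.0, 0.6, 0.5), (40.0, 0.9, 0.5)],
                "biomass_by_day": {d: 1.0 for d in range(1, 6)},
                "mobile_fraction_by_day": {d: 0.91 for d in range(1, 6)},
                "t1_mobile_s": 0.5,
                "t1_rigid_s": 20.0,
            }
        }
    }
    return build_scenario(cfg, seed=1)


def lorentzian_spectrum(center=90.0, hwhm=0.5, area=1.0, lo=0.0, hi=200.0, n=8192,
                        descending=True, **meta):
    """Analytic unit-area Lorentzian as a qDP spectrum (test helper)."""
    ppm = np.linspace(hi, lo, n) if descending else np.linspace(lo, hi, n)
    intensity = area * (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)
    defaults = dict(sample_mass_mg=1.0, n_scans=1, mode="qDP", day=1)
    defaults.update(meta)
    return Spectrum1D(ppm, intensity, **defaults)
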