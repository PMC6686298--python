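import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def metadata_csv(tmp_path):
    """A small well-formed fish metadata file."""
    path = tmp_path / "metadata.csv"
    path.write_text(
        "fish_id,island,phenotype,capture_depth_m\n"
        "MA-B-01,Makobe,blue,1.5\n"
        "MA-R-01,Makobe,red,5.0\n"
        "LU-I-01,Luanso,intermediate,2.0\n"
    )
    return path


@pytest.fixture
def flat_spectrum():
    """Unit irradiance on a 1 nm grid over 400-700 nm."""
    wl = np.arange(400.0, 701.0)
    return wl, np.ones_like(wl)


def spectra_frame(island="Makobe", date="2010-05-22", depth=1.0, replicate=1,
                  wavelengths=None, irradiance=None):
    if wavelengths is None:
        wavelengths = np.arange(400.0, 701.0)
    if irradiance is None:
        irradiance = np.ones_like(wavelengths)
    return pd.DataFrame(
        {
            "island": island,
            "date": date,
            "depth_m": depth,
            "replicate": replicate,
            "wavelength_nm": wavelengths,
            "irradiance": irradiance,
        }
    )
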