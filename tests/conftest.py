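import numpy as np
import pytest

from fluorogut.spectra import (
    AcquisitionRecord,
    Channel,
    DyeConfig,
    FLUORESCEIN,
    Spectrum,
)


@pytest.fixture
def grid():
    """Default wavelength grid, 350-900 nm at 0.5 nm."""
    return 350.0 + 0.5 * np.arange(1101)


def make_spectrum(
    grid,
    intensities,
    integration_time_s=1.0,
    timestamp_s=0.0,
    channel=Channel.FLUORESCENCE,
):
    return Spectrum(
        wavelengths_nm=grid,
        intensities=np.asarray(intensities, dtype=float),
        integration_time_s=integration_time_s,
        timestamp_s=timestamp_s,
        channel=channel,
    )


def make_record(
    grid,
    fluor_level=0.0,
    laser_level=1000.0,
    fluor_background=10.0,
    laser_background=1.0,
    t_f=1.0,
    t_l=1e-3,
    timestamp_s=0.0,
    dye=FLUORESCEIN,
):
    """Flat-band synthetic record: fluor_level counts added inside the
    emission band, laser_level inside the laser band, on flat backgrounds."""
    lam = grid
    fl = np.full(lam.size, fluor_background)
    e_lo, e_hi = dye.emission_band_nm
    fl[(lam >= e_lo) & (lam <= e_hi)] += fluor_level
    la = np.full(lam.size, laser_background)
    l_lo, l_hi = dye.laser_band_nm
    la[(lam >= l_lo) & (lam <= l_hi)] += laser_level
    return AcquisitionRecord(
        fluorescence=make_spectrum(
            lam, fl, t_f, timestamp_s, Channel.FLUORESCENCE
        ),
        laser=make_spectrum(lam, la, t_l, timestamp_s, Channel.LASER),
    )
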