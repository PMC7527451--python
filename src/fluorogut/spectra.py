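"""Background-subtracted band integration and laser-power normalisation.

A transcutaneous measurement consists of a fluorescence spectrum paired
with a backscattered-laser spectrum recorded immediately afterwards.  The
quantity of interest is the *normalised integrated fluorescence intensity*

    I_int = (sum over emission band of (I(lam) - B_F)) * t_L
            -----------------------------------------------
            (sum over laser band    of (L(lam) - B_L)) * t_F

where B_F and B_L are per-spectrum backgrounds (mean intensity over a
signal-free window, 350-450 nm by default), and t_F, t_L are the
integration times of the fluorescence and laser spectra.  Normalising by
the in-band laser power measured *at the skin* cancels laser-power
fluctuation, probe-contact pressure and skin-tone effects, so I_int can be
compared across time points, body sites and participants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .errors import EmptyBandError, LaserNormalizationError

__all__ = [
    "Channel",
    "Spectrum",
    "AcquisitionRecord",
    "DyeConfig",
    "BandSum",
    "FLUORESCEIN",
    "ICG",
    "get_dye",
    "estimate_background",
    "integrate_band",
    "normalized_intensity",
]

Band = Tuple[float, float]


class Channel(str, enum.Enum):
    FLUORESCENCE = "fluorescence"
    LASER = "laser"


@dataclass(frozen=True)
class Spectrum:
    """One wavelength-resolved intensity measurement.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    intensities
        Detector counts, same length as the grid.
    integration_time_s
        Total integration (exposure) time in seconds; must be positive.
    timestamp_s
        Seconds since the start of the measurement session.
    channel
        Whether this is a fluorescence or a backscattered-laser spectrum.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    integration_time_s: float
    timestamp_s: float
    channel: Channel

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "channel", Channel(self.channel))
        if wl.ndim != 1 or inten.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if wl.size != inten.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {inten.size} intensities"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not self.integration_time_s > 0:
            raise ValueError("integration_time_s must be positive")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


#: Maximum tolerated lag between a fluorescence spectrum and its paired
#: laser spectrum.  The laser spectrum is recorded immediately after the
#: fluorescence spectrum; a large gap risks anomalous normalisation if the
#: probe moved in between.
MAX_PAIR_LAG_S = 30.0


@dataclass(frozen=True)
class AcquisitionRecord:
    """A paired (fluorescence, laser) measurement at one time point."""

    fluorescence: Spectrum
    laser: Spectrum

    def __post_init__(self) -> None:
        if self.fluorescence.channel is not Channel.FLUORESCENCE:
            raise ValueError("fluorescence slot holds a non-fluorescence spectrum")
        if self.laser.channel is not Channel.LASER:
            raise ValueError("laser slot holds a non-laser spectrum")
        lag = abs(self.fluorescence.timestamp_s - self.laser.timestamp_s)
        if lag > MAX_PAIR_LAG_S:
            raise ValueError(
                f"fluorescence/laser pair separated by {lag:.1f} s "
                f"(> {MAX_PAIR_LAG_S:.0f} s); refusing pair, normalisation "
                "would be unreliable"
            )

    @property
    def time_s(self) -> float:
        """Session-clock time of the record (from the fluorescence spectrum)."""
        return float(self.fluorescence.timestamp_s)


@dataclass(frozen=True)
class DyeConfig:
    """Spectral bands for one contrast agent.

    ``emission_band_nm`` is the window summed to form the integrated
    fluorescence value; ``laser_band_nm`` the window summed on the
    backscattered-laser spectrum; ``background_band_nm`` the signal-free
    window whose mean serves as the per-spectrum background.
    """

    name: str
    emission_band_nm: Band
    laser_band_nm: Band
    background_band_nm: Band = (350.0, 450.0)

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("emission_band_nm", self.emission_band_nm),
            ("laser_band_nm", self.laser_band_nm),
            ("background_band_nm", self.background_band_nm),
        ):
            if not lo < hi:
                raise ValueError(f"{label}: need lo < hi, got ({lo}, {hi})")
        e_lo, e_hi = self.emission_band_nm
        l_lo, l_hi = self.laser_band_nm
        if e_lo <= l_hi and l_lo <= e_hi:
            raise ValueError("emission band must be disjoint from laser band")


FLUORESCEIN = DyeConfig(
    name="fluorescein",
    emission_band_nm=(500.0, 580.0),
    laser_band_nm=(485.0, 492.0),
)

ICG = DyeConfig(
    name="icg",
    emission_band_nm=(800.0, 880.0),
    laser_band_nm=(778.0, 785.0),
)

_DYES = {d.name: d for d in (FLUORESCEIN, ICG)}


def get_dye(name: str) -> DyeConfig:
    """Look up a built-in dye configuration by name."""
    try:
        return _DYES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown dye {name!r}; known dyes: {sorted(_DYES)}"
        ) from None


@dataclass(frozen=True)
class BandSum:
    """Background-subtracted summed counts over a band."""

    value: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _band_indices(spec: Spectrum, band: Band) -> np.ndarray:
    lo, hi = band
    return np.flatnonzero((spec.wavelengths_nm >= lo) & (spec.wavelengths_nm <= hi))


def estimate_background(spec: Spectrum, band: Band = (350.0, 450.0)) -> float:
    """Mean intensity over a signal-free wavelength window (inclusive).

    Raises
    ------
    EmptyBandError
        If no grid sample falls inside the window.
    """
    idx = _band_indices(spec, band)
    if idx.size == 0:
        raise EmptyBandError(
            f"empty background window {band} on grid "
            f"[{spec.wavelengths_nm[0]:g}, {spec.wavelengths_nm[-1]:g}] nm"
        )
    return float(np.mean(spec.intensities[idx]))


def integrate_band(spec: Spectrum, band: Band, background: float) -> BandSum:
    """Sum background-subtracted counts over a closed band.

    Band endpoints are inclusive and sums run over native grid samples (no
    interpolation).  Negative background-subtracted samples are retained so
    that pure-noise spectra integrate to ~0 on average.
    """
    idx = _band_indices(spec, band)
    if idx.size == 0:
        raise EmptyBandError(
            f"empty band {band} on grid "
            f"[{spec.wavelengths_nm[0]:g}, {spec.wavelengths_nm[-1]:g}] nm"
        )
    value = float(np.sum(spec.intensities[idx] - background))
    return BandSum(value=value, n_samples=int(idx.size))


def normalized_intensity(rec: AcquisitionRecord, dye: DyeConfig) -> float:
    """Normalised integrated fluorescence intensity of one record.

    Background is estimated independently on each channel's own spectrum
    over ``dye.background_band_nm``; the emission and laser band sums are
    then combined with the two integration times:

        I_int = (fluor_sum * t_L) / (laser_sum * t_F)

    Raises
    ------
    LaserNormalizationError
        If the laser band sum is not positive (occluded probe).
    """
    fl, la = rec.fluorescence, rec.laser
    b_f = estimate_background(fl, dye.background_band_nm)
    b_l = estimate_background(la, dye.background_band_nm)
    fluor = integrate_band(fl, dye.emission_band_nm, b_f)
    laser = integrate_band(la, dye.laser_band_nm, b_l)
    if laser.value <= 0:
        raise LaserNormalizationError(
            f"laser normalization failure at t={rec.time_s:g} s: "
            f"band sum {laser.value:g} <= 0 (occluded probe?)"
        )
    return (fluor.value * la.integration_time_s) / (
        laser.value * fl.integration_time_s
    )
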