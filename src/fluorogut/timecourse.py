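"""Uptake time-course assembly, peak detection and the AUC-to-peak marker.

After oral ingestion the normalised fluorescence intensity rises as dye is
absorbed from the small intestine into blood, peaks when absorption and
elimination balance, and decays.  Two statistics summarise the curve:

* **time-to-peak** — sensitive to gastric emptying rate (slower emptying,
  e.g. a milkshake vehicle, pushes the peak later);
* **AUC-to-peak** — the trapezoidal area under the curve from ingestion to
  the *first* peak, an estimate of the total amount of dye that has crossed
  the gut barrier and hence a marker of intestinal permeability
  (analogous to total lactulose recovery in urinary permeability assays,
  but with the collection window anchored at the blood-concentration peak).

The first local maximum is used rather than the global maximum because at
sensing sites where blood vessels lie deep (forearm, wrist) the signal
keeps rising after the blood peak as dye leaks into the epidermis; that
late rise is not a permeability signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import DuplicateTimestampError, NoPeakError
from .spectra import AcquisitionRecord, DyeConfig, normalized_intensity

__all__ = [
    "TimeCourse",
    "PeakResult",
    "AucResult",
    "assemble_timecourse",
    "baseline_subtract",
    "detect_peak",
    "auc_to_peak",
    "compare_conditions",
]

#: Intensity ranges below this (absolute, normalised units) are treated as flat.
FLAT_TOL = 1e-12

#: Detection-significance multiplier: the post-ingestion excursion must
#: exceed this many standard deviations of the pre-ingestion baseline
#: (when >= 3 baseline points are available) to count as a detected peak.
MIN_SNR = 5.0


@dataclass(frozen=True)
class TimeCourse:
    """Ordered (time, I_int) series with the ingestion time as origin."""

    times_s: np.ndarray
    intensities: np.ndarray
    t_ingest_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and intensities must be 1-D, same length")
        if t.size == 0:
            raise ValueError("empty time course")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def pre_mask(self) -> np.ndarray:
        return self.times_s < self.t_ingest_s

    @property
    def post_mask(self) -> np.ndarray:
        return self.times_s >= self.t_ingest_s


@dataclass(frozen=True)
class PeakResult:
    """First uptake peak of a time course (session-clock coordinates)."""

    t_peak_s: float
    i_peak: float
    time_to_peak_s: float
    fallback: bool = False  # True when no qualifying local max existed


@dataclass(frozen=True)
class AucResult:
    """Area under the baseline-subtracted curve from ingestion to peak.

    ``auc`` is in normalised-intensity x hours (time rescaled from seconds
    to hours purely as a reporting convention; condition *ratios* are
    unit-independent).
    """

    auc: float
    t_start_s: float
    t_end_s: float


def assemble_timecourse(
    records: Sequence[AcquisitionRecord],
    dye: DyeConfig,
    t_ingest_s: float,
) -> TimeCourse:
    """Apply the spectral normalisation to every record, ordered by time."""
    if len(records) == 0:
        raise ValueError("no acquisition records")
    recs = sorted(records, key=lambda r: r.time_s)
    times = np.array([r.time_s for r in recs], dtype=float)
    dups = np.flatnonzero(np.diff(times) == 0)
    if dups.size:
        raise DuplicateTimestampError(
            f"duplicate timestamp {times[dups[0]]:g} s in record stream"
        )
    intens = np.array([normalized_intensity(r, dye) for r in recs], dtype=float)
    return TimeCourse(times_s=times, intensities=intens, t_ingest_s=float(t_ingest_s))


def baseline_subtract(tc: TimeCourse) -> TimeCourse:
    """Subtract the mean pre-ingestion intensity from the whole curve.

    The per-spectrum background subtraction already removes most of the
    skin autofluorescence; this removes any residual constant offset using
    measurements taken before the dye was ingested.  With no pre-ingestion
    points the curve is returned unchanged with a warning.
    """
    pre = tc.pre_mask
    if not pre.any():
        warnings.warn(
            "no pre-ingestion points; baseline subtraction skipped", stacklevel=2
        )
        return tc
    offset = float(np.mean(tc.intensities[pre]))
    return TimeCourse(
        times_s=tc.times_s,
        intensities=tc.intensities - offset,
        t_ingest_s=tc.t_ingest_s,
    )


def _moving_average(t: np.ndarray, y: np.ndarray, window_s: float) -> np.ndarray:
    """Centred moving average on a possibly irregular time grid."""
    if window_s <= 0:
        return y.copy()
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(y)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_peak(
    tc: TimeCourse,
    smooth_window_s: float = 300.0,
    min_prominence_frac: float = 0.1,
    min_snr: float = MIN_SNR,
) -> PeakResult:
    """Locate the first uptake peak after ingestion.

    The post-ingestion series is smoothed with a centred moving average of
    width ``smooth_window_s`` (smoothing is used only to localise the peak;
    AUC computations use the raw curve).  The peak is the first local
    maximum whose prominence is at least ``min_prominence_frac`` of the
    total excursion above baseline; if none qualifies the global maximum is
    returned with ``fallback=True`` and a warning.  The reported time and
    intensity are taken from the unsmoothed grid at the sample of the
    smoothed maximum.

    Raises
    ------
    NoPeakError
        If the curve is flat to numerical tolerance, or — when at least
        three pre-ingestion points are available — if the post-ingestion
        excursion above baseline is below ``min_snr`` baseline standard
        deviations (signal below the detection limit).
    """
    post = tc.post_mask
    if int(post.sum()) < 3:
        raise ValueError("need >= 3 post-ingestion points to detect a peak")
    t = tc.times_s[post]
    y = tc.intensities[post]

    pre_y = tc.intensities[tc.pre_mask]
    baseline = float(np.mean(pre_y)) if pre_y.size else float(np.min(y))

    excursion = float(np.max(y) - baseline)
    if float(np.max(y) - np.min(y)) < FLAT_TOL or excursion < FLAT_TOL:
        raise NoPeakError("no peak: curve is flat to numerical tolerance")
    if pre_y.size >= 3:
        noise_sd = float(np.std(pre_y))
        if excursion < min_snr * noise_sd:
            raise NoPeakError(
                f"no peak: excursion {excursion:.3g} below detection limit "
                f"({min_snr:g} x baseline SD {noise_sd:.3g})"
            )

    ys = _moving_average(t, y, smooth_window_s)
    prominence = min_prominence_frac * max(float(np.max(ys) - baseline), FLAT_TOL)
    peaks, _ = find_peaks(ys, prominence=prominence)
    if peaks.size:
        i = int(peaks[0])
        fallback = False
    else:
        i = int(np.argmax(ys))
        fallback = True
        warnings.warn(
            "no local maximum with sufficient prominence; "
            "falling back to global maximum",
            stacklevel=2,
        )
    return PeakResult(
        t_peak_s=float(t[i]),
        i_peak=float(y[i]),
        time_to_peak_s=float(t[i] - tc.t_ingest_s),
        fallback=fallback,
    )


def auc_to_peak(tc: TimeCourse, peak: PeakResult) -> AucResult:
    """Trapezoidal area under the curve from ingestion to the peak.

    The curve should be baseline-subtracted first.  Integration limits are
    ``t_ingest_s`` and ``peak.t_peak_s``; boundary values are linearly
    interpolated if no sample falls exactly on a limit.  Time is rescaled
    to hours for reporting.
    """
    t0, t1 = tc.t_ingest_s, peak.t_peak_s
    if t1 <= t0:
        raise ValueError(f"peak time {t1:g} s is not after ingestion {t0:g} s")
    inner = (tc.times_s > t0) & (tc.times_s < t1)
    grid = np.concatenate(([t0], tc.times_s[inner], [t1]))
    vals = np.interp(grid, tc.times_s, tc.intensities)
    auc = float(np.trapezoid(vals, grid)) / 3600.0
    return AucResult(auc=auc, t_start_s=float(t0), t_end_s=float(t1))


def compare_conditions(a: AucResult, b: AucResult) -> float:
    """AUC ratio between two conditions (e.g. with sugar / without sugar)."""
    if b.auc <= 0:
        raise ValueError(f"reference AUC must be positive, got {b.auc:g}")
    return a.auc / b.auc
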