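"""Guideline time- and frequency-domain HRV features for one RRI window.

Eleven features form the feature-based baseline input: meanNN, SDNN,
RMSSD, NN50, pNN50 (time domain) and TotalPower, LF, HF, LF/HF, LFnu,
HFnu (frequency domain).  All are computed on raw, unstandardized R-R
intervals in milliseconds — guideline units — and any per-feature
standardization happens later, across the training set.

Frequency-domain estimation: the irregularly sampled tachogram is
interpolated with a cubic spline onto a 4-Hz grid, mean-removed, and its
power spectral density estimated by Welch's method (64-s segments, 50%
overlap).  Band powers are the integrated PSD over VLF 0.0033-0.04 Hz,
LF 0.04-0.15 Hz and HF 0.15-0.40 Hz; TotalPower spans 0.0033-0.40 Hz.
Normalized units: LFnu = 100 * LF / (TotalPower - VLF), and analogously
for HFnu.  A zero HF power makes LF/HF undefined; it is reported as NaN,
never infinity.

The guideline asks for at least 2 min of data for spectral features; the
60-s screening window violates that deliberately, so the length check is
off by default and available via ``enforce_guideline``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import ValidationError

__all__ = [
    "HRVFeatureVector",
    "FEATURE_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "hrv_features",
]

FEATURE_NAMES = (
    "meanNN",
    "SDNN",
    "RMSSD",
    "NN50",
    "pNN50",
    "TotalPower",
    "LF",
    "HF",
    "LF_HF",
    "LFnu",
    "HFnu",
)

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0
WELCH_SEGMENT_S = 64.0
NN50_THRESHOLD_MS = 50.0
GUIDELINE_MIN_SPAN_S = 120.0


@dataclass(frozen=True)
class HRVFeatureVector:
    """The 11 guideline HRV features for one window (ms / ms^2 / % units)."""

    meanNN: float
    SDNN: float
    RMSSD: float
    NN50: float
    pNN50: float
    TotalPower: float = np.nan
    LF: float = np.nan
    HF: float = np.nan
    LF_HF: float = np.nan
    LFnu: float = np.nan
    HFnu: float = np.nan

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def time_domain_features(rri_window: np.ndarray) -> HRVFeatureVector:
    """Time-domain features of a window of R-R intervals (seconds in, ms out).

    meanNN and SDNN are the mean and sample (n-1) standard deviation of the
    intervals; RMSSD the root-mean-square of successive differences; NN50
    the count of successive differences exceeding 50 ms; pNN50 that count
    as a percentage of the n-1 differences.
    """
    rri = np.asarray(rri_window, dtype=float)
    if rri.size < 2:
        raise ValidationError("time-domain features need at least 2 beats")
    nn_ms = rri * 1000.0
    diffs = np.diff(nn_ms)
    nn50 = int(np.sum(np.abs(diffs) > NN50_THRESHOLD_MS))
    return HRVFeatureVector(
        meanNN=float(np.mean(nn_ms)),
        SDNN=float(np.std(nn_ms, ddof=1)),
        RMSSD=float(np.sqrt(np.mean(diffs**2))),
        NN50=float(nn50),
        pNN50=100.0 * nn50 / (rri.size - 1),
    )


def _band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float], closed_right: bool = False
) -> float:
    """Integrated PSD over a half-open band [lo, hi) using rectangle bins.

    Half-open bins keep VLF/LF/HF disjoint and additive, so
    TotalPower - VLF equals LF + HF exactly and the normalized units sum
    to 100 whenever LF + HF > 0.
    """
    df = float(freqs[1] - freqs[0]) if freqs.size > 1 else 0.0
    if closed_right:
        mask = (freqs >= band[0]) & (freqs <= band[1])
    else:
        mask = (freqs >= band[0]) & (freqs < band[1])
    return float(psd[mask].sum() * df)


def frequency_domain_features(
    rri_window: np.ndarray, enforce_guideline: bool = False
) -> HRVFeatureVector:
    """Spectral features of a window of R-R intervals (seconds in, ms^2 out).

    Parameters
    ----------
    rri_window : array of intervals in seconds
    enforce_guideline : bool
        When true, require the window to span >= 120 s.
    """
    rri = np.asarray(rri_window, dtype=float)
    if rri.size < 4:
        raise ValidationError("frequency-domain features need at least 4 beats")
    span = float(rri.sum())
    if enforce_guideline and span < GUIDELINE_MIN_SPAN_S:
        raise ValidationError(
            f"window spans {span:.1f} s; guideline requires >= {GUIDELINE_MIN_SPAN_S:.0f} s"
        )
    # tachogram value = interval (ms) at the time of its closing beat
    beat_times = np.cumsum(rri)
    nn_ms = rri * 1000.0
    grid = np.arange(beat_times[0], beat_times[-1], 1.0 / RESAMPLE_HZ)
    resampled = CubicSpline(beat_times, nn_ms)(grid)
    resampled = resampled - resampled.mean()
    nperseg = min(int(WELCH_SEGMENT_S * RESAMPLE_HZ), resampled.size)
    freqs, psd = sps.welch(resampled, fs=RESAMPLE_HZ, nperseg=nperseg)
    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND, closed_right=True)
    total = vlf + lf + hf
    denom = total - vlf
    lfnu = 100.0 * lf / denom if denom > 0 else np.nan
    hfnu = 100.0 * hf / denom if denom > 0 else np.nan
    return HRVFeatureVector(
        meanNN=float(np.mean(nn_ms)),
        SDNN=float(np.std(nn_ms, ddof=1)),
        RMSSD=float(np.sqrt(np.mean(np.diff(nn_ms) ** 2))),
        NN50=float(np.sum(np.abs(np.diff(nn_ms)) > NN50_THRESHOLD_MS)),
        pNN50=100.0 * float(np.sum(np.abs(np.diff(nn_ms)) > NN50_THRESHOLD_MS)) / (rri.size - 1),
        TotalPower=total,
        LF=lf,
        HF=hf,
        LF_HF=lf / hf if hf > 0 else np.nan,
        LFnu=lfnu,
        HFnu=hfnu,
    )


def hrv_features(rri_window: np.ndarray, enforce_guideline: bool = False) -> HRVFeatureVector:
    """All 11 features for one window: time domain merged with frequency domain."""
    td = time_domain_features(rri_window)
    fd = frequency_domain_features(rri_window, enforce_guideline=enforce_guideline)
    return HRVFeatureVector(
        meanNN=td.meanNN,
        SDNN=td.SDNN,
        RMSSD=td.RMSSD,
        NN50=td.NN50,
        pNN50=td.pNN50,
        TotalPower=fd.TotalPower,
        LF=fd.LF,
        HF=fd.HF,
        LF_HF=fd.LF_HF,
        LFnu=fd.LFnu,
        HFnu=fd.HFnu,
    )
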