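"""R-wave detection in single-lead ECG via the Pan-Tompkins algorithm.

Stages: band-pass (5-15 Hz, isolating QRS energy), differentiation,
squaring, 150-ms moving-window integration, then adaptive dual-threshold
peak classification with search-back.  The running signal/noise peak
estimates make every threshold relative to the input, so detection is
invariant to a positive rescaling of the trace.

The band-pass and integration here are zero-phase (``filtfilt`` and a
centered window), so the integrated-signal fiducial sits on the QRS
complex itself; the final R time is the maximum of the band-passed
signal within +/-50 ms of that fiducial.

No ectopic-beat or artifact rejection is performed: the screening model
consumes the raw beat sequence, arrhythmia and all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import RRISeries, ValidationError

__all__ = ["ECGTrace", "detect_r_peaks", "peaks_to_rri"]

# Pan-Tompkins constants (original publication's values)
INTEGRATION_WINDOW_S = 0.150
REFRACTORY_S = 0.200
BANDPASS_HZ = (5.0, 15.0)
SEARCHBACK_FACTOR = 1.66
REFINE_HALF_WINDOW_S = 0.050


@dataclass(frozen=True)
class ECGTrace:
    """A single-lead ECG: sample amplitudes (arbitrary units) at a fixed rate."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def _preprocess(trace: ECGTrace) -> tuple[np.ndarray, np.ndarray]:
    """Return (band-passed signal, moving-window-integrated energy)."""
    fs = trace.sampling_rate
    nyq = fs / 2.0
    b, a = sps.butter(3, [BANDPASS_HZ[0] / nyq, BANDPASS_HZ[1] / nyq], btype="band")
    bp = sps.filtfilt(b, a, trace.samples)
    # five-point derivative, as in the original formulation
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    squared = deriv**2
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return bp, integrated


def detect_r_peaks(trace: ECGTrace) -> list[float]:
    """Detect R-wave times (seconds from trace start), strictly increasing.

    A flat or peak-free trace yields an empty list with a warning rather
    than an exception.

    Raises
    ------
    ValidationError
        If the trace is shorter than 2 s of signal.
    """
    fs = trace.sampling_rate
    if trace.samples.size < 2 * fs:
        raise ValidationError("trace too short for QRS detection (< 2 s)")
    if float(np.ptp(trace.samples)) == 0.0:
        warnings.warn("flat ECG trace: no R peaks detected", stacklevel=2)
        return []

    bp, integrated = _preprocess(trace)
    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        warnings.warn("no candidate peaks in integrated signal", stacklevel=2)
        return []

    # learning phase: initialize signal/noise levels from the first 2 s
    head = integrated[: int(2 * fs)]
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(head.mean())

    accepted: list[int] = []
    rejected: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        peak = integrated[idx]
        # search-back: long gap since the last QRS -> revisit rejected peaks
        if accepted and rr_history:
            rr_avg = float(np.mean(rr_history[-8:]))
            if (idx - accepted[-1]) / fs > SEARCHBACK_FACTOR * rr_avg:
                window = [
                    r
                    for r in rejected
                    if accepted[-1] + refractory < r < idx - refractory
                ]
                if window:
                    back = max(window, key=lambda r: integrated[r])
                    if integrated[back] > 0.5 * threshold1():
                        rr_history.append((back - accepted[-1]) / fs)
                        accepted.append(back)
                        spki = 0.25 * float(integrated[back]) + 0.75 * spki
        if peak > threshold1():
            if accepted:
                rr_history.append((idx - accepted[-1]) / fs)
            accepted.append(idx)
            spki = 0.125 * float(peak) + 0.875 * spki
        else:
            rejected.append(idx)
            npki = 0.125 * float(peak) + 0.875 * npki

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold", stacklevel=2)
        return []

    # refine each fiducial to the band-passed maximum within +/-50 ms
    half = int(round(REFINE_HALF_WINDOW_S * fs))
    times = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(bp.size, idx + half + 1)
        times.append((lo + int(np.argmax(bp[lo:hi]))) / fs)
    # refinement can merge neighbours onto one sample; enforce monotonicity
    out: list[float] = []
    for t in sorted(times):
        if not out or t - out[-1] > REFRACTORY_S / 2:
            out.append(float(t))
    return out


def peaks_to_rri(peaks: list[float], subject_id: str) -> RRISeries:
    """Convert strictly increasing R-peak times to an RRI series.

    ``intervals[i] = peaks[i+1] - peaks[i]``; the first peak time becomes
    the series' ``origin_time``.
    """
    arr = np.asarray(peaks, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 peaks to form R-R intervals")
    if np.any(np.diff(arr) <= 0):
        raise ValidationError("peak times must be strictly increasing")
    return RRISeries(
        subject_id=subject_id, intervals=np.diff(arr), origin_time=float(arr[0])
    )
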