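"""Seeded synthetic cohorts with cyclical variation of heart rate (CVHR).

The generator emulates the screening study's raw material — a night of
R-R intervals per subject with expert-style apnea annotations — without
clinical data.  The instantaneous R-R interval is modeled as

    r(t) = base + rsa_amp * sin(2 pi 0.25 t)          (respiratory sinus
                                                       arrhythmia)
         + lf_amp * sin(2 pi 0.10 t + phi)            (baroreflex band)
         + cvhr_amp * sin(2 pi (t - t0) / period)     (during apnea
                                                       episodes only)

and beats are produced by integrate-and-fire: a beat fires whenever the
phase integral of 1/r(t) crosses an integer, giving exact ground truth
for both beat times and the modulation each beat carries.  Per-interval
Gaussian jitter models everything the sinusoids do not.

Patient records receive non-overlapping apnea episodes at a target rate
(events/hour); the CVHR oscillation extends 10 s before each onset and
after each offset, reflecting the observation that heart-rate changes
bracket the apnea itself.  The recorded AHI is the realized episode
count per hour, so the ground-truth label and group derive from what was
actually generated.

Synthetic single-lead ECG places a Gaussian-template QRS at every beat
time over baseline wander plus white noise, for exercising the QRS
detector end to end.  Ectopic-beat injection replaces a normal interval
pair with a premature/compensatory 0.6/1.4 split (pair sum conserved) to
probe arrhythmia-driven false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .ecg import ECGTrace
from .io import EventAnnotation, RRISeries, SubjectRecord, ValidationError

__all__ = [
    "SyntheticCohortSpec",
    "generate_subject",
    "generate_cohort",
    "generate_ecg",
    "inject_ectopics",
]

_PHASE_DT_S = 0.01  # integration grid for the phase integral


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator parameters; defaults are the study-like conditions."""

    n_patients: int = 10
    n_healthy: int = 10
    record_duration_s: float = 6 * 3600.0  # one night
    base_rri_s: float = 0.9
    rsa_amp_s: float = 0.03
    rsa_freq_hz: float = 0.25
    lf_amp_s: float = 0.02
    lf_freq_hz: float = 0.10
    cvhr_period_s: float = 60.0
    cvhr_amp_s: float = 0.15
    event_rate_per_h: float = 40.0
    event_duration_s: tuple[float, float] = (20.0, 60.0)
    pre_post_extension_s: float = 10.0
    ectopic_rate_per_h: float = 0.0
    noise_sd_s: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rri_s <= self.cvhr_amp_s + self.rsa_amp_s + self.lf_amp_s:
            raise ValidationError(
                "base_rri_s must exceed the summed modulation amplitudes"
            )
        if self.cvhr_period_s <= 0:
            raise ValidationError("cvhr_period_s must be > 0")
        lo, hi = self.event_duration_s
        if not (0 < lo <= hi):
            raise ValidationError("event_duration_s must satisfy 0 < lo <= hi")


def _place_episodes(spec: SyntheticCohortSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Non-overlapping (onset, duration) pairs at ~event_rate_per_h."""
    ext = spec.pre_post_extension_s
    mean_dur = float(np.mean(spec.event_duration_s))
    busy = mean_dur + 2 * ext + 1.0
    target_spacing = 3600.0 / spec.event_rate_per_h
    if target_spacing < busy + 1.0:
        raise ValidationError(
            f"event rate {spec.event_rate_per_h}/h cannot fit episodes of "
            f"~{busy:.0f} s (incl. pre/post extension) without overlap"
        )
    mean_gap = target_spacing - busy
    episodes: list[tuple[float, float]] = []
    cursor = ext  # earliest admissible onset keeps the extension in-record
    while True:
        onset = cursor + rng.exponential(mean_gap)
        duration = rng.uniform(*spec.event_duration_s)
        if onset + duration + ext > spec.record_duration_s - 1.0:
            break
        episodes.append((onset, duration))
        cursor = onset + duration + 2 * ext + 1.0
    return episodes


def _instantaneous_rri(
    spec: SyntheticCohortSpec,
    t: np.ndarray,
    episodes: Sequence[tuple[float, float]],
    phi: float,
) -> np.ndarray:
    r = (
        spec.base_rri_s
        + spec.rsa_amp_s * np.sin(2 * np.pi * spec.rsa_freq_hz * t)
        + spec.lf_amp_s * np.sin(2 * np.pi * spec.lf_freq_hz * t + phi)
    )
    ext = spec.pre_post_extension_s
    for onset, duration in episodes:
        t0, t1 = onset - ext, onset + duration + ext
        win = (t >= t0) & (t < t1)
        r[win] += spec.cvhr_amp_s * np.sin(
            2 * np.pi * (t[win] - t0) / spec.cvhr_period_s
        )
    return r


def _integrate_and_fire(r: np.ndarray, dt: float) -> np.ndarray:
    """Beat times where the cumulative phase 1/r(t) dt crosses integers."""
    phase = np.concatenate(([0.0], np.cumsum(dt / r)))
    t_grid = dt * np.arange(phase.size)
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(phase, targets)
    # linear interpolation inside the grid cell containing each crossing
    p0, p1 = phase[idx - 1], phase[idx]
    frac = (targets - p0) / (p1 - p0)
    return t_grid[idx - 1] + frac * dt


def generate_subject(
    spec: SyntheticCohortSpec,
    group: str,
    subject_id: str | None = None,
    seed: int | None = None,
) -> tuple[RRISeries, list[EventAnnotation], SubjectRecord]:
    """Generate one subject's RRI series, annotations, and subject record.

    ``group`` is ``"patient"`` (apnea episodes with CVHR) or
    ``"healthy"`` (no episodes, AHI 0).
    """
    if group not in ("patient", "healthy"):
        raise ValidationError("group must be 'patient' or 'healthy'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sid = subject_id or (f"{'P' if group == 'patient' else 'H'}{rng.integers(1e6)}")

    episodes = _place_episodes(spec, rng) if group == "patient" else []
    phi = rng.uniform(0, 2 * np.pi)
    t = np.arange(0.0, spec.record_duration_s, _PHASE_DT_S)
    r = _instantaneous_rri(spec, t, episodes, phi)
    beat_times = _integrate_and_fire(r, _PHASE_DT_S)
    intervals = np.diff(beat_times)
    intervals = intervals + rng.normal(0.0, spec.noise_sd_s, size=intervals.size)
    if np.any(intervals <= 0):
        raise ValidationError("noise level produced a non-positive interval")

    series = RRISeries(subject_id=sid, intervals=intervals)
    events = [
        EventAnnotation(onset=o, duration=d, event_type="apnea") for o, d in episodes
    ]
    ahi = len(episodes) / (spec.record_duration_s / 3600.0)
    return series, events, SubjectRecord(subject_id=sid, ahi=ahi)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> list[tuple[RRISeries, list[EventAnnotation], SubjectRecord]]:
    """Generate the full seeded cohort: patients first, then healthy."""
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s) for s in ss.generate_state(spec.n_patients + spec.n_healthy)]
    cohort = []
    for i in range(spec.n_patients):
        cohort.append(
            generate_subject(spec, "patient", subject_id=f"P{i + 1}", seed=child_seeds[i])
        )
    for i in range(spec.n_healthy):
        cohort.append(
            generate_subject(
                spec, "healthy", subject_id=f"H{i + 1}",
                seed=child_seeds[spec.n_patients + i],
            )
        )
    return cohort


def generate_ecg(
    rri: RRISeries,
    sampling_rate: float = 200.0,
    qrs_amplitude: float = 1.0,
    qrs_sigma_s: float = 0.012,
    wander_amp: float = 0.05,
    wander_freq_hz: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[ECGTrace, np.ndarray]:
    """Synthesize a single-lead ECG trace from an RRI series.

    Returns ``(trace, r_times)`` where ``r_times`` are the ground-truth R
    times in seconds.  One QRS complex is placed at every beat time — a
    series of N intervals yields N+1 complexes.
    """
    if sampling_rate < 50:
        raise ValidationError("sampling_rate must be >= 50 Hz for QRS synthesis")
    rng = np.random.default_rng(seed)
    r_times = rri.beat_times()
    duration = float(r_times[-1]) + 0.5
    n = int(np.ceil(duration * sampling_rate))
    tt = np.arange(n) / sampling_rate
    sig = wander_amp * np.sin(2 * np.pi * wander_freq_hz * tt)
    half = int(np.ceil(5 * qrs_sigma_s * sampling_rate))
    kernel_t = np.arange(-half, half + 1) / sampling_rate
    for rt in r_times:
        center = int(round(rt * sampling_rate))
        lo, hi = max(0, center - half), min(n, center + half + 1)
        klo = lo - (center - half)
        template = qrs_amplitude * np.exp(
            -((kernel_t[klo : klo + hi - lo] + (center / sampling_rate - rt)) ** 2)
            / (2 * qrs_sigma_s**2)
        )
        sig[lo:hi] += template
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return ECGTrace(samples=sig, sampling_rate=sampling_rate), r_times


def inject_ectopics(
    rri: RRISeries, rate_per_h: float, seed: int = 0
) -> tuple[RRISeries, list[EventAnnotation]]:
    """Replace random interval pairs with a premature/compensatory split.

    The selected interval ``z_i`` shortens to ``0.6 z_i`` and the excess
    moves to ``z_{i+1}`` (the compensatory pause), conserving the pair
    sum — and hence total record duration — exactly.  Each injection is
    annotated as an arrhythmia event spanning the modified pair.
    """
    if rate_per_h < 0:
        raise ValidationError("ectopic rate must be >= 0")
    if rate_per_h == 0 or len(rri) < 3:
        return rri, []
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate_per_h * rri.duration / 3600.0)
    if n_events == 0:
        return rri, []
    candidates = np.arange(0, len(rri) - 1)
    rng.shuffle(candidates)
    chosen: list[int] = []
    used: set[int] = set()
    for i in candidates:
        if i in used or i + 1 in used or i - 1 in used:
            continue
        chosen.append(int(i))
        used.update((i, i + 1))
        if len(chosen) >= n_events:
            break
    intervals = rri.intervals.copy()
    beat_times = rri.beat_times()
    events = []
    for i in sorted(chosen):
        z = intervals[i]
        intervals[i + 1] += z - 0.6 * z
        intervals[i] = 0.6 * z
        onset = float(beat_times[i])
        span = float(beat_times[i + 2] - beat_times[i])
        events.append(EventAnnotation(onset=onset, duration=span, event_type="arrhythmia"))
    out = replace(rri, intervals=intervals)
    return out, events
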