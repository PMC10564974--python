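"""Interbeat-interval pipeline for cardiac aggregate recordings.

Optical traces of spontaneously beating heart-cell aggregates (sampled
at 40 Hz) are band-pass filtered, beats are detected as upward
threshold crossings, and interbeat intervals (IBIs) are analysed for
the onset of alternans — a period-doubling rhythm in which the IBI
return map (IBI_{n+1} vs IBI_n) develops a slope near -1.

A synthetic recording generator emulates such records (slow baseline
drift, optional growing alternans after a known onset beat, beat-scale
noise) and returns the ground truth, so every stage of the pipeline can
be tested end to end without experimental data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.stats import linregress

__all__ = [
    "SAMPLE_RATE",
    "BeatRecord",
    "SynthConfig",
    "bandpass",
    "detect_beats",
    "compute_ibis",
    "detect_pd_onset",
    "extract_null_segments",
    "synthesize_aggregate_recording",
]

#: fixed optical sampling rate, Hz
SAMPLE_RATE = 40.0
#: band-pass cutoff frequencies, Hz
BAND = (0.1, 6.5)
#: beat threshold: record mean plus this many standard deviations
BEAT_THRESHOLD_SD = 0.7


@dataclass
class BeatRecord:
    """Beat times (s), interbeat intervals (s) and, if detected, the
    beat index of period-doubling onset."""

    beat_times: np.ndarray
    ibi: np.ndarray
    pd_onset_index: Optional[int] = None


def bandpass(trace: np.ndarray, fs: float = SAMPLE_RATE, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass, 0.1-6.5 Hz passband."""
    x = np.asarray(trace, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of data to band-pass filter")
    sos = butter(order, BAND, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def detect_beats(filtered: np.ndarray, fs: float = SAMPLE_RATE) -> np.ndarray:
    """Beat times: upward crossings of mean + 0.7 sd of the filtered
    record, at sample resolution (seconds)."""
    x = np.asarray(filtered, dtype=float)
    if np.ptp(x) == 0:
        return np.array([])
    thr = x.mean() + BEAT_THRESHOLD_SD * x.std()
    above = x > thr
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    return crossings / fs


def compute_ibis(
    beat_times: np.ndarray,
    gaps: Optional[Sequence[tuple[float, float]]] = None,
) -> np.ndarray:
    """Interbeat intervals between consecutive beats.  Beat pairs that
    straddle an annotated recording gap (start_s, end_s) are dropped:
    pauses would otherwise create spurious giant intervals."""
    bt = np.asarray(beat_times, dtype=float)
    if len(bt) < 2:
        return np.array([])
    ibi = np.diff(bt)
    if gaps:
        keep = np.ones(len(ibi), dtype=bool)
        for lo, hi in gaps:
            keep &= ~((bt[:-1] < hi) & (bt[1:] > lo))
        ibi = ibi[keep]
    return ibi


def detect_pd_onset(
    ibi: np.ndarray,
    window_size: int = 10,
    slope_threshold: float = -0.95,
    persistence: int = 10,
) -> Optional[int]:
    """Period-doubling onset: the first beat index at which the linear
    regression slope of the return map (consecutive (IBI_n, IBI_{n+1})
    pairs within a trailing window of ``window_size`` intervals) falls
    below ``slope_threshold`` and stays below it for the next
    ``persistence`` beats.  A window whose predictor has zero variance
    has no defined slope and counts as not-below-threshold.
    """
    x = np.asarray(ibi, dtype=float)
    if len(x) <= window_size + persistence:
        raise ValueError("IBI record too short for the onset rule")
    n_slopes = len(x) - window_size + 1
    below = np.zeros(n_slopes, dtype=bool)
    for s in range(n_slopes):
        w = x[s : s + window_size]
        a, b = w[:-1], w[1:]
        if np.ptp(a) == 0:
            continue
        below[s] = linregress(a, b).slope < slope_threshold
    # slope index s describes the window ending at beat s + window_size - 1
    for s in range(n_slopes - persistence + 1):
        if below[s : s + persistence].all():
            return s + window_size - 1
    return None


def extract_null_segments(
    records: Sequence[np.ndarray],
    n_segments: int,
    rng_seed=None,
    length_range: tuple[int, int] = (100, 500),
) -> list[np.ndarray]:
    """Random segments from non-transitioning IBI records, with uniform
    random length in ``length_range`` at random positions; serve as
    null time series.  Records shorter than the minimum length are
    skipped with a warning."""
    rng = np.random.default_rng(rng_seed)
    lo, hi = length_range
    usable = []
    for i, rec in enumerate(records):
        if len(rec) < lo:
            warnings.warn(f"record {i} shorter than {lo} intervals; skipped")
        else:
            usable.append(np.asarray(rec, dtype=float))
    if not usable:
        raise ValueError("no record long enough to extract null segments")
    segments = []
    for _ in range(n_segments):
        rec = usable[int(rng.integers(len(usable)))]
        length = int(rng.integers(lo, min(hi, len(rec)) + 1))
        start = int(rng.integers(0, len(rec) - length + 1))
        segments.append(rec[start : start + length].copy())
    return segments


@dataclass
class SynthConfig:
    """Synthetic aggregate recording: a slowly drifting baseline IBI,
    optional alternans growing after ``alternans_onset`` (beat index in
    the IBI sequence), and beat-scale noise, rendered as a smooth
    40 Hz pulse train."""

    n_beats: int = 400
    baseline_ibi: float = 1.0          # s
    drift_amplitude: float = 0.05      # s, slow sinusoidal wander
    drift_period_beats: float = 300.0
    alternans_onset: Optional[int] = None
    alternans_initial: float = 0.02    # s, first alternation half-amplitude
    alternans_growth: float = 1.25     # per-beat geometric growth
    alternans_max: float = 0.15        # s, saturation half-amplitude
    noise_sd: float = 0.01             # s, i.i.d. IBI jitter
    pulse_width: float = 0.08          # s, optical pulse sd
    trace_noise_sd: float = 0.02       # intensity units


def synthesize_aggregate_recording(
    config: SynthConfig = SynthConfig(),
    rng_seed=None,
) -> tuple[np.ndarray, BeatRecord]:
    """Generate a synthetic optical trace plus its ground truth.

    Returns ``(trace, truth)`` where ``trace`` is the 40 Hz intensity
    signal and ``truth`` holds the true beat times, IBI sequence and
    the configured alternans onset index.
    """
    cfg = config
    if cfg.n_beats < 50:
        raise ValueError("need at least 50 beats")
    rng = np.random.default_rng(rng_seed)
    n = cfg.n_beats
    idx = np.arange(n)
    phase = rng.uniform(0, 2 * np.pi)
    ibi = cfg.baseline_ibi + cfg.drift_amplitude * np.sin(
        2 * np.pi * idx / cfg.drift_period_beats + phase
    )
    ibi = ibi + cfg.noise_sd * rng.standard_normal(n)
    if cfg.alternans_onset is not None:
        k = idx - cfg.alternans_onset
        amp = np.where(
            k >= 0,
            np.minimum(cfg.alternans_max, cfg.alternans_initial * cfg.alternans_growth ** np.maximum(k, 0)),
            0.0,
        )
        ibi = ibi + amp * (-1.0) ** idx
    ibi = np.maximum(ibi, 0.3)  # physiological floor

    beat_times = np.concatenate([[0.5], 0.5 + np.cumsum(ibi)])
    duration = beat_times[-1] + 1.0
    t = np.arange(0, duration, 1.0 / SAMPLE_RATE)
    trace = np.zeros_like(t)
    for bt in beat_times:
        trace += np.exp(-0.5 * ((t - bt) / cfg.pulse_width) ** 2)
    trace += cfg.trace_noise_sd * rng.standard_normal(len(t))
    truth = BeatRecord(
        beat_times=beat_times, ibi=ibi, pd_onset_index=cfg.alternans_onset
    )
    return trace, truth
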