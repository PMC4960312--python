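"""Baseline-noise estimation and event detection on current sweeps.

Noise is characterized the way failure analysis requires: the peak-to-trough
amplitude difference inside 30-ms windows taken from quiescent stretches
(prestimulus intervals, or event-free segments of spontaneous sweeps), with
at least eight windows. Mini detection finds negative-going excursions whose
magnitude over the local baseline clears a noise-scaled threshold; evoked
measurement takes the filtered minimum in a fixed post-stimulus window
against the pre-stimulus baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientDataError, ValidationError
from .qtrc import TraceSweep

log = logging.getLogger(__name__)

__all__ = ["NoiseModel", "estimate_noise", "detect_minis", "measure_evoked"]

#: Absolute amplitude floor (nA) used when the noise model is degenerate.
ABS_FLOOR_NA = 0.05


@dataclass(frozen=True)
class NoiseModel:
    """Baseline-noise summary.

    ``mean_na``/``sd_na`` are the mean and s.d. of peak-to-trough amplitude
    differences in 30-ms quiescent windows (the failure-analysis statistic);
    ``sample_sd_na`` is the pooled per-sample s.d. within those windows,
    used to scale detection thresholds.
    """

    mean_na: float
    sd_na: float
    sample_sd_na: float
    n_windows: int
    window_ms: float = 30.0
    method: str = "range"


def _window_indices(sweep: TraceSweep, window_ms: float, exclude_times_s=None):
    """Candidate quiescent windows as (start, stop) sample indices."""
    w = int(round(window_ms / 1000.0 * sweep.sample_rate_hz))
    n = sweep.current_na.size
    if sweep.stim_times_s.size:
        # one window ending 1 ms before each stimulus, clear of the previous
        # stimulus response (>=100 ms after it)
        gap = int(round(0.001 * sweep.sample_rate_hz))
        windows = []
        prev_end = 0
        for t in sweep.stim_times_s:
            stop = int(round(t * sweep.sample_rate_hz)) - gap
            start = stop - w
            if start >= prev_end and stop <= n:
                windows.append((start, stop))
            prev_end = int(round((t + 0.1) * sweep.sample_rate_hz))
        return windows
    starts = np.arange(0, n - w + 1, w)
    windows = [(int(s), int(s + w)) for s in starts]
    if exclude_times_s is not None and len(exclude_times_s):
        ev = np.asarray(exclude_times_s, dtype=float)
        pad = 0.02  # s; keep clear of event rise and decay
        kept = []
        for s, e in windows:
            t0, t1 = s / sweep.sample_rate_hz, e / sweep.sample_rate_hz
            if not np.any((ev >= t0 - pad) & (ev <= t1 + pad)):
                kept.append((s, e))
        windows = kept
    return windows


def estimate_noise(
    sweep: TraceSweep,
    window_ms: float = 30.0,
    min_windows: int = 8,
    exclude_times_s=None,
    method: str = "range",
    robust: bool = False,
) -> NoiseModel:
    """Estimate baseline noise from quiescent 30-ms windows.

    For evoked sweeps, windows end 1 ms before each stimulus; for
    spontaneous sweeps the trace is tiled, optionally excluding windows near
    known event times. ``method='range'`` records the peak-to-trough
    difference per window (the literal reading of the window statistic);
    ``method='sd'`` records the per-window sample s.d. instead. With
    ``robust=True`` windows whose range exceeds twice the median window
    range are dropped first — a guard against spontaneous events landing in
    candidate windows when no event list is available yet. Raises
    :class:`InsufficientDataError` with fewer than ``min_windows`` windows.
    """
    if method not in ("range", "sd"):
        raise ValidationError(f"unknown noise method {method!r}")
    windows = _window_indices(sweep, window_ms, exclude_times_s)
    x = sweep.current_na
    if robust and len(windows) >= min_windows:
        ranges = np.array([np.ptp(x[s:e]) for s, e in windows])
        med = np.median(ranges)
        if med > 0:
            kept = [w for w, r in zip(windows, ranges) if r <= 2.0 * med]
            if len(kept) >= min_windows:
                windows = kept
    if len(windows) < min_windows:
        raise InsufficientDataError(
            f"only {len(windows)} usable {window_ms:g}-ms windows; need >= {min_windows}"
        )
    stats = []
    samples = []
    for s, e in windows:
        seg = x[s:e]
        stats.append(np.ptp(seg) if method == "range" else seg.std(ddof=1))
        samples.append(seg - seg.mean())
    stats = np.asarray(stats)
    pooled = np.concatenate(samples)
    return NoiseModel(
        mean_na=float(stats.mean()),
        sd_na=float(stats.std(ddof=1)) if stats.size > 1 else 0.0,
        sample_sd_na=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        n_windows=len(windows),
        window_ms=window_ms,
        method=method,
    )


def _smooth(x: np.ndarray, sample_rate_hz: float, width_ms: float = 1.0) -> np.ndarray:
    w = max(1, int(round(width_ms / 1000.0 * sample_rate_hz)))
    if w == 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def detect_minis(
    sweep: TraceSweep,
    noise: NoiseModel,
    threshold_k: float = 4.5,
    refractory_ms: float = 5.0,
    baseline_ms: float = 10.0,
) -> pd.DataFrame:
    """Detect spontaneous miniature events.

    Events are negative-going excursions of a lightly smoothed (1 ms boxcar)
    trace whose magnitude over the local baseline exceeds
    ``threshold_k * noise.sample_sd_na``. The baseline is the median of the
    ``baseline_ms`` preceding the event onset; candidates closer than
    ``refractory_ms`` are merged keeping the larger peak. With a degenerate
    noise model (zero s.d.) an absolute floor of 0.05 nA applies.

    Returns an event table with columns time_s, amplitude_na, baseline_na,
    kind.
    """
    sr = sweep.sample_rate_hz
    floor = threshold_k * noise.sample_sd_na
    if floor == 0.0:
        log.warning("noise model has zero s.d.; falling back to absolute floor %.3g nA", ABS_FLOOR_NA)
        floor = ABS_FLOOR_NA
    x = _smooth(sweep.current_na, sr)
    neg = -x  # events point upward in this view
    distance = max(1, int(round(refractory_ms / 1000.0 * sr)))
    peaks, _ = signal.find_peaks(neg, prominence=floor, distance=distance)

    bl_w = int(round(baseline_ms / 1000.0 * sr))
    lead = int(round(0.002 * sr))  # baseline window ends 2 ms before the peak
    rows = []
    for p in peaks:
        s = max(0, p - lead - bl_w)
        e = max(s + 1, p - lead)
        baseline = float(np.median(sweep.current_na[s:e]))
        amp = baseline - float(sweep.current_na[p])
        if amp >= floor:
            rows.append(
                dict(time_s=p / sr, amplitude_na=amp, baseline_na=baseline, kind="mejc")
            )
    return pd.DataFrame(rows, columns=["time_s", "amplitude_na", "baseline_na", "kind"])


def measure_evoked(
    sweep: TraceSweep,
    noise: NoiseModel | None = None,
    search_ms: float = 30.0,
    baseline_ms: float = 10.0,
) -> pd.DataFrame:
    """Measure the evoked response amplitude for every stimulus.

    Amplitude = |trace minimum in the (0, ``search_ms``] post-stimulus
    window - baseline|, with baseline the median of the ``baseline_ms``
    immediately pre-stimulus. Exactly one row per stimulus; near-zero
    amplitudes are candidate failures. Stimuli whose search window runs past
    the sweep end are flagged and excluded with a warning.
    """
    if sweep.stim_times_s.size == 0:
        raise ValidationError("measure_evoked requires a sweep with stimulus times")
    sr = sweep.sample_rate_hz
    n = sweep.current_na.size
    w = int(round(search_ms / 1000.0 * sr))
    bl_w = int(round(baseline_ms / 1000.0 * sr))
    rows = []
    for k, t in enumerate(sweep.stim_times_s):
        i = int(round(t * sr))
        if i + w > n:
            log.warning("stimulus %d at %.3f s: search window past sweep end; excluded", k, t)
            continue
        baseline = float(np.median(sweep.current_na[max(0, i - bl_w) : max(1, i)]))
        trough = float(sweep.current_na[i : i + w].min())
        rows.append(
            dict(
                time_s=t,
                amplitude_na=max(0.0, baseline - trough),
                baseline_na=baseline,
                kind="ejc",
                stim_index=k,
            )
        )
    return pd.DataFrame(
        rows, columns=["time_s", "amplitude_na", "baseline_na", "kind", "stim_index"]
    )
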