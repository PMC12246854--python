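"""Electrodermal-activity preprocessing and tonic-level stage summaries.

The chain: flag detachment artifacts (abrupt jumps that leave a local
robust band), repair them by linear interpolation between valid neighbours,
smooth with a zero-phase low-pass Butterworth filter, min-max normalize per
participant, then summarize the tonic skin-conductance level (SCL) per
experimental stage with a rolling-window mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError, ValidationError
from .io_formats import EDASeries, StageSchedule

DEFAULT_JUMP_THRESHOLD_US = 0.01
DEFAULT_CUTOFF_HZ = 0.5
DEFAULT_FILTER_ORDER = 4
DEFAULT_WINDOW_S = 120.0
DEFAULT_BAND_K = 3.0
DEFAULT_BAND_WINDOW_S = 30.0
DEFAULT_GLOBAL_K_LOW = 1.0
DEFAULT_GLOBAL_K_HIGH = 3.0
DEFAULT_GLOBAL_Q_LOW = 0.05
DEFAULT_GLOBAL_Q_HIGH = 0.02
DEFAULT_MIN_VALID_FRACTION = 0.7


@dataclass(frozen=True)
class EDAStageSummary:
    """Tonic (SCL) summary of one stage for one participant."""

    participant_id: str
    stage_label: str
    tonic_mean: float  # normalized conductance in [0, 1]
    n_valid_samples: int
    fraction_repaired: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_repaired <= 1.0:
            raise ValidationError("fraction_repaired outside [0, 1]")


def _rolling_band(values: np.ndarray, sample_rate: float, window_s: float,
                  k: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling median +/- k*IQR acceptable band."""
    win = max(3, int(round(window_s * sample_rate)))
    s = pd.Series(values)
    roll = s.rolling(win, center=True, min_periods=1)
    med = roll.median().to_numpy()
    iqr = (roll.quantile(0.75) - roll.quantile(0.25)).to_numpy()
    return med - k * iqr, med + k * iqr


def detect_artifacts(series: EDASeries,
                     jump_threshold: float = DEFAULT_JUMP_THRESHOLD_US,
                     band_k: float = DEFAULT_BAND_K,
                     band_window_s: float = DEFAULT_BAND_WINDOW_S,
                     global_k_low: float = DEFAULT_GLOBAL_K_LOW,
                     global_k_high: float = DEFAULT_GLOBAL_K_HIGH,
                     global_q_low: float = DEFAULT_GLOBAL_Q_LOW,
                     global_q_high: float = DEFAULT_GLOBAL_Q_HIGH,
                     ) -> EDASeries:
    """Flag artifact samples; values are left untouched.

    A sample is flagged when its absolute difference to the previous *valid*
    sample exceeds ``jump_threshold`` (microsiemens) AND it falls outside the
    acceptable range.  The acceptable range is the union of two robust bands:
    a centered rolling median +/- ``band_k`` * IQR band (local level) and a
    whole-recording quantile envelope
    ``[q(global_q_low) - global_k_low * IQR,
    q(1 - global_q_high) + global_k_high * IQR]`` describing the
    participant's physiological range.  Requiring a sample to leave *both*
    keeps genuine fast skin-conductance responses -- which exceed a
    quiet-period local band but stay within the session's range -- from
    being flagged, while detachment drops toward 0 uS fail both.  The
    envelope is asymmetric by design: detachments depress the signal, so the
    low edge sits tightly under the low quantile (which itself must be
    robust to an artifact fraction up to ``global_q_low``), while the high
    edge is generous because large upward excursions are usually genuine
    skin-conductance responses.  Contiguous flagged samples form artifact
    segments.
    """
    if not jump_threshold > 0:
        raise ParameterError(f"jump threshold must be > 0, got {jump_threshold}")
    x = series.values
    lo, hi = _rolling_band(x, series.sample_rate, band_window_s, band_k)
    g_iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    g_lo = float(np.quantile(x, global_q_low)) - global_k_low * g_iqr
    g_hi = float(np.quantile(x, 1.0 - global_q_high)) + global_k_high * g_iqr
    outside = ((x < lo) | (x > hi)) & ((x < g_lo) | (x > g_hi))
    mask = np.zeros(x.size, dtype=bool)
    last_valid = None
    for i in range(x.size):
        if last_valid is None:
            flagged = bool(outside[i])
        else:
            flagged = abs(x[i] - last_valid) > jump_threshold and bool(outside[i])
        mask[i] = flagged
        if not flagged:
            last_valid = x[i]
    if mask.all():
        raise ValidationError("no valid anchor samples: every sample flagged")
    out = series.copy()
    out.artifact_mask = mask
    return out


def artifact_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of contiguous flagged samples."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def repair_artifacts(series: EDASeries, mode: str = "interpolate") -> EDASeries:
    """Replace flagged samples; the mask is retained for provenance.

    ``interpolate`` (default) discards flagged segments and fills them by
    linear interpolation between the nearest valid neighbours; artifact
    segments touching the recording head or tail are filled by extending the
    nearest valid value.  ``relevel`` instead shifts each flagged segment by a
    constant so that its first sample continues from the last valid value --
    an alternative reading of range re-adjustment for level-shift artifacts.
    """
    mask = series.artifact_mask
    valid = ~mask
    if not valid.any():
        raise ValidationError("cannot repair a series with no valid samples")
    out = series.copy()
    if not mask.any():
        return out
    x = out.values
    if mode == "interpolate":
        idx = np.arange(x.size)
        x[mask] = np.interp(idx[mask], idx[valid], x[valid])
    elif mode == "relevel":
        for a, b in artifact_segments(mask):
            anchor = x[a - 1] if a > 0 else x[b] if b < x.size else x[a]
            x[a:b] += anchor - x[a]
    else:
        raise ParameterError(f"unknown repair mode {mode!r}")
    out.values = x
    return out


def lowpass(series: EDASeries, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
            order: int = DEFAULT_FILTER_ORDER) -> EDASeries:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    nyq = series.sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=series.sample_rate,
                 output="sos")
    out = series.copy()
    out.values = sosfiltfilt(sos, series.values)
    return out


def normalize_minmax(series: EDASeries) -> EDASeries:
    """Min-max scale to [0, 1] over the full recording.

    Normalization is per participant over the whole session; a constant
    series maps to all zeros (documented degenerate convention).
    """
    x = series.values
    if x.size == 0:
        raise ValidationError("cannot normalize an empty series")
    lo, hi = float(x.min()), float(x.max())
    out = series.copy()
    out.values = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return out


def rolling_stage_mean(values: np.ndarray, sample_rate: float,
                       start_s: float, end_s: float, window_s: float,
                       ) -> float:
    """Mean of fully-overlapping rolling-window means inside a stage.

    Windows step one sample and must lie entirely within the stage interval,
    so the result is a (triangular-weighted) average of the stage samples.
    """
    i0 = int(round(start_s * sample_rate))
    i1 = int(round(end_s * sample_rate))
    seg = values[i0:i1]
    win = int(round(window_s * sample_rate))
    if win < 1 or win > seg.size:
        raise ParameterError(
            f"window ({window_s} s) longer than stage interval "
            f"[{start_s}, {end_s}) s"
        )
    window_means = np.convolve(seg, np.ones(win) / win, mode="valid")
    return float(window_means.mean())


def summarize_stages(series: EDASeries, schedule: StageSchedule,
                     window_s: float = DEFAULT_WINDOW_S,
                     ) -> list[EDAStageSummary]:
    """Per-stage tonic SCL means from a repaired, normalized series."""
    if schedule.end_s > series.duration_s + 1e-9:
        outside = [lab for lab, _s, e in schedule.stages
                   if e > series.duration_s + 1e-9]
        raise ValidationError(
            f"stages outside the recording span: {outside}"
        )
    out = []
    for label, start, end in schedule.stages:
        sl = series.values[int(round(start * series.sample_rate)):
                           int(round(end * series.sample_rate))]
        mask = series.artifact_mask[int(round(start * series.sample_rate)):
                                    int(round(end * series.sample_rate))]
        try:
            tonic = rolling_stage_mean(series.values, series.sample_rate,
                                       start, end, window_s)
        except ParameterError as exc:
            raise ParameterError(f"stage {label!r}: {exc}") from exc
        out.append(EDAStageSummary(
            participant_id=series.participant_id,
            stage_label=label,
            tonic_mean=tonic,
            n_valid_samples=int((~mask).sum()),
            fraction_repaired=float(mask.mean()) if sl.size else 0.0,
        ))
    return out


def preprocess(series: EDASeries,
               jump_threshold: float = DEFAULT_JUMP_THRESHOLD_US,
               cutoff_hz: float = DEFAULT_CUTOFF_HZ,
               order: int = DEFAULT_FILTER_ORDER,
               band_k: float = DEFAULT_BAND_K,
               global_k_low: float = DEFAULT_GLOBAL_K_LOW,
               global_k_high: float = DEFAULT_GLOBAL_K_HIGH,
               repair_mode: str = "interpolate") -> EDASeries:
    """Full single-device chain: detect, repair, low-pass, normalize."""
    s = detect_artifacts(series, jump_threshold=jump_threshold, band_k=band_k,
                         global_k_low=global_k_low,
                         global_k_high=global_k_high)
    s = repair_artifacts(s, mode=repair_mode)
    s = lowpass(s, cutoff_hz=cutoff_hz, order=order)
    return normalize_minmax(s)


def fuse_device_summaries(per_device: list[list[EDAStageSummary]],
                          min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
                          ) -> list[EDAStageSummary]:
    """Combine stage summaries from 1-2 wristbands worn simultaneously.

    Devices whose overall valid fraction is at least ``min_valid_fraction``
    are averaged; if no device passes, the one with the most valid samples is
    used alone.
    """
    if not per_device:
        raise ValidationError("no device summaries to fuse")
    if len(per_device) == 1:
        return per_device[0]

    def valid_fraction(summaries: list[EDAStageSummary]) -> float:
        return 1.0 - float(np.mean([s.fraction_repaired for s in summaries]))

    fractions = [valid_fraction(d) for d in per_device]
    keep = [d for d, f in zip(per_device, fractions)
            if f >= min_valid_fraction]
    if not keep:
        keep = [per_device[int(np.argmax(fractions))]]
    by_stage: dict[str, list[EDAStageSummary]] = {}
    for dev in keep:
        for s in dev:
            by_stage.setdefault(s.stage_label, []).append(s)
    fused = []
    for stage, items in by_stage.items():
        fused.append(EDAStageSummary(
            participant_id=items[0].participant_id,
            stage_label=stage,
            tonic_mean=float(np.mean([s.tonic_mean for s in items])),
            n_valid_samples=int(np.sum([s.n_valid_samples for s in items])),
            fraction_repaired=float(np.mean([s.fraction_repaired
                                             for s in items])),
        ))
    return fused
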