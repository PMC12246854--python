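"""fNIRS preprocessing: modified Beer-Lambert conversion, scalp-coupling
quality control, hemodynamic band-pass filtering, and stage averages.

Optical-density changes at two wavelengths are converted to oxy- and
deoxy-haemoglobin concentration changes (micromol/L) with the modified
Beer-Lambert law, using per-channel source-detector distances and an age- and
wavelength-dependent differential pathlength factor (DPF).  Channel quality
is scored with the scalp coupling index (SCI): the zero-lag correlation of
the two wavelengths' cardiac-band (0.7-1.5 Hz) components; channels below
the 0.75 cutoff are excluded.  Retained concentration traces are band-pass
filtered (0.02-0.18 Hz by default) and summarized per experimental stage
with the same rolling-window mean used for EDA.

A note on sustained activation: a zero-phase band-pass whose low edge is
0.02 Hz removes nearly all of a constant multi-minute activation block, so
per-stage means of the fully band-passed signal carry only filter-transient
residue whose sign depends on stage length.  Stage summaries therefore
default to the low-pass-only (high edge of the hemodynamic band) signal,
which retains sustained blocks; the full band-pass remains available for
the oscillation-band waveform products and can be routed into the summary
path via configuration.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigError, NumericalError, ParameterError, ValidationError
from .io_formats import RawFNIRS, StageSchedule
from .eda import rolling_stage_mean

DEFAULT_CARDIAC_BAND_HZ = (0.7, 1.5)
DEFAULT_HEMO_BAND_HZ = (0.02, 0.18)
DEFAULT_SCI_THRESHOLD = 0.75
DEFAULT_WINDOW_S = 120.0
DEFAULT_FILTER_ORDER = 4

#: Molar extinction coefficients of haemoglobin, 1/(M*cm), at the default
#: wavelengths; values from the standard compiled in-vitro haemoglobin
#: absorption tables.  Keys: wavelength nm -> (epsilon_OHb, epsilon_HHb).
EXTINCTION_TABLE: dict[float, tuple[float, float]] = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

# General age + wavelength DPF equation coefficients (adult head):
# DPF = a + b*age^c + d*wl^3 + e*wl^2 + f*wl   (age in years, wl in nm)
_DPF_COEFFS = (223.3, 0.05624, 0.8493, -5.723e-7, 1.245e-3, -0.9025)


def compute_dpf(age_years: float, wavelength_nm: float) -> float:
    """Differential pathlength factor for a given age and wavelength."""
    if not 0 < age_years <= 100:
        raise ParameterError(f"age {age_years} outside (0, 100] years")
    if not 600 <= wavelength_nm <= 1000:
        raise ParameterError(
            f"wavelength {wavelength_nm} nm outside the device range "
            f"[600, 1000] nm"
        )
    a, b, c, d, e, f = _DPF_COEFFS
    dpf = (a + b * age_years ** c + d * wavelength_nm ** 3
           + e * wavelength_nm ** 2 + f * wavelength_nm)
    if not dpf > 0:
        raise NumericalError(
            f"DPF non-positive at age={age_years}, wavelength={wavelength_nm}"
        )
    return float(dpf)


@dataclass
class HemoSeries:
    """Concentration-change traces (micromol/L) for retained channels."""

    participant_id: str
    sample_rate: float
    delta_ohb: dict[str, np.ndarray]
    delta_hhb: dict[str, np.ndarray]
    retained_channels: tuple[str, ...]

    def __post_init__(self) -> None:
        for cid in self.retained_channels:
            if cid not in self.delta_ohb or cid not in self.delta_hhb:
                raise ValidationError(
                    f"retained channel {cid!r} lacks a concentration trace"
                )
            if self.delta_ohb[cid].size != self.delta_hhb[cid].size:
                raise ValidationError(
                    f"channel {cid!r}: OHb and HHb trace lengths differ"
                )

    @property
    def n_samples(self) -> int:
        return next(iter(self.delta_ohb.values())).size

    def copy(self) -> "HemoSeries":
        return HemoSeries(
            participant_id=self.participant_id,
            sample_rate=self.sample_rate,
            delta_ohb={k: v.copy() for k, v in self.delta_ohb.items()},
            delta_hhb={k: v.copy() for k, v in self.delta_hhb.items()},
            retained_channels=tuple(self.retained_channels),
        )


@dataclass(frozen=True)
class SCIReport:
    """Per-channel scalp coupling index and keep/reject decision."""

    sci: dict[str, float]
    threshold: float = DEFAULT_SCI_THRESHOLD

    @property
    def keep(self) -> dict[str, bool]:
        return {cid: v >= self.threshold for cid, v in self.sci.items()}

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, k in self.keep.items() if k))


def _extinction_matrix(wavelengths: tuple[float, float],
                       extinction: dict[float, tuple[float, float]],
                       distance_cm: float, age_years: float,
                       dpf: dict[float, float] | None = None) -> np.ndarray:
    """2x2 system matrix mapping (dOHb, dHHb) in micromol/L to dOD."""
    rows = []
    for wl in wavelengths:
        if wl not in extinction:
            raise ConfigError(
                f"no extinction coefficients for wavelength {wl} nm"
            )
        pf = dpf[wl] if dpf is not None else compute_dpf(age_years, wl)
        eps_o, eps_h = extinction[wl]
        # 1e-6 converts micromol/L to mol/L for the molar coefficients
        rows.append([eps_o * distance_cm * pf * 1e-6,
                     eps_h * distance_cm * pf * 1e-6])
    return np.asarray(rows)


def beer_lambert(raw: RawFNIRS,
                 extinction: dict[float, tuple[float, float]] | None = None,
                 dpf: dict[float, float] | None = None,
                 channels: tuple[str, ...] | None = None) -> HemoSeries:
    """Invert the modified Beer-Lambert law per channel.

    Solves, per sample, ``dOD(wl) = [eps_OHb(wl)*dC_OHb + eps_HHb(wl)*dC_HHb]
    * d * DPF(wl)`` for the two concentration changes (micromol/L).
    """
    extinction = extinction if extinction is not None else EXTINCTION_TABLE
    wavelengths = raw.wavelengths
    if len(wavelengths) != 2:
        raise ValidationError(
            f"need exactly 2 wavelengths, got {wavelengths}"
        )
    use = channels if channels is not None else raw.channel_ids
    delta_ohb: dict[str, np.ndarray] = {}
    delta_hhb: dict[str, np.ndarray] = {}
    for cid in use:
        ch = raw.montage.channel(cid)
        if not ch.source_detector_distance_cm > 0:
            raise ConfigError(f"channel {cid!r}: missing optode distance")
        m = _extinction_matrix(wavelengths, extinction,
                               ch.source_detector_distance_cm,
                               raw.age_years, dpf)
        det = np.linalg.det(m)
        if abs(det) < 1e-15:
            raise NumericalError(
                f"extinction matrix singular for channel {cid!r}"
            )
        od = np.vstack([raw.od[(cid, wl)] for wl in wavelengths])
        conc = np.linalg.solve(m, od)
        delta_ohb[cid] = conc[0]
        delta_hhb[cid] = conc[1]
    return HemoSeries(
        participant_id=raw.participant_id,
        sample_rate=raw.sample_rate,
        delta_ohb=delta_ohb,
        delta_hhb=delta_hhb,
        retained_channels=tuple(use),
    )


def forward_od(delta_ohb: np.ndarray, delta_hhb: np.ndarray,
               wavelengths: tuple[float, float], distance_cm: float,
               age_years: float,
               extinction: dict[float, tuple[float, float]] | None = None,
               ) -> dict[float, np.ndarray]:
    """Forward Beer-Lambert model: concentrations -> per-wavelength dOD.

    The synthetic generator uses this exact forward map (same extinction
    table and DPF as the inverse), which is what makes the round-trip
    identity test meaningful.
    """
    extinction = extinction if extinction is not None else EXTINCTION_TABLE
    m = _extinction_matrix(tuple(wavelengths), extinction, distance_cm,
                           age_years)
    conc = np.vstack([delta_ohb, delta_hhb])
    od = m @ conc
    return {wl: od[i] for i, wl in enumerate(wavelengths)}


def _bandpass_sos(band: tuple[float, float], fs: float, order: int):
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ParameterError(
            f"band {band} Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    return butter(order, [lo, hi], btype="band", fs=fs, output="sos")


def compute_sci(raw: RawFNIRS, channel_id: str,
                band: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
                order: int = DEFAULT_FILTER_ORDER) -> float:
    """Scalp coupling index of one channel.

    Both wavelength traces are band-passed to the cardiac band, scaled to
    unit variance, and their zero-lag normalized cross-correlation is
    returned (in [-1, 1]).  A zero-variance filtered trace yields SCI = 0
    (documented convention).
    """
    wls = raw.wavelengths
    sos = _bandpass_sos(band, raw.sample_rate, order)
    traces = []
    for wl in wls:
        if (channel_id, wl) not in raw.od:
            raise ValidationError(
                f"channel {channel_id!r} missing wavelength {wl}"
            )
        traces.append(sosfiltfilt(sos, raw.od[(channel_id, wl)]))
    x, y = traces
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean(((x - x.mean()) / sx) * ((y - y.mean()) / sy)))


def reject_channels(raw: RawFNIRS,
                    threshold: float = DEFAULT_SCI_THRESHOLD,
                    band: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
                    order: int = DEFAULT_FILTER_ORDER) -> SCIReport:
    """Score every channel; keep iff SCI >= threshold (boundary inclusive).

    All traces are filtered in one batched call; the per-channel result is
    identical to :func:`compute_sci`.
    """
    channels = raw.channel_ids
    wls = raw.wavelengths
    sos = _bandpass_sos(band, raw.sample_rate, order)
    stacked = np.vstack([raw.od[(cid, wl)] for cid in channels for wl in wls])
    filt = sosfiltfilt(sos, stacked, axis=-1)
    sci = {}
    for i, cid in enumerate(channels):
        x, y = filt[2 * i], filt[2 * i + 1]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            sci[cid] = 0.0
        else:
            sci[cid] = float(np.mean(
                ((x - x.mean()) / sx) * ((y - y.mean()) / sy)))
    return SCIReport(sci=sci, threshold=threshold)


def _apply_sos(hemo: HemoSeries, sos) -> HemoSeries:
    chans = hemo.retained_channels
    stacked = np.vstack([hemo.delta_ohb[c] for c in chans]
                        + [hemo.delta_hhb[c] for c in chans])
    filt = sosfiltfilt(sos, stacked, axis=-1)
    k = len(chans)
    return HemoSeries(
        participant_id=hemo.participant_id,
        sample_rate=hemo.sample_rate,
        delta_ohb={c: filt[i] for i, c in enumerate(chans)},
        delta_hhb={c: filt[k + i] for i, c in enumerate(chans)},
        retained_channels=tuple(chans),
    )


def bandpass_hemo(hemo: HemoSeries,
                  band: tuple[float, float] = DEFAULT_HEMO_BAND_HZ,
                  order: int = DEFAULT_FILTER_ORDER) -> HemoSeries:
    """Zero-phase Butterworth band-pass on both chromophore traces."""
    return _apply_sos(hemo, _bandpass_sos(band, hemo.sample_rate, order))


def lowpass_hemo(hemo: HemoSeries,
                 cutoff_hz: float = DEFAULT_HEMO_BAND_HZ[1],
                 order: int = DEFAULT_FILTER_ORDER) -> HemoSeries:
    """Zero-phase Butterworth low-pass; retains sustained activation blocks."""
    nyq = hemo.sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = butter(order, cutoff_hz, btype="low", fs=hemo.sample_rate,
                 output="sos")
    return _apply_sos(hemo, sos)


@dataclass(frozen=True)
class HemoStageSummary:
    """Stage means of dOHb / dHHb (micromol/L) for one retained channel."""

    participant_id: str
    channel_id: str
    stage_label: str
    mean_delta_ohb: float
    mean_delta_hhb: float


def stage_averages(hemo: HemoSeries, schedule: StageSchedule,
                   window_s: float = DEFAULT_WINDOW_S,
                   ) -> list[HemoStageSummary]:
    """Rolling-window stage means per retained channel and chromophore."""
    duration = hemo.n_samples / hemo.sample_rate
    if schedule.end_s > duration + 1e-9:
        outside = [lab for lab, _s, e in schedule.stages
                   if e > duration + 1e-9]
        raise ValidationError(f"stages outside the recording span: {outside}")
    out = []
    for cid in hemo.retained_channels:
        for label, start, end in schedule.stages:
            try:
                m_o = rolling_stage_mean(hemo.delta_ohb[cid],
                                         hemo.sample_rate, start, end,
                                         window_s)
                m_h = rolling_stage_mean(hemo.delta_hhb[cid],
                                         hemo.sample_rate, start, end,
                                         window_s)
            except ParameterError as exc:
                raise ParameterError(f"stage {label!r}: {exc}") from exc
            out.append(HemoStageSummary(
                participant_id=hemo.participant_id,
                channel_id=cid,
                stage_label=label,
                mean_delta_ohb=m_o,
                mean_delta_hhb=m_h,
            ))
    return out


def preprocess(raw: RawFNIRS,
               sci_threshold: float = DEFAULT_SCI_THRESHOLD,
               cardiac_band: tuple[float, float] = DEFAULT_CARDIAC_BAND_HZ,
               hemo_band: tuple[float, float] = DEFAULT_HEMO_BAND_HZ,
               order: int = DEFAULT_FILTER_ORDER,
               extinction: dict[float, tuple[float, float]] | None = None,
               summary_filter: str = "lowpass",
               ) -> tuple[HemoSeries, SCIReport]:
    """Full chain: SCI rejection on raw OD, Beer-Lambert, filtering.

    ``summary_filter`` selects what feeds the stage summaries: ``lowpass``
    (default) applies only the high edge of the hemodynamic band, so
    sustained activation blocks survive into the stage means; ``bandpass``
    applies the full band (the printed processing chain), whose 0.02 Hz low
    edge strips multi-minute blocks down to filter transients.
    """
    report = reject_channels(raw, threshold=sci_threshold, band=cardiac_band,
                             order=order)
    hemo = beer_lambert(raw, extinction=extinction,
                        channels=report.retained)
    if summary_filter == "lowpass":
        return lowpass_hemo(hemo, cutoff_hz=hemo_band[1], order=order), report
    if summary_filter == "bandpass":
        return bandpass_hemo(hemo, band=hemo_band, order=order), report
    raise ParameterError(
        f"summary_filter must be 'lowpass' or 'bandpass', got "
        f"{summary_filter!r}")
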