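"""Synthetic multimodal stress-study cohorts with known ground truth.

Generates complete cohorts -- wrist EDA at 4 Hz with detachment artifacts,
fNIRS optical densities at 50 Hz built through the exact Beer-Lambert
forward model used by the analysis inverse (plus cardiac, Mayer-wave,
respiratory and white-noise components), and five-point salivary cortisol
panels with group-specific recovery kinetics -- together with the ground
truth needed to score every recovery test: clean EDA traces, injected
artifact segments, true per-channel stage means, cortisol curve parameters
and the list of decoupled channels.

Default parameters emulate the study's structure: 12/11/12 participants in
the soothing / robotic / silence groups, a 40-minute stage schedule, a
stress-stage arousal increase in EDA, a right-lateralized stress increase in
dOHb, a sound-stage group contrast confined to a fixed channel set, and a
soothing-group cortisol recovery rate twice that of the controls.

Cortisol model: lognormal baseline (median ~10 nmol/L), additive rise at the
stress sample, first-order exponential decay at the group's rate constant,
multiplicative lognormal measurement noise.

A note on ground-truth fNIRS stage means: the analysis band-pass (0.02 Hz
low edge) removes nearly all of a sustained activation block, so the stored
"true" stage means are the stage means of the *filtered clean* concentration
traces -- the value an ideal noise-free analysis would produce -- rather
than the raw injected block heights.  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eda as eda_mod
from . import fnirs as fnirs_mod
from .cortisol import DEFAULT_MINUTES
from .errors import ValidationError
from .io_formats import (
    CORTISOL_STAGES,
    CortisolPanel,
    EDASeries,
    Montage,
    RawFNIRS,
    StageSchedule,
    default_montage,
    default_schedule,
    write_cortisol_csv,
    write_eda_csv,
    write_fnirs_edf,
    save_montage,
    save_schedule,
)

GROUP_ORDER = ("soothing", "robotic", "silence")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CortisolModel:
    log_baseline_mean: float = math.log(10.0)  # median 10 nmol/L
    log_baseline_sd: float = 0.3
    stress_rise_nmol: float = 6.0
    rise_sd_log: float = 0.15
    #: first-order recovery rate constants, 1/min (soothing = 2x controls)
    recovery_rate_per_min: dict = field(default_factory=lambda: {
        "soothing": 0.16, "robotic": 0.08, "silence": 0.08})
    noise_sd_log: float = 0.06  # multiplicative assay noise
    sample_minutes: dict = field(default_factory=lambda: dict(DEFAULT_MINUTES))


@dataclass
class EDAModel:
    tonic_baseline_mean_us: float = 2.0
    tonic_baseline_sd_us: float = 0.4
    #: sustained arousal increment per stage, microsiemens
    stage_increments_us: dict = field(default_factory=lambda: {
        "baseline": 0.0, "anticipation": 0.3, "stress": 0.8,
        "intermediate": 0.4, "sound": 0.25, "rest1": 0.15, "rest2": 0.1})
    transition_smooth_s: float = 15.0
    drift_amp_us: float = 0.08
    drift_period_s: float = 900.0
    scr_rate_per_min: dict = field(default_factory=lambda: {
        "baseline": 2.0, "anticipation": 3.0, "stress": 6.0,
        "intermediate": 3.0, "sound": 2.0, "rest1": 2.0, "rest2": 2.0})
    scr_amp_mean_us: float = 0.2
    scr_rise_s: float = 0.7
    scr_decay_s: float = 3.0
    noise_sd_us: float = 0.01
    artifact_rate: float = 3.0  # expected detachments per recording
    artifact_duration_s: tuple = (1.0, 4.0)
    artifact_drop_to_us: float = 0.05
    artifact_boundary_margin_s: float = 5.0
    n_devices: int = 2


@dataclass
class FNIRSModel:
    sample_rate: float = 50.0
    #: sustained stress-stage dOHb block, micromol/L (pre-filter)
    stress_ohb_right_umol: float = 1.0
    stress_ohb_left_umol: float = 0.4
    hhb_ratio: float = -0.3  # dHHb block = ratio * dOHb block
    #: channels carrying the sound-stage group contrast
    sound_contrast_channels: tuple = ("Tx3-Rx2", "Tx3-Rx3",
                                      "Tx8-Rx7", "Tx6-Rx6")
    #: sound-stage dOHb block for the control groups (soothing group: 0)
    sound_ohb_control_umol: float = 0.8
    #: per-participant lognormal spread of all block amplitudes
    amp_sd_log: float = 0.3
    cardiac_freq_hz: float = 1.1
    cardiac_freq_jitter_hz: float = 0.1
    cardiac_amp_od: float = 0.01
    cardiac_wl_ratio: float = 0.8  # second wavelength's share of the pulse
    mayer_freq_hz: float = 0.095
    mayer_amp_umol: float = 0.2
    resp_freq_hz: float = 0.25
    resp_amp_umol: float = 0.1
    od_noise_sd: float = 2e-4
    decoupled_channels: tuple = ()
    decoupled_noise_sd: float = 5e-4
    age_mean_years: float = 23.0
    age_sd_years: float = 5.0


@dataclass
class SyntheticConfig:
    n_per_group: tuple = (12, 11, 12)  # soothing, robotic, silence
    schedule: StageSchedule = field(default_factory=default_schedule)
    eda_sample_rate: float = 4.0
    start_time: float = 1.7e9  # UTC epoch of recording start
    wavelengths: tuple = (760.0, 850.0)
    summary_window_s: float = 120.0  # rolling window used for ground truth
    cortisol: CortisolModel = field(default_factory=CortisolModel)
    eda: EDAModel = field(default_factory=EDAModel)
    fnirs: FNIRSModel = field(default_factory=FNIRSModel)

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValidationError("group counts must be >= 2")

    def participant_table(self) -> list[tuple[str, str]]:
        """Ordered (participant_id, group) assignments."""
        out = []
        i = 1
        for group, n in zip(GROUP_ORDER, self.n_per_group):
            for _ in range(n):
                out.append((f"p{i:02d}", group))
                i += 1
        return out


def scaled_config(stage_s: float = 60.0, fnirs_fs: float = 10.0,
                  eda_fs: float = 4.0, window_s: float = 30.0,
                  **overrides) -> SyntheticConfig:
    """A reduced-size study configuration for simulation studies.

    Same stage structure and effect parameters as the default, with every
    stage shortened to ``stage_s`` seconds and the fNIRS sampling rate
    reduced; used for replicate-cohort simulations where the full 40-min
    50 Hz recordings would be needlessly expensive.
    """
    labels = default_schedule().labels
    stages = tuple((lab, i * stage_s, (i + 1) * stage_s)
                   for i, lab in enumerate(labels))
    cfg = SyntheticConfig(schedule=StageSchedule(stages),
                          eda_sample_rate=eda_fs,
                          summary_window_s=window_s, **overrides)
    cfg.fnirs.sample_rate = fnirs_fs
    return cfg


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    groups: dict  # pid -> group
    ages: dict  # pid -> age_years
    cortisol_params: dict  # pid -> {baseline, rise, rate_per_min}
    clean_eda: dict  # pid -> list per device of clean np.ndarray
    eda_artifacts: dict  # pid -> list per device of [(start, stop)] indices
    true_stage_means: dict  # pid -> {channel -> {stage -> (ohb, hhb)}}
    decoupled_channels: tuple
    sound_contrast_channels: tuple


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    age_years: float
    eda: list  # list[EDASeries], one per device
    fnirs: RawFNIRS | None


@dataclass
class Cohort:
    config: SyntheticConfig
    montage: Montage
    schedule: StageSchedule
    participants: list  # list[ParticipantData]
    panel: CortisolPanel
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Cortisol
# ---------------------------------------------------------------------------

def simulate_cortisol_panel(config: SyntheticConfig, rng: np.random.Generator,
                            null: bool = False,
                            ) -> tuple[CortisolPanel, dict]:
    """Five-point panels for the whole cohort; returns (panel, true params)."""
    cm = config.cortisol
    rows = []
    params = {}
    for pid, group in config.participant_table():
        baseline = float(np.exp(rng.normal(cm.log_baseline_mean,
                                           cm.log_baseline_sd)))
        rise = 0.0 if null else float(
            cm.stress_rise_nmol * np.exp(rng.normal(0.0, cm.rise_sd_log)))
        rate = cm.recovery_rate_per_min[group]
        params[pid] = {"baseline": baseline, "rise": rise,
                       "rate_per_min": rate}
        for stage in CORTISOL_STAGES:
            t = cm.sample_minutes[stage]
            if t < 0:
                true = baseline
            else:
                true = baseline + rise * math.exp(-rate * t)
            value = true * float(np.exp(rng.normal(0.0, cm.noise_sd_log)))
            rows.append({"participant_id": pid, "group": group,
                         "stage": stage, "nmol_per_l": value})
    return CortisolPanel(pd.DataFrame(rows)), params


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def _stage_profile(schedule: StageSchedule, sample_rate: float,
                   levels: dict, smooth_s: float) -> np.ndarray:
    """Piecewise-constant per-stage levels, smoothed at the transitions."""
    from scipy.ndimage import gaussian_filter1d

    n = int(round(schedule.end_s * sample_rate))
    prof = np.zeros(n)
    for label, start, end in schedule.stages:
        prof[int(round(start * sample_rate)):
             int(round(end * sample_rate))] = levels.get(label, 0.0)
    if smooth_s > 0:
        prof = gaussian_filter1d(prof, smooth_s * sample_rate / 2.355)
    return prof


def _scr_train(schedule: StageSchedule, sample_rate: float,
               rates_per_min: dict, amp_mean: float, rise_s: float,
               decay_s: float, rng: np.random.Generator) -> np.ndarray:
    """Phasic skin-conductance responses: Poisson events, bi-exponential."""
    n = int(round(schedule.end_s * sample_rate))
    impulses = np.zeros(n)
    for label, start, end in schedule.stages:
        lam = rates_per_min.get(label, 0.0) / 60.0  # events per second
        t = start
        while True:
            t += rng.exponential(1.0 / lam) if lam > 0 else float("inf")
            if t >= end:
                break
            impulses[int(t * sample_rate)] += rng.exponential(amp_mean)
    # bi-exponential kernel, peak-normalized
    kt = np.arange(0, int((rise_s + 6 * decay_s) * sample_rate)) / sample_rate
    kernel = np.exp(-kt / decay_s) - np.exp(-kt / rise_s)
    if kernel.max() > 0:
        kernel /= kernel.max()
    return np.convolve(impulses, kernel)[:n]


def _artifact_segments(schedule: StageSchedule, sample_rate: float,
                       model: EDAModel, rng: np.random.Generator,
                       ) -> list[tuple[int, int]]:
    """Detachment windows, kept clear of stage boundaries, non-overlapping."""
    n = int(round(schedule.end_s * sample_rate))
    margin = int(round(model.artifact_boundary_margin_s * sample_rate))
    boundaries = [0] + [int(round(e * sample_rate))
                        for _l, _s, e in schedule.stages]
    # every recording shows at least one detachment (observed device trait)
    count = 1 + rng.poisson(max(model.artifact_rate - 1.0, 0.0))
    segments: list[tuple[int, int]] = []
    attempts = 0
    while len(segments) < count and attempts < 100 * (count + 1):
        attempts += 1
        dur = int(round(rng.uniform(*model.artifact_duration_s) * sample_rate))
        start = int(rng.integers(margin, max(margin + 1, n - dur - margin)))
        stop = start + dur
        if any(start - margin < b < stop + margin for b in boundaries):
            continue
        if any(not (stop + margin <= a or b + margin <= start)
               for a, b in segments):
            continue
        segments.append((start, stop))
    return sorted(segments)


def simulate_eda(config: SyntheticConfig, rng: np.random.Generator,
                 participant_id: str, null: bool = False,
                 ) -> tuple[list[EDASeries], list[np.ndarray],
                            list[list[tuple[int, int]]]]:
    """Per-device EDA recordings plus clean traces and artifact segments."""
    em = config.eda
    fs = config.eda_sample_rate
    schedule = config.schedule
    tonic0 = max(0.5, rng.normal(em.tonic_baseline_mean_us,
                                 em.tonic_baseline_sd_us))
    increments = ({k: 0.0 for k in em.stage_increments_us} if null
                  else em.stage_increments_us)
    rates = (
        {k: float(np.mean(list(em.scr_rate_per_min.values())))
         for k in em.scr_rate_per_min}
        if null else em.scr_rate_per_min)

    n = int(round(schedule.end_s * fs))
    t = np.arange(n) / fs
    series_list, clean_list, segment_list = [], [], []
    for _dev in range(em.n_devices):
        tonic = tonic0 + _stage_profile(schedule, fs, increments,
                                        em.transition_smooth_s)
        drift = em.drift_amp_us * np.sin(
            2 * np.pi * t / em.drift_period_s + rng.uniform(0, 2 * np.pi))
        scr = _scr_train(schedule, fs, rates, em.scr_amp_mean_us,
                         em.scr_rise_s, em.scr_decay_s, rng)
        clean = tonic + drift + scr
        noisy = clean + rng.normal(0.0, em.noise_sd_us, n)
        segments = _artifact_segments(schedule, fs, em, rng)
        values = noisy.copy()
        for a, b in segments:
            values[a:b] = em.artifact_drop_to_us + rng.normal(
                0.0, em.noise_sd_us, b - a)
        marks = [(config.start_time + s, lab)
                 for lab, s, _e in schedule.stages]
        series_list.append(EDASeries(
            participant_id=participant_id,
            start_time=config.start_time,
            sample_rate=fs,
            values=values,
            event_marks=marks,
        ))
        clean_list.append(clean)  # noise-free, artifact-free ground truth
        segment_list.append(segments)
    return series_list, clean_list, segment_list


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------

def _channel_block_umol(config: SyntheticConfig, montage: Montage, cid: str,
                        group: str, null: bool) -> dict:
    """Per-stage sustained dOHb block (micromol/L) for one channel."""
    fm = config.fnirs
    levels = {lab: 0.0 for lab in config.schedule.labels}
    if null:
        return levels
    ch = montage.channel(cid)
    levels["stress"] = (fm.stress_ohb_right_umol if ch.hemisphere == "right"
                        else fm.stress_ohb_left_umol)
    if cid in fm.sound_contrast_channels and group != "soothing":
        levels["sound"] = fm.sound_ohb_control_umol
    return levels


def simulate_fnirs(config: SyntheticConfig, rng: np.random.Generator,
                   participant_id: str, group: str, montage: Montage,
                   null: bool = False,
                   truth_cache: dict | None = None,
                   ) -> tuple[RawFNIRS, dict]:
    """One participant's optical-density recording plus true stage means.

    True stage means are rolling-window stage means of the clean
    concentration blocks passed through the analysis summary filter (the
    low-pass of the hemodynamic band) -- the value an ideal noise-free
    analysis would produce.
    """
    fm = config.fnirs
    fs = fm.sample_rate
    schedule = config.schedule
    n = int(round(schedule.end_s * fs))
    t = np.arange(n) / fs
    age = float(np.clip(rng.normal(fm.age_mean_years, fm.age_sd_years),
                        18.0, 35.0))
    amp_scale = float(np.exp(rng.normal(0.0, fm.amp_sd_log)))
    f_card = fm.cardiac_freq_hz + rng.uniform(-fm.cardiac_freq_jitter_hz,
                                              fm.cardiac_freq_jitter_hz)
    wl_scale = {config.wavelengths[0]: 1.0,
                config.wavelengths[1]: fm.cardiac_wl_ratio}

    od: dict[tuple[str, float], np.ndarray] = {}
    true_means: dict[str, dict] = {}
    if truth_cache is None:
        truth_cache = {}
    matrix_cache: dict[float, np.ndarray] = {}
    for cid in montage.channel_ids:
        ch = montage.channel(cid)
        blocks = _channel_block_umol(config, montage, cid, group, null)
        key = tuple(sorted(blocks.items()))
        if key in truth_cache:
            block_ohb, unit_means = truth_cache[key]
        else:
            block_ohb = _stage_profile(schedule, fs, blocks, smooth_s=0.0)
            # ground truth: what a noise-free analysis would measure
            clean = fnirs_mod.HemoSeries(
                participant_id="truth", sample_rate=fs,
                delta_ohb={"x": block_ohb},
                delta_hhb={"x": fm.hhb_ratio * block_ohb},
                retained_channels=("x",))
            filtered = fnirs_mod.lowpass_hemo(clean)
            unit_means = {}
            for label, start, end in schedule.stages:
                unit_means[label] = (
                    eda_mod.rolling_stage_mean(filtered.delta_ohb["x"], fs,
                                               start, end,
                                               config.summary_window_s),
                    eda_mod.rolling_stage_mean(filtered.delta_hhb["x"], fs,
                                               start, end,
                                               config.summary_window_s),
                )
            truth_cache[key] = (block_ohb, unit_means)
        # blocks (and hence their filtered means) scale linearly with the
        # participant's amplitude factor
        true_means[cid] = {lab: (amp_scale * o, amp_scale * h)
                           for lab, (o, h) in unit_means.items()}

        if cid in fm.decoupled_channels:
            for wl in config.wavelengths:
                od[(cid, wl)] = rng.normal(0.0, fm.decoupled_noise_sd, n)
            continue

        mayer = fm.mayer_amp_umol * np.sin(
            2 * np.pi * fm.mayer_freq_hz * t + rng.uniform(0, 2 * np.pi))
        resp = fm.resp_amp_umol * np.sin(
            2 * np.pi * fm.resp_freq_hz * t + rng.uniform(0, 2 * np.pi))
        conc_ohb = amp_scale * block_ohb + mayer + resp
        conc_hhb = amp_scale * fm.hhb_ratio * block_ohb - 0.3 * mayer \
            + 0.2 * resp
        dist = ch.source_detector_distance_cm
        if dist not in matrix_cache:
            matrix_cache[dist] = fnirs_mod._extinction_matrix(
                tuple(config.wavelengths), fnirs_mod.EXTINCTION_TABLE,
                dist, age)
        m = matrix_cache[dist]
        forward = m @ np.vstack([conc_ohb, conc_hhb])
        cardiac = np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi))
        for i, wl in enumerate(config.wavelengths):
            od[(cid, wl)] = (forward[i]
                             + fm.cardiac_amp_od * wl_scale[wl] * cardiac
                             + rng.normal(0.0, fm.od_noise_sd, n))

    raw = RawFNIRS(participant_id=participant_id, sample_rate=fs,
                   montage=montage, od=od, age_years=age)
    return raw, true_means


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort_arrays(config: SyntheticConfig, seed: int,
                           null: bool = False, with_eda: bool = True,
                           with_fnirs: bool = True,
                           montage: Montage | None = None) -> Cohort:
    """Deterministic in-memory cohort (no disk I/O)."""
    rng = np.random.default_rng(seed)
    montage = montage or default_montage()
    panel, cort_params = simulate_cortisol_panel(config, rng, null=null)
    participants = []
    clean_eda, eda_artifacts, true_means, groups_map, ages = {}, {}, {}, {}, {}
    truth_cache: dict = {}
    for pid, group in config.participant_table():
        groups_map[pid] = group
        eda_series: list[EDASeries] = []
        if with_eda:
            eda_series, clean, segments = simulate_eda(config, rng, pid,
                                                       null=null)
            clean_eda[pid] = clean
            eda_artifacts[pid] = segments
        raw = None
        if with_fnirs:
            raw, means = simulate_fnirs(config, rng, pid, group, montage,
                                        null=null, truth_cache=truth_cache)
            true_means[pid] = means
        ages[pid] = raw.age_years if raw is not None else float(
            config.fnirs.age_mean_years)
        participants.append(ParticipantData(
            participant_id=pid, group=group, age_years=ages[pid],
            eda=eda_series, fnirs=raw))
    truth = GroundTruth(
        groups=groups_map, ages=ages, cortisol_params=cort_params,
        clean_eda=clean_eda, eda_artifacts=eda_artifacts,
        true_stage_means=true_means,
        decoupled_channels=tuple(config.fnirs.decoupled_channels),
        sound_contrast_channels=tuple(config.fnirs.sound_contrast_channels),
    )
    return Cohort(config=config, montage=montage, schedule=config.schedule,
                  participants=participants, panel=panel, truth=truth)


def _truth_to_jsonable(truth: GroundTruth) -> dict:
    return {
        "groups": truth.groups,
        "ages": truth.ages,
        "cortisol_params": truth.cortisol_params,
        "eda_artifacts": {pid: [[list(seg) for seg in dev] for dev in devs]
                          for pid, devs in truth.eda_artifacts.items()},
        "true_stage_means": {
            pid: {cid: {stage: list(v) for stage, v in stages.items()}
                  for cid, stages in chans.items()}
            for pid, chans in truth.true_stage_means.items()},
        "decoupled_channels": list(truth.decoupled_channels),
        "sound_contrast_channels": list(truth.sound_contrast_channels),
    }


def generate_cohort(config: SyntheticConfig, out_dir, seed: int,
                    null: bool = False) -> tuple[Cohort, dict]:
    """Write a cohort in the pipeline's on-disk layout.

    Layout: ``participants.csv``, ``montage.yaml``, ``schedule.yaml``,
    ``cortisol.csv``, ``eda/<pid>_dev<k>.csv`` (+ ``_tags.txt``),
    ``fnirs/<pid>.edf``, ``ground_truth/truth.json`` (+ clean EDA CSVs) and
    a ``manifest.json`` listing every file.  Deterministic given the seed;
    CSV outputs are byte-identical across runs, EDF equal within the 16-bit
    representation precision.
    """
    out_dir = Path(out_dir)
    cohort = generate_cohort_arrays(config, seed, null=null)
    (out_dir / "eda").mkdir(parents=True, exist_ok=True)
    (out_dir / "fnirs").mkdir(exist_ok=True)
    (out_dir / "ground_truth").mkdir(exist_ok=True)
    files = []

    pd.DataFrame(
        [{"participant_id": p.participant_id, "group": p.group,
          "age_years": p.age_years} for p in cohort.participants]
    ).to_csv(out_dir / "participants.csv", index=False)
    files.append("participants.csv")
    save_montage(cohort.montage, out_dir / "montage.yaml")
    save_schedule(cohort.schedule, out_dir / "schedule.yaml")
    write_cortisol_csv(cohort.panel, out_dir / "cortisol.csv")
    files += ["montage.yaml", "schedule.yaml", "cortisol.csv"]

    for p in cohort.participants:
        for k, series in enumerate(p.eda, start=1):
            rel = f"eda/{p.participant_id}_dev{k}.csv"
            tags = f"eda/{p.participant_id}_dev{k}_tags.txt"
            write_eda_csv(series, out_dir / rel, tags_path=out_dir / tags)
            files += [rel, tags]
        if p.fnirs is not None:
            rel = f"fnirs/{p.participant_id}.edf"
            write_fnirs_edf(p.fnirs, out_dir / rel)
            files.append(rel)
        for k, clean in enumerate(cohort.truth.clean_eda.get(
                p.participant_id, []), start=1):
            rel = f"ground_truth/{p.participant_id}_dev{k}_clean.csv"
            np.savetxt(out_dir / rel, clean, fmt="%.17g")
            files.append(rel)

    truth_rel = "ground_truth/truth.json"
    (out_dir / truth_rel).write_text(
        json.dumps(_truth_to_jsonable(cohort.truth), indent=1))
    files.append(truth_rel)

    manifest = {
        "seed": seed,
        "null": null,
        "n_participants": len(cohort.participants),
        "n_per_group": list(config.n_per_group),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return cohort, manifest


def generate_null_cohort_arrays(config: SyntheticConfig, seed: int,
                                **kwargs) -> Cohort:
    """As :func:`generate_cohort_arrays` with every effect zeroed."""
    return generate_cohort_arrays(config, seed, null=True, **kwargs)


def generate_null_cohort(config: SyntheticConfig, out_dir, seed: int,
                         ) -> tuple[Cohort, dict]:
    """As :func:`generate_cohort` with every effect zeroed."""
    return generate_cohort(config, out_dir, seed, null=True)
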