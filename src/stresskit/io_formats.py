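"""Domain types and file I/O for the multimodal stress-recovery pipeline.

Everything the pipeline reads or writes passes through this module: the
wrist-device EDA CSV dialect (with a separate event-tag file), fNIRS
optical-density recordings in European Data Format (EDF), the salivary
cortisol panel CSV, montage / stage-schedule YAML configs, and the tidy
statistical-results table.

EDF reading goes through :mod:`mne`.  EDF writing (needed by the synthetic
cohort generator) is a minimal plain-EDF writer implemented here: 16-bit
samples, one-second data records, channel labels ``"Tx<i>-Rx<j> <nm>"``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

#: Stage labels of the five-point salivary cortisol panel, in sampling order.
CORTISOL_STAGES = ("baseline", "stress", "sound", "rest1", "rest2")

#: Experimental groups.
GROUPS = ("soothing", "robotic", "silence")

#: Default device wavelengths (nm).  The montage hardware pairs one short and
#: one long wavelength per channel; these defaults are configurable because
#: they are an assumption about the device class, not a measured value.
DEFAULT_WAVELENGTHS = (760.0, 850.0)

HEMISPHERES = ("left", "right")
BRODMANN_AREAS = (9, 10, 44, 45, 46, 47)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One source-detector channel of the prefrontal montage."""

    channel_id: str
    hemisphere: str
    brodmann_area: int
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"channel {self.channel_id}: hemisphere must be one of "
                f"{HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.brodmann_area not in BRODMANN_AREAS:
            raise ValidationError(
                f"channel {self.channel_id}: Brodmann area {self.brodmann_area}"
                f" not in {BRODMANN_AREAS}"
            )
        if not self.source_detector_distance_cm > 0:
            raise ValidationError(
                f"channel {self.channel_id}: source-detector distance must be"
                f" > 0, got {self.source_detector_distance_cm}"
            )


@dataclass(frozen=True)
class Montage:
    """Channel catalogue plus the right/left pairs used for laterality."""

    channels: tuple[Channel, ...]
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate channel ids in montage: {dupes}")
        by_id = {c.channel_id: c for c in self.channels}
        for right_id, left_id in self.pairs:
            for cid in (right_id, left_id):
                if cid not in by_id:
                    raise ValidationError(
                        f"laterality pair references unknown channel {cid!r}"
                    )
            if by_id[right_id].hemisphere != "right":
                raise ValidationError(
                    f"pair ({right_id}, {left_id}): first member must be a "
                    f"right-hemisphere channel"
                )
            if by_id[left_id].hemisphere != "left":
                raise ValidationError(
                    f"pair ({right_id}, {left_id}): second member must be a "
                    f"left-hemisphere channel"
                )

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(c.channel_id for c in self.channels)

    def channel(self, channel_id: str) -> Channel:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise ConfigError(f"channel {channel_id!r} not in montage")


@dataclass
class EDASeries:
    """Uniformly sampled skin-conductance trace (microsiemens).

    ``artifact_mask`` flags invalid samples (True = flagged); it starts all
    False and is filled by :func:`stresskit.eda.detect_artifacts`.
    """

    participant_id: str
    start_time: float  # UTC epoch seconds
    sample_rate: float  # Hz
    values: np.ndarray  # microsiemens
    event_marks: list[tuple[float, str]] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.sample_rate > 0:
            raise ValidationError(
                f"EDA sample rate must be > 0, got {self.sample_rate}"
            )
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                f"EDA series needs at least 2 samples, got {self.values.size}"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.values.size, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.values.shape:
            raise ValidationError(
                "artifact mask length does not match values length"
            )
        end = self.start_time + self.values.size / self.sample_rate
        for ts, label in self.event_marks:
            if not (self.start_time <= ts <= end):
                raise ValidationError(
                    f"event tag {label!r} at {ts} outside recording span "
                    f"[{self.start_time}, {end}]"
                )

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate

    def copy(self) -> "EDASeries":
        return EDASeries(
            participant_id=self.participant_id,
            start_time=self.start_time,
            sample_rate=self.sample_rate,
            values=self.values.copy(),
            event_marks=list(self.event_marks),
            artifact_mask=self.artifact_mask.copy(),
        )


@dataclass
class RawFNIRS:
    """Per-channel, per-wavelength optical-density change traces."""

    participant_id: str
    sample_rate: float
    montage: Montage
    od: dict[tuple[str, float], np.ndarray]  # (channel_id, wavelength_nm)
    age_years: float

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValidationError("fNIRS sample rate must be > 0")
        lengths = set()
        per_channel: dict[str, set[float]] = {}
        montage_ids = set(self.montage.channel_ids)
        for (cid, wl), trace in self.od.items():
            if cid not in montage_ids:
                raise ValidationError(
                    f"optical-density trace for unknown channel {cid!r}"
                )
            self.od[(cid, wl)] = np.asarray(trace, dtype=float)
            lengths.add(self.od[(cid, wl)].size)
            per_channel.setdefault(cid, set()).add(wl)
        if len(lengths) > 1:
            raise ValidationError(
                f"optical-density traces have unequal lengths: {sorted(lengths)}"
            )
        bad = sorted(c for c, wls in per_channel.items() if len(wls) != 2)
        if bad:
            raise FormatError(
                f"channels without exactly 2 wavelengths: {bad}"
            )

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(sorted({cid for cid, _ in self.od}))

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted({wl for _, wl in self.od}))

    @property
    def n_samples(self) -> int:
        return next(iter(self.od.values())).size


@dataclass
class StageSchedule:
    """Ordered, non-overlapping stage intervals.

    Offsets are seconds from recording start; intervals are half-open
    ``[start, end)``.
    """

    stages: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        labels = [s[0] for s in self.stages]
        if len(set(labels)) != len(labels):
            raise ValidationError("stage labels must be unique")
        prev_end = -math.inf
        for label, start, end in self.stages:
            if not start < end:
                raise ValidationError(
                    f"stage {label!r}: interval [{start}, {end}) is empty"
                )
            if start < prev_end:
                raise ValidationError(
                    f"stage {label!r} overlaps the previous stage"
                )
            prev_end = end

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.stages)

    def interval(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.stages:
            if lab == label:
                return (start, end)
        raise ValidationError(f"unknown stage {label!r}")

    @property
    def end_s(self) -> float:
        return self.stages[-1][2]

    def sample_slice(self, label: str, sample_rate: float) -> slice:
        start, end = self.interval(label)
        return slice(int(round(start * sample_rate)),
                     int(round(end * sample_rate)))


class CortisolPanel:
    """Participants x stages salivary cortisol concentrations (nmol/L)."""

    COLUMNS = ("participant_id", "group", "stage", "nmol_per_l")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"cortisol table missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        bad_stage = sorted(set(frame["stage"]) - set(CORTISOL_STAGES))
        if bad_stage:
            raise ValidationError(f"unknown cortisol stage labels: {bad_stage}")
        if (frame["nmol_per_l"] < 0).any():
            rows = frame.index[frame["nmol_per_l"] < 0].tolist()
            raise ValidationError(
                f"negative cortisol concentration in rows {rows}"
            )
        dup = frame.duplicated(subset=["participant_id", "stage"])
        if dup.any():
            pairs = frame.loc[dup, ["participant_id", "stage"]]
            raise ValidationError(
                "duplicate (participant, stage) rows: "
                + ", ".join(f"({r.participant_id}, {r.stage})"
                            for r in pairs.itertuples())
            )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.frame["participant_id"].unique())

    def group_of(self, participant_id: str) -> str:
        rows = self.frame[self.frame["participant_id"] == participant_id]
        if rows.empty:
            raise ValidationError(f"participant {participant_id!r} not in panel")
        return rows["group"].iloc[0]

    def value(self, participant_id: str, stage: str) -> float:
        rows = self.frame[
            (self.frame["participant_id"] == participant_id)
            & (self.frame["stage"] == stage)
        ]
        if rows.empty:
            raise ValidationError(
                f"no cortisol sample for ({participant_id}, {stage})"
            )
        return float(rows["nmol_per_l"].iloc[0])


@dataclass
class StatsResult:
    """One statistical comparison, shaped like the published result tables."""

    test: str  # levene | paired_t | independent_t | rm_anova
    measure: str  # cortisol | eda | hbo | hhb | lir
    statistic: float
    df: float
    p: float
    effect_size: float
    effect_size_kind: str  # cohen_d | partial_eta_sq | eta_sq | none
    channel: str | None = None
    pair: tuple[str, str] | None = None
    stages: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()
    hemisphere: str | None = None
    brodmann_area: int | None = None
    df2: float | None = None
    effect: str | None = None  # for rm_anova rows: stage | group | interaction
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")
        if not self.df > 0:
            raise ValidationError(f"degrees of freedom must be > 0, got {self.df}")

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "measure": self.measure,
            "effect": self.effect,
            "channel": self.channel,
            "pair": "|".join(self.pair) if self.pair else None,
            "stages": "|".join(self.stages),
            "groups": "|".join(self.groups),
            "statistic": self.statistic,
            "df": self.df,
            "df2": self.df2,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_kind": self.effect_size_kind,
            "hemisphere": self.hemisphere,
            "brodmann_area": self.brodmann_area,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# EDA device-dialect CSV
# ---------------------------------------------------------------------------

def read_eda_csv(path, tags_path=None, participant_id: str | None = None
                 ) -> EDASeries:
    """Read a wrist-device EDA recording.

    Dialect: row 1 is the UTC start timestamp (epoch seconds), row 2 the
    sample rate in Hz, every following row one conductance sample in
    microsiemens.  ``tags_path`` optionally names a file with one event
    timestamp (epoch seconds) per line.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected header rows 1-2, found {len(lines)}")
    try:
        start_time = float(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}: row 1 is not an epoch timestamp: "
                          f"{lines[0]!r}") from exc
    try:
        sample_rate = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: row 2 is not a sample rate: "
                          f"{lines[1]!r}") from exc
    values = []
    for i, ln in enumerate(lines[2:], start=3):
        try:
            values.append(float(ln))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i} is not a sample: {ln!r}") from exc

    event_marks: list[tuple[float, str]] = []
    if tags_path is not None:
        tag_lines = [ln.strip() for ln in Path(tags_path).read_text().splitlines()
                     if ln.strip()]
        for i, ln in enumerate(tag_lines, start=1):
            try:
                ts = float(ln)
            except ValueError as exc:
                raise FormatError(
                    f"{tags_path}: row {i} is not an epoch timestamp: {ln!r}"
                ) from exc
            event_marks.append((ts, f"tag{i}"))

    return EDASeries(
        participant_id=participant_id or path.stem,
        start_time=start_time,
        sample_rate=sample_rate,
        values=np.asarray(values, dtype=float),
        event_marks=event_marks,
    )


def write_eda_csv(series: EDASeries, path, tags_path=None) -> None:
    """Write an :class:`EDASeries` in the wrist-device CSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{float(series.start_time)!r}\n")
        fh.write(f"{float(series.sample_rate)!r}\n")
        for v in series.values:
            fh.write(f"{float(v)!r}\n")
    if tags_path is not None:
        with Path(tags_path).open("w") as fh:
            for ts, _label in series.event_marks:
                fh.write(f"{float(ts)!r}\n")


# ---------------------------------------------------------------------------
# fNIRS EDF
# ---------------------------------------------------------------------------

def _parse_edf_label(label: str) -> tuple[str, float] | None:
    """Parse ``"Tx<i>-Rx<j> <wavelength nm>"``; None if not in convention."""
    parts = label.strip().split()
    if len(parts) != 2:
        return None
    cid, wl = parts
    if "-" not in cid:
        return None
    try:
        return cid, float(wl)
    except ValueError:
        return None


def read_fnirs_edf(path, montage: Montage, age_years: float,
                   participant_id: str | None = None,
                   label_map: Mapping[str, tuple[str, float]] | None = None,
                   ) -> RawFNIRS:
    """Read an optical-density EDF export into a :class:`RawFNIRS`.

    EDF channel labels must map one-to-one onto ``(channel_id, wavelength)``,
    either through the default ``"Tx<i>-Rx<j> <nm>"`` naming convention or
    through an explicit ``label_map``.
    """
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    od: dict[tuple[str, float], np.ndarray] = {}
    unmatched = []
    for i, label in enumerate(raw.ch_names):
        if label_map is not None:
            key = label_map.get(label)
        else:
            key = _parse_edf_label(label)
        if key is None:
            unmatched.append(label)
            continue
        od[(key[0], float(key[1]))] = data[i]
    if unmatched:
        raise FormatError(
            f"{path}: EDF labels not matching the channel naming convention: "
            f"{unmatched}"
        )
    return RawFNIRS(
        participant_id=participant_id or path.stem,
        sample_rate=float(raw.info["sfreq"]),
        montage=montage,
        od=od,
        age_years=age_years,
    )


def write_fnirs_edf(raw: RawFNIRS, path) -> None:
    """Write optical-density traces as a plain EDF file.

    Minimal writer: 16-bit samples, one-second data records (the trace length
    must be an integer number of seconds), labels ``"<channel> <nm>"``,
    dimensionless physical unit.  Quantization limits the round-trip fidelity
    to roughly ``(max - min) / 2**16`` per signal.
    """
    fs = raw.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    keys = sorted(raw.od.keys())
    sigs = np.vstack([raw.od[k] for k in keys])
    labels = [f"{cid} {int(wl) if float(wl).is_integer() else wl}"
              for cid, wl in keys]
    nsig, n = sigs.shape
    if n % fs != 0:
        raise FormatError(
            f"trace length {n} is not a whole number of 1-s records at {fs} Hz"
        )
    nrec = n // fs
    dmin, dmax = -32768, 32767

    def fx(s, w: int) -> bytes:
        b = str(s).encode("ascii")[:w]
        return b + b" " * (w - len(b))

    pmins, pmaxs = [], []
    pmin_fields, pmax_fields = b"", b""
    for i in range(nsig):
        lo, hi = float(sigs[i].min()), float(sigs[i].max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = ("%.6f" % lo)[:8], ("%.6f" % hi)[:8]
        # use the truncated header representation for exact scaling
        lo_t, hi_t = float(lo_s), float(hi_s)
        if hi_t <= lo_t:
            hi_t = lo_t + 1.0
            hi_s = ("%.6f" % hi_t)[:8]
        pmins.append(lo_t)
        pmaxs.append(hi_t)
        pmin_fields += fx(lo_s, 8)
        pmax_fields += fx(hi_s, 8)

    hdr = fx("0", 8)
    hdr += fx(raw.participant_id.replace(" ", "_") or "X", 80)
    hdr += fx("Startdate 01-JAN-2000 X X X", 80)
    hdr += fx("01.01.00", 8) + fx("00.00.00", 8)
    hdr += fx(256 * (nsig + 1), 8) + fx("", 44)
    hdr += fx(nrec, 8) + fx("1", 8) + fx(nsig, 4)
    for lab in labels:
        hdr += fx(lab, 16)
    hdr += b" " * 80 * nsig          # transducer type
    hdr += fx("", 8) * nsig          # physical dimension (dimensionless OD)
    hdr += pmin_fields + pmax_fields
    hdr += fx(dmin, 8) * nsig + fx(dmax, 8) * nsig
    hdr += b" " * 80 * nsig          # prefiltering
    hdr += fx(fs, 8) * nsig          # samples per record
    hdr += b" " * 32 * nsig
    assert len(hdr) == 256 * (nsig + 1)

    gains = [(dmax - dmin) / (pmaxs[i] - pmins[i]) for i in range(nsig)]
    with Path(path).open("wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            for i in range(nsig):
                seg = sigs[i, r * fs:(r + 1) * fs]
                dig = np.round((seg - pmins[i]) * gains[i]) + dmin
                fh.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# Cortisol CSV and tidy results
# ---------------------------------------------------------------------------

def read_cortisol_csv(path) -> CortisolPanel:
    """Read a cortisol panel CSV (participant, group, stage, nmol_per_L)."""
    frame = pd.read_csv(path)
    rename = {}
    for col in frame.columns:
        low = col.strip().lower()
        if low in ("participant", "participant_id"):
            rename[col] = "participant_id"
        elif low == "group":
            rename[col] = "group"
        elif low == "stage":
            rename[col] = "stage"
        elif low in ("nmol_per_l", "nmol/l", "concentration"):
            rename[col] = "nmol_per_l"
    frame = frame.rename(columns=rename)
    frame["participant_id"] = frame.get(
        "participant_id", pd.Series(dtype=str)).astype(str)
    return CortisolPanel(frame)


def write_cortisol_csv(panel: CortisolPanel, path) -> None:
    panel.frame.rename(columns={"nmol_per_l": "nmol_per_L"}).to_csv(
        path, index=False)


def results_frame(results: Sequence[StatsResult]) -> pd.DataFrame:
    """Tidy results table, one comparison per row."""
    cols = ["test", "measure", "effect", "channel", "pair", "stages", "groups",
            "statistic", "df", "df2", "p", "effect_size", "effect_size_kind",
            "hemisphere", "brodmann_area", "significant"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_row() for r in results], columns=cols)


def write_tidy_results(results: Sequence[StatsResult], path) -> None:
    results_frame(results).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Montage / schedule configs
# ---------------------------------------------------------------------------

def montage_from_dict(cfg: Mapping) -> Montage:
    dist = float(cfg.get("source_detector_distance_cm", 3.0))
    channels = tuple(
        Channel(
            channel_id=c["id"],
            hemisphere=c["hemisphere"],
            brodmann_area=int(c["brodmann_area"]),
            source_detector_distance_cm=float(
                c.get("source_detector_distance_cm", dist)),
        )
        for c in cfg["channels"]
    )
    pairs = tuple((p[0], p[1]) for p in cfg.get("pairs", []))
    return Montage(channels=channels, pairs=pairs)


def load_montage(path) -> Montage:
    with Path(path).open() as fh:
        return montage_from_dict(yaml.safe_load(fh))


def save_montage(montage: Montage, path) -> None:
    cfg = {
        "channels": [
            {
                "id": c.channel_id,
                "hemisphere": c.hemisphere,
                "brodmann_area": c.brodmann_area,
                "source_detector_distance_cm": c.source_detector_distance_cm,
            }
            for c in montage.channels
        ],
        "pairs": [list(p) for p in montage.pairs],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def default_montage() -> Montage:
    """The packaged 2 x 12-channel prefrontal montage."""
    ref = resources.files("stresskit").joinpath("data/montage.yaml")
    return montage_from_dict(yaml.safe_load(ref.read_text()))


def schedule_from_dict(cfg: Mapping) -> StageSchedule:
    return StageSchedule(tuple(
        (s["label"], float(s["start_s"]), float(s["end_s"]))
        for s in cfg["stages"]
    ))


def load_schedule(path) -> StageSchedule:
    with Path(path).open() as fh:
        return schedule_from_dict(yaml.safe_load(fh))


def save_schedule(schedule: StageSchedule, path) -> None:
    cfg = {"stages": [
        {"label": lab, "start_s": start, "end_s": end}
        for lab, start, end in schedule.stages
    ]}
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def default_schedule() -> StageSchedule:
    """The packaged default stage schedule (40-min session)."""
    ref = resources.files("stresskit").joinpath("data/schedule.yaml")
    return schedule_from_dict(yaml.safe_load(ref.read_text()))
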