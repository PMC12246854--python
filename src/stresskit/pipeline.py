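"""End-to-end cohort pipeline: ingest, preprocess, summarize, LIR, stats.

``run_pipeline`` reads a cohort directory (the layout written by
:func:`stresskit.synthetic.generate_cohort`), runs every modality through
its preprocessing chain, computes per-stage summaries, the laterality table
and the statistical battery, and writes tidy CSV outputs plus a run manifest
recording the full configuration snapshot, per-participant channel
rejections and artifact fractions.  Unreadable participants are logged and
skipped with a warning, never silently dropped.  Input files are never
modified.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import eda as eda_mod
from . import fnirs as fnirs_mod
from . import laterality as lat_mod
from . import stats as stats_mod
from .errors import ConfigError, StressKitError, ValidationError
from .io_formats import (
    CortisolPanel,
    Montage,
    StageSchedule,
    load_montage,
    load_schedule,
    read_cortisol_csv,
    read_eda_csv,
    read_fnirs_edf,
    results_frame,
    write_tidy_results,
)

logger = logging.getLogger(__name__)


@dataclass
class EDAConfig:
    jump_threshold_us: float = 0.01
    filter_cutoff_hz: float = 0.5
    filter_order: int = 4
    window_s: float = 120.0
    band_k: float = 3.0
    global_k_low: float = 1.0
    global_k_high: float = 3.0
    min_valid_fraction: float = 0.7
    repair_mode: str = "interpolate"


@dataclass
class FNIRSConfig:
    cardiac_band_hz: tuple = (0.7, 1.5)
    hemo_band_hz: tuple = (0.02, 0.18)
    sci_threshold: float = 0.75
    window_s: float = 120.0
    filter_order: int = 4
    #: signal feeding the stage summaries: "lowpass" retains sustained
    #: activation blocks; "bandpass" is the full printed chain.
    summary_filter: str = "lowpass"


@dataclass
class LIRConfig:
    mode: str = "rectified"
    floor: float = 1e-9


@dataclass
class StatsConfig:
    alpha: float = 0.05
    fdr: bool = False


@dataclass
class PipelineConfig:
    eda: EDAConfig = field(default_factory=EDAConfig)
    fnirs: FNIRSConfig = field(default_factory=FNIRSConfig)
    lir: LIRConfig = field(default_factory=LIRConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section in ("eda", "fnirs", "lir", "stats"):
            for key, value in (raw.get(section) or {}).items():
                target = getattr(cfg, section)
                if not hasattr(target, key):
                    raise ConfigError(f"unknown config key {section}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg


@dataclass
class RunManifest:
    config: dict
    version: str
    n_participants: int
    channel_rejections: dict  # pid -> list of rejected channel ids
    artifact_fractions: dict  # pid -> per-device fraction of repaired samples
    warnings: list
    outputs: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def process_participant(pid: str, group: str, eda_series: list,
                        raw_fnirs, schedule: StageSchedule,
                        config: PipelineConfig) -> dict:
    """One participant through both modality chains; returns summaries."""
    out: dict = {"participant_id": pid, "group": group}

    device_summaries = []
    artifact_fractions = []
    for series in eda_series:
        cleaned = eda_mod.preprocess(
            series,
            jump_threshold=config.eda.jump_threshold_us,
            cutoff_hz=config.eda.filter_cutoff_hz,
            order=config.eda.filter_order,
            band_k=config.eda.band_k,
            global_k_low=config.eda.global_k_low,
            global_k_high=config.eda.global_k_high,
            repair_mode=config.eda.repair_mode)
        artifact_fractions.append(float(cleaned.artifact_mask.mean()))
        device_summaries.append(eda_mod.summarize_stages(
            cleaned, schedule, window_s=config.eda.window_s))
    out["eda_summaries"] = (
        eda_mod.fuse_device_summaries(
            device_summaries,
            min_valid_fraction=config.eda.min_valid_fraction)
        if device_summaries else [])
    out["artifact_fractions"] = artifact_fractions

    out["hemo_summaries"] = []
    out["sci_report"] = None
    if raw_fnirs is not None:
        hemo, report = fnirs_mod.preprocess(
            raw_fnirs,
            sci_threshold=config.fnirs.sci_threshold,
            cardiac_band=config.fnirs.cardiac_band_hz,
            hemo_band=config.fnirs.hemo_band_hz,
            order=config.fnirs.filter_order,
            summary_filter=config.fnirs.summary_filter)
        out["sci_report"] = report
        out["hemo_summaries"] = fnirs_mod.stage_averages(
            hemo, schedule, window_s=config.fnirs.window_s)
    return out


def process_cohort(cohort, config: PipelineConfig | None = None,
                   plan=None) -> dict:
    """Run an in-memory cohort (see :mod:`stresskit.synthetic`) end to end."""
    config = config or PipelineConfig()
    montage: Montage = cohort.montage
    schedule: StageSchedule = cohort.schedule
    warnings_list: list[str] = []
    eda_summaries, hemo_summaries = [], []
    rejections, artifact_fractions, groups = {}, {}, {}
    for p in cohort.participants:
        groups[p.participant_id] = p.group
        try:
            res = process_participant(p.participant_id, p.group, p.eda,
                                      p.fnirs, schedule, config)
        except StressKitError as exc:
            msg = f"participant {p.participant_id} skipped: {exc}"
            logger.warning(msg)
            warnings_list.append(msg)
            continue
        eda_summaries.extend(res["eda_summaries"])
        hemo_summaries.extend(res["hemo_summaries"])
        artifact_fractions[p.participant_id] = res["artifact_fractions"]
        if res["sci_report"] is not None:
            rejections[p.participant_id] = sorted(
                c for c, k in res["sci_report"].keep.items() if not k)

    lir_frame = lat_mod.lir_table(
        hemo_summaries, montage.pairs, mode=config.lir.mode,
        floor=config.lir.floor, montage=montage) if hemo_summaries else None

    results = stats_mod.run_battery(
        cortisol_panel=cohort.panel,
        eda_summaries=eda_summaries,
        hemo_summaries=hemo_summaries,
        lir_frame=lir_frame,
        groups=groups,
        montage=montage,
        plan=plan,
        alpha=config.stats.alpha,
        fdr=config.stats.fdr)

    return {
        "eda_summaries": eda_summaries,
        "hemo_summaries": hemo_summaries,
        "lir": lir_frame,
        "results": results,
        "rejections": rejections,
        "artifact_fractions": artifact_fractions,
        "warnings": warnings_list,
        "groups": groups,
    }


def load_cohort_dir(cohort_dir, skip_unreadable: bool = False):
    """Read a cohort directory into the in-memory cohort structure.

    With ``skip_unreadable`` a participant whose files fail to parse is
    dropped and reported in the returned warnings list instead of aborting
    the whole run.  Returns ``(cohort, warnings)``.
    """
    from .synthetic import Cohort, ParticipantData  # local: avoid cycle

    cohort_dir = Path(cohort_dir)
    required = ["participants.csv", "montage.yaml", "schedule.yaml",
                "cortisol.csv"]
    missing = [f for f in required if not (cohort_dir / f).exists()]
    if missing:
        raise ConfigError(
            f"cohort directory {cohort_dir} missing files: {missing}")
    montage = load_montage(cohort_dir / "montage.yaml")
    schedule = load_schedule(cohort_dir / "schedule.yaml")
    panel = read_cortisol_csv(cohort_dir / "cortisol.csv")
    roster = pd.read_csv(cohort_dir / "participants.csv",
                         dtype={"participant_id": str})
    if roster.empty:
        raise ValidationError("empty cohort: no participants listed")
    participants = []
    warnings_list: list[str] = []
    for row in roster.itertuples():
        pid = row.participant_id
        try:
            eda_series = []
            for dev_csv in sorted((cohort_dir / "eda").glob(f"{pid}_dev*.csv")):
                tags = dev_csv.with_name(dev_csv.stem + "_tags.txt")
                eda_series.append(read_eda_csv(
                    dev_csv, tags_path=tags if tags.exists() else None,
                    participant_id=pid))
            edf = cohort_dir / "fnirs" / f"{pid}.edf"
            raw = (read_fnirs_edf(edf, montage, float(row.age_years),
                                  participant_id=pid)
                   if edf.exists() else None)
        except StressKitError as exc:
            if not skip_unreadable:
                raise
            msg = f"participant {pid} skipped (unreadable): {exc}"
            logger.warning(msg)
            warnings_list.append(msg)
            continue
        participants.append(ParticipantData(
            participant_id=pid, group=row.group,
            age_years=float(row.age_years), eda=eda_series, fnirs=raw))
    cohort = Cohort(config=None, montage=montage, schedule=schedule,
                    participants=participants, panel=panel, truth=None)
    return cohort, warnings_list


def run_pipeline(cohort_dir, out_dir, config: PipelineConfig | None = None,
                 plan=None) -> RunManifest:
    """Disk-to-disk pipeline run; returns the manifest (also written)."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("stresskit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cohort, load_warnings = load_cohort_dir(cohort_dir,
                                                skip_unreadable=True)
        processed = process_cohort(cohort, config, plan=plan)
        processed["warnings"] = load_warnings + processed["warnings"]

        outputs = ["run.log"]
        write_tidy_results(processed["results"], out_dir / "results.csv")
        outputs.append("results.csv")
        if processed["lir"] is not None:
            processed["lir"].to_csv(out_dir / "lir.csv", index=False)
            outputs.append("lir.csv")
        pd.DataFrame([dataclasses.asdict(s)
                      for s in processed["eda_summaries"]]).to_csv(
            out_dir / "eda_summaries.csv", index=False)
        outputs.append("eda_summaries.csv")
        pd.DataFrame([dataclasses.asdict(s)
                      for s in processed["hemo_summaries"]]).to_csv(
            out_dir / "hemo_summaries.csv", index=False)
        outputs.append("hemo_summaries.csv")

        manifest = RunManifest(
            config=config.to_dict(),
            version=__version__,
            n_participants=len(cohort.participants),
            channel_rejections=processed["rejections"],
            artifact_fractions=processed["artifact_fractions"],
            warnings=processed["warnings"],
            outputs=outputs + ["manifest.json"],
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
        logger.info("run complete: %d participants, %d warnings",
                    manifest.n_participants, len(manifest.warnings))
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()


def qc_report(cohort_dir, config: PipelineConfig | None = None
              ) -> pd.DataFrame:
    """SCI and artifact-fraction report only (no statistics)."""
    config = config or PipelineConfig()
    cohort, _warnings = load_cohort_dir(cohort_dir, skip_unreadable=True)
    rows = []
    for p in cohort.participants:
        artifact_fracs = []
        for series in p.eda:
            flagged = eda_mod.detect_artifacts(
                series, jump_threshold=config.eda.jump_threshold_us,
                band_k=config.eda.band_k)
            artifact_fracs.append(float(flagged.artifact_mask.mean()))
        sci = {}
        if p.fnirs is not None:
            report = fnirs_mod.reject_channels(
                p.fnirs, threshold=config.fnirs.sci_threshold,
                band=config.fnirs.cardiac_band_hz,
                order=config.fnirs.filter_order)
            sci = report.sci
        for cid, value in sci.items():
            rows.append({"participant_id": p.participant_id,
                         "channel_id": cid, "sci": value,
                         "keep": value >= config.fnirs.sci_threshold,
                         "eda_artifact_fraction":
                             float(pd.Series(artifact_fracs).mean())
                             if artifact_fracs else None})
    return pd.DataFrame(rows)
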