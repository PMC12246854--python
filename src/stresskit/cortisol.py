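"""Salivary cortisol trajectories and recovery metrics.

The five-point panel (baseline, stress, sound, rest1, rest2) is anchored in
minutes relative to the end of the stress task: baseline at -15 min, stress
at 0, the sound sample right after the intervention (about +10 min, stored
per participant because it depends on the track length), rest1 10 min after
the sound sample and rest2 20 min after it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io_formats import CORTISOL_STAGES, CortisolPanel

#: Default sampling clock, minutes from stress-task end.
DEFAULT_MINUTES = {
    "baseline": -15.0,
    "stress": 0.0,
    "sound": 10.0,
    "rest1": 20.0,
    "rest2": 30.0,
}

DEFAULT_TOLERANCE = 0.05


@dataclass
class CortisolTrajectory:
    """One participant's stage-labelled concentrations, ordered in time."""

    participant_id: str
    group: str
    samples: tuple[tuple[str, float, float], ...]  # (stage, minutes, nmol/L)

    def __post_init__(self) -> None:
        times = [t for _s, t, _v in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"{self.participant_id}: cortisol samples not strictly "
                f"ordered in time"
            )
        if any(v < 0 for _s, _t, v in self.samples):
            raise ValidationError(
                f"{self.participant_id}: negative cortisol concentration"
            )

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(s for s, _t, _v in self.samples)

    def concentration(self, stage: str) -> float:
        for s, _t, v in self.samples:
            if s == stage:
                return v
        raise ValidationError(
            f"{self.participant_id}: stage {stage!r} missing from trajectory"
        )

    def minutes(self, stage: str) -> float:
        for s, t, _v in self.samples:
            if s == stage:
                return t
        raise ValidationError(
            f"{self.participant_id}: stage {stage!r} missing from trajectory"
        )


def stage_delta(traj: CortisolTrajectory, from_stage: str, to_stage: str
                ) -> float:
    """Concentration change, nmol/L: to_stage minus from_stage."""
    return traj.concentration(to_stage) - traj.concentration(from_stage)


def baseline_return(traj: CortisolTrajectory,
                    tolerance_fraction: float = DEFAULT_TOLERANCE,
                    ) -> str | None:
    """Earliest post-stress stage back within tolerance of baseline.

    Returns the first stage strictly after the stress sample whose
    concentration is <= baseline * (1 + tolerance); None if the trajectory
    never returns.  Monotone in tolerance: a larger tolerance never yields a
    later stage.
    """
    if tolerance_fraction < 0:
        raise ParameterError("tolerance must be >= 0")
    base = traj.concentration("baseline")  # raises if missing
    t_stress = traj.minutes("stress")
    ceiling = base * (1.0 + tolerance_fraction)
    for stage, t, value in traj.samples:
        if t <= t_stress:
            continue
        if value <= ceiling:
            return stage
    return None


def trajectories_from_panel(panel: CortisolPanel,
                            minutes: dict[str, float] | None = None,
                            ) -> list[CortisolTrajectory]:
    """Build per-participant trajectories from a validated panel."""
    minutes = minutes or DEFAULT_MINUTES
    out = []
    for pid in panel.participants:
        rows = panel.frame[panel.frame["participant_id"] == pid]
        samples = []
        for stage in CORTISOL_STAGES:
            sel = rows[rows["stage"] == stage]
            if sel.empty:
                continue
            samples.append((stage, minutes[stage],
                            float(sel["nmol_per_l"].iloc[0])))
        samples.sort(key=lambda s: s[1])
        out.append(CortisolTrajectory(
            participant_id=pid,
            group=rows["group"].iloc[0],
            samples=tuple(samples),
        ))
    return out


def recovery_elevation(panel: CortisolPanel) -> "pd.Series":
    """Per-participant mean post-intervention elevation above baseline.

    The average of the sound, rest1 and rest2 concentrations minus the
    baseline concentration (nmol/L).  A group that clears cortisol faster
    shows a smaller elevation; this is the pipeline's group-level recovery
    contrast (it pools all three post-intervention samples instead of
    betting on a single time point).
    """
    wide = panel.frame.pivot_table(index="participant_id", columns="stage",
                                   values="nmol_per_l")
    missing = [s for s in ("baseline", "sound", "rest1", "rest2")
               if s not in wide.columns]
    if missing:
        raise ValidationError(f"panel lacks stages {missing}")
    return wide[["sound", "rest1", "rest2"]].mean(axis=1) - wide["baseline"]


#: chronological rank of each possible return stage; no-return sorts last
RETURN_ORDER = {"sound": 0, "rest1": 1, "rest2": 2, None: 3}


def group_return_rank(panel: CortisolPanel, group: str | tuple,
                      tolerance_fraction: float = DEFAULT_TOLERANCE,
                      minutes: dict[str, float] | None = None) -> float:
    """Median per-participant baseline-return rank of one or more groups.

    Each participant's earliest return stage is mapped to its chronological
    rank (no return sorts after every stage); the group's recovery timing is
    the median rank, which is robust to individual assay noise.  Lower means
    earlier recovery.  ``group`` may be a tuple to pool groups (e.g. both
    control conditions).
    """
    wanted = (group,) if isinstance(group, str) else tuple(group)
    ranks = [RETURN_ORDER[baseline_return(t, tolerance_fraction)]
             for t in trajectories_from_panel(panel, minutes=minutes)
             if t.group in wanted]
    if not ranks:
        raise ValidationError(f"no participants in groups {wanted}")
    return float(np.median(ranks))


def group_mean_trajectory(panel: CortisolPanel, group: str,
                          minutes: dict[str, float] | None = None,
                          ) -> CortisolTrajectory:
    """Stage-wise mean trajectory of one experimental group."""
    minutes = minutes or DEFAULT_MINUTES
    rows = panel.frame[panel.frame["group"] == group]
    if rows.empty:
        raise ValidationError(f"no participants in group {group!r}")
    samples = []
    for stage in CORTISOL_STAGES:
        sel = rows[rows["stage"] == stage]
        if sel.empty:
            continue
        samples.append((stage, minutes[stage],
                        float(sel["nmol_per_l"].mean())))
    samples.sort(key=lambda s: s[1])
    return CortisolTrajectory(participant_id=f"group:{group}", group=group,
                              samples=tuple(samples))
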