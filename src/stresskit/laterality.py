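"""Laterality Index Response (LIR) over right/left prefrontal channel pairs.

``LIR = (R - L) / (R + L)`` over paired region dOHb stage means; positive
values indicate right-dominant prefrontal activity.  Because band-passed
stage means can be negative, the verbatim ratio is unbounded; the default
"rectified" mode first shifts each channel's stage means by that channel's
minimum across stages (activities then >= 0 and the index lies in [-1, 1]),
while "raw" mode applies the ratio verbatim.  Whenever |R + L| falls below
the degeneracy floor the index is undefined and reported as NaN -- never
silently zero -- which downstream statistics treat as a missing value.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, ParameterError
from .fnirs import HemoStageSummary
from .io_formats import Montage

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-9
MODES = ("rectified", "raw")


def compute_lir(right_activity: float, left_activity: float,
                floor: float = DEFAULT_FLOOR) -> float:
    """(R - L) / (R + L); NaN when |R + L| < floor (undefined, not 0)."""
    s = right_activity + left_activity
    if abs(s) < floor:
        return float("nan")
    return (right_activity - left_activity) / s


def _rectify(stage_values: dict[str, float]) -> dict[str, float]:
    """Shift a channel's stage means by its minimum across stages (>= 0)."""
    m = min(stage_values.values())
    return {s: max(v - m, 0.0) for s, v in stage_values.items()}


def lir_table(summaries: Sequence[HemoStageSummary],
              pairs: Iterable[tuple[str, str]],
              mode: str = "rectified",
              floor: float = DEFAULT_FLOOR,
              montage: Montage | None = None) -> pd.DataFrame:
    """One LIR row per (participant, pair, stage) from dOHb stage means.

    Pairs whose right or left member was rejected for a participant are
    skipped for that participant and logged.  Columns: participant_id,
    right_channel, left_channel, stage_label, right_activity, left_activity,
    lir.
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    pairs = list(pairs)
    if montage is not None:
        known = set(montage.channel_ids)
        for r, l in pairs:
            bad = [c for c in (r, l) if c not in known]
            if bad:
                raise ConfigError(
                    f"laterality pair ({r}, {l}) references unknown "
                    f"channels: {bad}"
                )

    # (participant, channel) -> stage -> mean dOHb
    activity: dict[tuple[str, str], dict[str, float]] = {}
    for s in summaries:
        activity.setdefault((s.participant_id, s.channel_id), {})[
            s.stage_label] = s.mean_delta_ohb

    participants = sorted({s.participant_id for s in summaries})
    rows = []
    for pid in participants:
        for right_id, left_id in pairs:
            r_act = activity.get((pid, right_id))
            l_act = activity.get((pid, left_id))
            if r_act is None or l_act is None:
                missing = [c for c, a in ((right_id, r_act), (left_id, l_act))
                           if a is None]
                logger.info("participant %s: pair (%s, %s) skipped, "
                            "rejected channel(s) %s", pid, right_id, left_id,
                            missing)
                continue
            stages = [s for s in r_act if s in l_act]
            if mode == "rectified":
                r_use = _rectify({s: r_act[s] for s in stages})
                l_use = _rectify({s: l_act[s] for s in stages})
            else:
                r_use = {s: r_act[s] for s in stages}
                l_use = {s: l_act[s] for s in stages}
            for stage in stages:
                rows.append({
                    "participant_id": pid,
                    "right_channel": right_id,
                    "left_channel": left_id,
                    "stage_label": stage,
                    "right_activity": r_use[stage],
                    "left_activity": l_use[stage],
                    "lir": compute_lir(r_use[stage], l_use[stage],
                                       floor=floor),
                })
    return pd.DataFrame(rows, columns=[
        "participant_id", "right_channel", "left_channel", "stage_label",
        "right_activity", "left_activity", "lir"])
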