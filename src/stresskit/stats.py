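"""The stage-by-group statistical battery.

Variance homogeneity (Levene, median-centered), paired and independent
two-sided t-tests with Cohen's d, and a mixed repeated-measures ANOVA (one
between-subjects factor "group", one within-subjects factor "stage") with
partial eta-squared effect sizes.  ``run_battery`` applies a declarative
analysis plan to the cohort's stage summaries, LIR table and cortisol panel
and emits one tidy :class:`~stresskit.io_formats.StatsResult` per comparison.

The mixed ANOVA is implemented from its sums-of-squares decomposition so
that the additivity of the partition can be asserted directly:

    SS_total = SS_group + SS_subjects_within_groups
               + SS_stage + SS_interaction + SS_error_within

F_group      = MS_group / MS_subjects_within_groups
F_stage      = MS_stage / MS_error_within
F_interact   = MS_interaction / MS_error_within

Sphericity is not corrected by default; a Greenhouse-Geisser flag applies
the epsilon correction to the within-factor degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, ValidationError
from .io_formats import CortisolPanel, Montage, StatsResult
from .eda import EDAStageSummary
from .fnirs import HemoStageSummary

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def levene(samples: Sequence[np.ndarray], measure: str = "",
           center: str = "median", **context) -> StatsResult:
    """Levene's variance-homogeneity test (median-centered by default)."""
    if len(samples) < 2:
        raise ValidationError("Levene's test needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in samples]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"Levene group {i} has n < 2")
    w, p = scipy.stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(g.size for g in arrays)
    return StatsResult(
        test="levene", measure=measure, statistic=float(w),
        df=float(k - 1), df2=float(n - k), p=float(p),
        effect_size=float("nan"), effect_size_kind="none", **context)


def cohens_d_paired(diff: np.ndarray) -> float:
    """mean(diff) / sd(diff), sample sd with ddof=1."""
    sd = np.std(diff, ddof=1)
    if sd == 0:
        raise ValidationError("degenerate contrast: zero-variance difference")
    return float(np.mean(diff) / sd)


def cohens_d_independent(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-standard-deviation standardized mean difference (a minus b)."""
    na, nb = a.size, b.size
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2)
    if sp2 == 0:
        raise ValidationError("degenerate contrast: zero pooled variance")
    return float((np.mean(a) - np.mean(b)) / math.sqrt(sp2))


def paired_t(x: np.ndarray, y: np.ndarray, measure: str = "",
             **context) -> StatsResult:
    """Two-sided paired t-test; x = y gives t = 0, d = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples must have equal length")
    if x.size < 2:
        raise ValidationError("paired t-test needs n >= 2")
    diff = x - y
    if np.allclose(diff, diff[0]) and np.all(diff == 0):
        # identical samples: t = 0, p = 1 (scipy returns NaN here)
        return StatsResult(test="paired_t", measure=measure, statistic=0.0,
                           df=float(x.size - 1), p=1.0, effect_size=0.0,
                           effect_size_kind="cohen_d", **context)
    d = cohens_d_paired(diff)
    t, p = scipy.stats.ttest_rel(x, y)
    return StatsResult(test="paired_t", measure=measure, statistic=float(t),
                       df=float(x.size - 1), p=float(p), effect_size=d,
                       effect_size_kind="cohen_d", **context)


def independent_t(a: np.ndarray, b: np.ndarray, measure: str = "",
                  **context) -> StatsResult:
    """Two-sided independent-samples t-test with pooled-sd Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("independent t-test needs n >= 2 per group")
    d = cohens_d_independent(a, b)
    t, p = scipy.stats.ttest_ind(a, b)
    return StatsResult(test="independent_t", measure=measure,
                       statistic=float(t), df=float(a.size + b.size - 2),
                       p=float(p), effect_size=d,
                       effect_size_kind="cohen_d", **context)


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaDecomposition:
    """Full sums-of-squares partition of the mixed design."""

    ss_total: float
    ss_group: float
    ss_subjects_within: float
    ss_stage: float
    ss_interaction: float
    ss_error_within: float
    df_group: int
    df_subjects_within: int
    df_stage: int
    df_interaction: int
    df_error_within: int
    n_subjects: int
    n_stages: int
    n_groups: int
    gg_epsilon: float


def _pivot_rm(data: pd.DataFrame, subject: str, within: str, between: str,
              value: str) -> tuple[np.ndarray, np.ndarray, list]:
    wide = data.pivot_table(index=subject, columns=within, values=value,
                            aggfunc="first", sort=True)
    missing = [(pid, stage)
               for pid in wide.index for stage in wide.columns
               if pd.isna(wide.loc[pid, stage])]
    if missing:
        raise ValidationError(
            f"unbalanced within factor; missing cells: {missing}"
        )
    grp_map = data.drop_duplicates(subject).set_index(subject)[between]
    groups = grp_map.reindex(wide.index).to_numpy()
    return wide.to_numpy(dtype=float), groups, list(wide.columns)


def _gg_epsilon(vals: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance."""
    s = vals.shape[1]
    if s < 3:
        return 1.0
    cov = np.cov(vals, rowvar=False)
    mean_diag = np.trace(cov) / s
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (s * (mean_diag - mean_all)) ** 2
    den = (s - 1) * (np.sum(cov ** 2) - 2 * s * np.sum(row_means ** 2)
                     + s ** 2 * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (s - 1))))


def anova_decomposition(data: pd.DataFrame, subject: str = "participant_id",
                        within: str = "stage", between: str = "group",
                        value: str = "value") -> AnovaDecomposition:
    """Sums of squares and degrees of freedom of the mixed design."""
    vals, groups, _stages = _pivot_rm(data, subject, within, between, value)
    n, s = vals.shape
    if s < 2:
        raise ValidationError("need at least 2 within-factor levels")
    ug = list(dict.fromkeys(groups))
    g = len(ug)
    grand = vals.mean()
    subj_means = vals.mean(axis=1)
    ss_total = float(((vals - grand) ** 2).sum())
    ss_subjects = float(s * ((subj_means - grand) ** 2).sum())
    ss_group = float(sum(
        s * (groups == grp).sum() * (vals[groups == grp].mean() - grand) ** 2
        for grp in ug))
    ss_sw = ss_subjects - ss_group
    stage_means = vals.mean(axis=0)
    ss_stage = float((n * (stage_means - grand) ** 2).sum())
    ss_int = 0.0
    for grp in ug:
        cell = vals[groups == grp]
        for j in range(s):
            ss_int += cell.shape[0] * (
                cell[:, j].mean() - cell.mean() - stage_means[j] + grand) ** 2
    ss_err = ss_total - ss_subjects - ss_stage - ss_int
    return AnovaDecomposition(
        ss_total=ss_total, ss_group=ss_group, ss_subjects_within=ss_sw,
        ss_stage=ss_stage, ss_interaction=float(ss_int),
        ss_error_within=float(ss_err),
        df_group=g - 1, df_subjects_within=n - g, df_stage=s - 1,
        df_interaction=(g - 1) * (s - 1), df_error_within=(n - g) * (s - 1),
        n_subjects=n, n_stages=s, n_groups=g,
        gg_epsilon=_gg_epsilon(vals))


def rm_anova(data: pd.DataFrame, subject: str = "participant_id",
             within: str = "stage", between: str = "group",
             value: str = "value", measure: str = "",
             effect_size: str = "partial_eta_sq",
             greenhouse_geisser: bool = False,
             **context) -> list[StatsResult]:
    """Mixed repeated-measures ANOVA.

    Returns the within (stage) effect, and -- when more than one group is
    present -- the between (group) effect and the interaction.  Effect sizes
    are partial eta-squared by default (classical ``eta_sq`` available).
    Every subject must have every stage; a missing cell raises listing the
    (subject, stage) pairs.
    """
    if effect_size not in ("partial_eta_sq", "eta_sq"):
        raise ValidationError(f"unknown effect size {effect_size!r}")
    dec = anova_decomposition(data, subject, within, between, value)

    def eta(ss_effect: float, ss_error: float) -> float:
        if effect_size == "partial_eta_sq":
            denom = ss_effect + ss_error
        else:
            denom = dec.ss_total
        return ss_effect / denom if denom > 0 else 0.0

    eps = dec.gg_epsilon if greenhouse_geisser else 1.0
    results = []

    def f_result(effect: str, ss_e: float, df_e: float, ss_r: float,
                 df_r: float, corr: float = 1.0) -> StatsResult:
        ms_e = ss_e / df_e
        ms_r = ss_r / df_r
        f = ms_e / ms_r if ms_r > 0 else 0.0
        p = (float(scipy.stats.f.sf(f, df_e * corr, df_r * corr))
             if ms_r > 0 else 1.0)
        return StatsResult(
            test="rm_anova", measure=measure, effect=effect,
            statistic=float(f), df=float(df_e * corr),
            df2=float(df_r * corr), p=p,
            effect_size=float(eta(ss_e, ss_r)),
            effect_size_kind=effect_size, **context)

    results.append(f_result("stage", dec.ss_stage, dec.df_stage,
                            dec.ss_error_within, dec.df_error_within,
                            corr=eps))
    if dec.n_groups > 1:
        results.append(f_result("group", dec.ss_group, dec.df_group,
                                dec.ss_subjects_within,
                                dec.df_subjects_within))
        results.append(f_result("interaction", dec.ss_interaction,
                                dec.df_interaction, dec.ss_error_within,
                                dec.df_error_within, corr=eps))
    return results


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# Analysis plan / battery
# ---------------------------------------------------------------------------

GROUP_CONTRASTS = (("soothing", "silence"), ("soothing", "robotic"),
                   ("robotic", "silence"))


def default_plan(montage: Montage) -> list[dict]:
    """The comparisons mirroring the published result tables.

    Cortisol: 3x2 and 3x3 mixed ANOVAs plus a Levene check at the stress
    stage.  EDA: 3x5 mixed ANOVA.  Haemodynamics: per-channel paired t-tests
    baseline vs stress and per-channel between-group t-tests at the sound
    stage.  LIR: per-pair paired t-tests baseline vs stress and between-group
    t-tests at the sound stage.
    """
    plan: list[dict] = [
        {"measure": "cortisol", "test": "levene", "stage": "stress"},
        {"measure": "cortisol", "test": "rm_anova",
         "stages": ["baseline", "stress"]},
        {"measure": "cortisol", "test": "rm_anova",
         "stages": ["baseline", "stress", "sound"]},
        {"measure": "eda", "test": "rm_anova",
         "stages": ["baseline", "stress", "sound", "rest1", "rest2"]},
    ]
    for hb in ("hbo", "hhb"):
        plan.append({"measure": hb, "test": "paired_t", "channels": "all",
                     "stages": ["stress", "baseline"]})
        for ga, gb in GROUP_CONTRASTS:
            plan.append({"measure": hb, "test": "independent_t",
                         "channels": "all", "stage": "sound",
                         "groups": [ga, gb]})
    plan.append({"measure": "lir", "test": "paired_t", "pairs": "all",
                 "stages": ["stress", "baseline"]})
    for ga, gb in GROUP_CONTRASTS:
        plan.append({"measure": "lir", "test": "independent_t",
                     "pairs": "all", "stage": "sound", "groups": [ga, gb]})
    return plan


def _hemo_frame(summaries: Sequence[HemoStageSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": s.participant_id, "channel_id": s.channel_id,
        "stage_label": s.stage_label, "hbo": s.mean_delta_ohb,
        "hhb": s.mean_delta_hhb} for s in summaries])


def _eda_frame(summaries: Sequence[EDAStageSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": s.participant_id, "stage_label": s.stage_label,
        "value": s.tonic_mean} for s in summaries])


def _paired_stage_values(frame: pd.DataFrame, value_col: str,
                         stage_a: str, stage_b: str,
                         ) -> tuple[np.ndarray, np.ndarray]:
    wide = frame.pivot_table(index="participant_id", columns="stage_label",
                             values=value_col, aggfunc="first")
    wide = wide.dropna(subset=[stage_a, stage_b])
    return wide[stage_a].to_numpy(), wide[stage_b].to_numpy()


def run_battery(cortisol_panel: CortisolPanel | None = None,
                eda_summaries: Sequence[EDAStageSummary] = (),
                hemo_summaries: Sequence[HemoStageSummary] = (),
                lir_frame: pd.DataFrame | None = None,
                groups: Mapping[str, str] | None = None,
                montage: Montage | None = None,
                plan: Sequence[dict] | None = None,
                alpha: float = DEFAULT_ALPHA,
                fdr: bool = False) -> list[StatsResult]:
    """Run every planned comparison and flag significance at ``alpha``.

    ``groups`` maps participant ids to experimental groups and is required
    for any between-group comparison; ``montage`` annotates per-channel rows
    with hemisphere and Brodmann area.  An empty plan yields empty results.
    """
    if plan is None:
        if montage is None:
            raise ConfigError("default plan needs a montage")
        plan = default_plan(montage)
    groups = dict(groups or {})
    hemo = _hemo_frame(hemo_summaries) if hemo_summaries else pd.DataFrame()
    eda = _eda_frame(eda_summaries) if eda_summaries else pd.DataFrame()
    results: list[StatsResult] = []

    def channel_context(cid: str) -> dict:
        if montage is None:
            return {"channel": cid}
        ch = montage.channel(cid)
        return {"channel": cid, "hemisphere": ch.hemisphere,
                "brodmann_area": ch.brodmann_area}

    def group_of_frame(frame: pd.DataFrame) -> pd.Series:
        missing = [p for p in frame["participant_id"].unique()
                   if p not in groups]
        if missing:
            raise ConfigError(f"no group assignment for participants "
                              f"{missing}")
        return frame["participant_id"].map(groups)

    for item in plan:
        measure = item["measure"]
        test = item["test"]

        if measure == "cortisol":
            if cortisol_panel is None:
                raise ConfigError("plan references cortisol but no panel given")
            cframe = cortisol_panel.frame.rename(
                columns={"stage": "stage_label", "nmol_per_l": "value"})
            if test == "levene":
                stage = item["stage"]
                sel = cframe[cframe["stage_label"] == stage]
                samples = [sel[sel["group"] == g]["value"].to_numpy()
                           for g in sel["group"].unique()]
                results.append(levene(samples, measure="cortisol",
                                      stages=(stage,),
                                      groups=tuple(sel["group"].unique())))
            elif test == "rm_anova":
                stages = item["stages"]
                sel = cframe[cframe["stage_label"].isin(stages)]
                results.extend(rm_anova(
                    sel.rename(columns={"stage_label": "stage"}),
                    measure="cortisol", stages=tuple(stages),
                    groups=tuple(sorted(sel["group"].unique()))))
            else:
                raise ConfigError(f"unsupported cortisol test {test!r}")

        elif measure == "eda":
            if eda.empty:
                raise ConfigError("plan references EDA but no summaries given")
            stages = item["stages"]
            sel = eda[eda["stage_label"].isin(stages)].copy()
            sel["group"] = group_of_frame(sel)
            results.extend(rm_anova(
                sel.rename(columns={"stage_label": "stage"}),
                measure="eda", stages=tuple(stages),
                groups=tuple(sorted(sel["group"].unique()))))

        elif measure in ("hbo", "hhb"):
            if hemo.empty:
                raise ConfigError(f"plan references {measure} but no "
                                  f"haemodynamic summaries given")
            channels = item.get("channels", "all")
            if channels == "all":
                channels = sorted(hemo["channel_id"].unique())
            else:
                known = set(hemo["channel_id"].unique())
                if montage is not None:
                    known |= set(montage.channel_ids)
                bad = [c for c in channels if c not in known]
                if bad:
                    raise ConfigError(f"plan references absent channels {bad}")
            for cid in channels:
                sub = hemo[hemo["channel_id"] == cid]
                if sub.empty:
                    continue
                try:
                    if test == "paired_t":
                        sa, sb = item["stages"]
                        x, y = _paired_stage_values(sub, measure, sa, sb)
                        if x.size < 2:
                            continue
                        results.append(paired_t(
                            x, y, measure=measure, stages=(sa, sb),
                            **channel_context(cid)))
                    elif test == "independent_t":
                        stage = item["stage"]
                        ga, gb = item["groups"]
                        sel = sub[sub["stage_label"] == stage].copy()
                        sel["group"] = group_of_frame(sel)
                        a = sel[sel["group"] == ga][measure].to_numpy()
                        b = sel[sel["group"] == gb][measure].to_numpy()
                        if a.size < 2 or b.size < 2:
                            continue
                        results.append(independent_t(
                            a, b, measure=measure, stages=(stage,),
                            groups=(ga, gb), **channel_context(cid)))
                    else:
                        raise ConfigError(
                            f"unsupported {measure} test {test!r}")
                except ValidationError:
                    continue  # degenerate contrast on this channel

        elif measure == "lir":
            if lir_frame is None or lir_frame.empty:
                raise ConfigError("plan references LIR but no table given")
            pairs = item.get("pairs", "all")
            table = lir_frame.dropna(subset=["lir"])
            all_pairs = sorted(set(zip(table["right_channel"],
                                       table["left_channel"])))
            if pairs != "all":
                bad = [p for p in pairs if tuple(p) not in set(all_pairs)]
                if bad and montage is not None:
                    known = set(montage.pairs)
                    bad = [p for p in bad if tuple(p) not in known]
                if bad:
                    raise ConfigError(f"plan references unknown pairs {bad}")
                all_pairs = [tuple(p) for p in pairs]
            for right_id, left_id in all_pairs:
                sub = table[(table["right_channel"] == right_id)
                            & (table["left_channel"] == left_id)]
                sub = sub.rename(columns={"lir": "value"})
                try:
                    if test == "paired_t":
                        sa, sb = item["stages"]
                        x, y = _paired_stage_values(sub, "value", sa, sb)
                        if x.size < 2:
                            continue
                        results.append(paired_t(
                            x, y, measure="lir", stages=(sa, sb),
                            pair=(right_id, left_id)))
                    elif test == "independent_t":
                        stage = item["stage"]
                        ga, gb = item["groups"]
                        sel = sub[sub["stage_label"] == stage].copy()
                        sel["group"] = group_of_frame(sel)
                        a = sel[sel["group"] == ga]["value"].to_numpy()
                        b = sel[sel["group"] == gb]["value"].to_numpy()
                        if a.size < 2 or b.size < 2:
                            continue
                        results.append(independent_t(
                            a, b, measure="lir", stages=(stage,),
                            groups=(ga, gb), pair=(right_id, left_id)))
                    else:
                        raise ConfigError(f"unsupported lir test {test!r}")
                except ValidationError:
                    continue

        else:
            raise ConfigError(f"unknown measure {measure!r} in plan")

    for r in results:
        r.significant = bool(r.p < alpha)
    if fdr and results:
        adjusted = bh_fdr([r.p for r in results])
        for r, q in zip(results, adjusted):
            r.significant = bool(q < alpha)
    return results
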