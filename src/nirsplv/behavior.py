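"""Behavioral analyses of the selection log.

Two measures per participant and condition: the time spent selecting a
product (response time per stimulus screen, 30 selections per
condition) and the frequency of choosing one of the lower-priced
options (count out of 30).

Response times: each participant gets a two-sample t over their 30 OOC
vs 30 SOC selection RTs (the per-participant difference table), and
the group-level test is a paired t on per-subject mean RTs. Low-price
frequency: counts per subject/condition with a group paired t; the
summary table reports mean, sd and ratio = mean/30·100 per condition.
A "selection-slot" mode additionally pairs the 30 selection slots
(proportions averaged over subjects, df = 29) for comparability with
analyses run over selection slots rather than subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import DataError, DegenerateInputError
from .stats import StatResult, paired_ttest

logger = logging.getLogger(__name__)

CONDITIONS = ("OOC", "SOC")


@dataclass
class BehaviorSummary:
    """Per-subject tables plus the group-level paired test."""

    per_subject: pd.DataFrame
    group: StatResult
    condition_summary: pd.DataFrame | None = None
    slot_group: StatResult | None = None

    def summary(self) -> str:
        parts = []
        if self.condition_summary is not None:
            parts.append(self.condition_summary.to_string())
        g = self.group
        parts.append(
            f"group paired t({g.df}) = {g.t:.3f}, p = {g.p_raw:.4g}, dz = {g.dz:.3f}"
        )
        if self.slot_group is not None:
            s = self.slot_group
            parts.append(
                f"selection-slot mode: t({s.df}) = {s.t:.3f}, p = {s.p_raw:.4g}"
            )
        return "\n".join(parts)


def _complete_subjects(records: pd.DataFrame, min_per_condition: int = 2) -> list:
    keep = []
    for subject, grp in records.groupby("subject"):
        counts = grp.groupby("condition").size()
        if all(counts.get(c, 0) >= min_per_condition for c in CONDITIONS):
            keep.append(subject)
        else:
            logger.warning("subject %s skipped: missing condition data", subject)
    return keep


def rt_contrast(records: pd.DataFrame, alpha: float = 0.05) -> BehaviorSummary:
    """Response-time contrast (OOC − SOC).

    ``per_subject`` columns: mean RT per condition, ``rt_diff_ms``,
    per-subject two-sample t/p over the individual selections and a
    significance flag at ``alpha``.
    """
    rows = []
    for subject in _complete_subjects(records):
        grp = records[records["subject"] == subject]
        rts = {c: grp.loc[grp["condition"] == c, "rt_ms"].to_numpy() for c in CONDITIONS}
        t, p = sst.ttest_ind(rts["OOC"], rts["SOC"])
        rows.append(
            {
                "subject": subject,
                "mean_rt_OOC_ms": rts["OOC"].mean(),
                "mean_rt_SOC_ms": rts["SOC"].mean(),
                "rt_diff_ms": rts["OOC"].mean() - rts["SOC"].mean(),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    if len(rows) < 2:
        raise DegenerateInputError("need at least 2 complete subjects")
    per_subject = pd.DataFrame(rows)
    group = paired_ttest(
        per_subject["mean_rt_OOC_ms"].to_numpy(),
        per_subject["mean_rt_SOC_ms"].to_numpy(),
        unit="mean_rt",
    )
    return BehaviorSummary(per_subject=per_subject, group=group)


def low_price_contrast(records: pd.DataFrame) -> BehaviorSummary:
    """Low-price selection-frequency contrast.

    Counts low-price selections per subject and condition (0..30 for
    complete data), tests the group with a paired t over subjects, and
    reports the per-condition mean/sd/ratio table. Also runs the
    selection-slot variant (pairing the 30 trial×screen slots on
    subject-averaged proportions, df = n_slots − 1).
    """
    if records["price_tier"].isna().any() or not set(records["price_tier"]) <= {
        "low",
        "high",
    }:
        raise DataError("every record needs a price_tier label of 'low' or 'high'")
    subjects = _complete_subjects(records)
    rows = []
    for subject in subjects:
        grp = records[records["subject"] == subject]
        counts = {
            c: int((grp.loc[grp["condition"] == c, "price_tier"] == "low").sum())
            for c in CONDITIONS
        }
        n_sel = {c: int((grp["condition"] == c).sum()) for c in CONDITIONS}
        rows.append(
            {
                "subject": subject,
                "low_count_OOC": counts["OOC"],
                "low_count_SOC": counts["SOC"],
                "n_OOC": n_sel["OOC"],
                "n_SOC": n_sel["SOC"],
            }
        )
    if len(rows) < 2:
        raise DegenerateInputError("need at least 2 complete subjects")
    per_subject = pd.DataFrame(rows)
    group = paired_ttest(
        per_subject["low_count_OOC"].to_numpy(dtype=float),
        per_subject["low_count_SOC"].to_numpy(dtype=float),
        unit="low_price_count",
    )
    n_per = per_subject[["n_OOC", "n_SOC"]].to_numpy().max()
    condition_summary = pd.DataFrame(
        {
            "n_selections": [n_per, n_per],
            "mean": [
                per_subject["low_count_OOC"].mean(),
                per_subject["low_count_SOC"].mean(),
            ],
            "sd": [
                per_subject["low_count_OOC"].std(ddof=1),
                per_subject["low_count_SOC"].std(ddof=1),
            ],
        },
        index=pd.Index(CONDITIONS, name="condition"),
    )
    condition_summary["ratio_pct"] = condition_summary["mean"] / n_per * 100.0

    # selection-slot mode: one paired observation per (trial, screen) slot
    slot = (
        records.assign(low=(records["price_tier"] == "low").astype(float))
        .groupby(["condition", "trial", "screen"])["low"]
        .mean()
        .unstack("condition")
    )
    slot_group = None
    if len(slot) >= 2 and not slot[list(CONDITIONS)].isna().any().any():
        slot_group = paired_ttest(
            slot["OOC"].to_numpy(), slot["SOC"].to_numpy(), unit="low_price_slot"
        )
    return BehaviorSummary(
        per_subject=per_subject,
        group=group,
        condition_summary=condition_summary,
        slot_group=slot_group,
    )
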