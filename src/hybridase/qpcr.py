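"""Relative expression by the Livak 2^-ddCt method.

Per sample, dCt = mean Ct(target) - mean Ct(reference); ddCt subtracts the
calibrator group's mean dCt; the fold is 2^-ddCt.  Amplification
efficiency is fixed at 2 (no standard curves).  Technical replicates are
averaged within a sample before dCt.  Group comparisons are a one-way
ANOVA with Tukey HSD on log2 folds, rendered as a compact letter display.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


@dataclass
class RelativeExpression:
    """Per-sample folds and group summaries, calibrated to one group.

    ``per_sample`` has columns ``sample_id, group, dct, ddct, fold``;
    ``group_stats`` has ``group, n, mean_fold, sd_fold, letter``.  Groups
    sharing a letter are not significantly different (Tukey HSD at the
    chosen alpha on log2 folds).  All folds are positive; the calibrator
    group's mean fold is 1 on noiseless data.
    """

    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    calibrator: str
    alpha: float
    anova_pvalue: float | None = None
    pairwise: pd.DataFrame | None = None

    def group_mean(self, group: str) -> float:
        sub = self.group_stats.loc[self.group_stats["group"] == group, "mean_fold"]
        if sub.empty:
            raise ValueError(f"group {group!r} absent from expression summary")
        return float(sub.iloc[0])

    def sample_folds(self, group: str) -> np.ndarray:
        sub = self.per_sample.loc[self.per_sample["group"] == group, "fold"]
        if sub.empty:
            raise ValueError(f"group {group!r} absent from expression table")
        return sub.to_numpy(dtype=float)


def _compact_letters(groups: list[str], nonsig: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significance
    graph (brute force; group counts here are single digits)."""
    n = len(groups)
    cliques: list[set[str]] = []
    for mask in range(1, 1 << n):
        members = {groups[i] for i in range(n) if mask >> i & 1}
        if all(
            frozenset((a, b)) in nonsig
            for a in members
            for b in members
            if a < b
        ):
            cliques.append(members)
    maximal = [
        c for c in cliques if not any(c < d for d in cliques)
    ]
    maximal.sort(key=lambda c: min(groups.index(g) for g in c))
    letters: dict[str, str] = {g: "" for g in groups}
    for k, clique in enumerate(maximal):
        ch = chr(ord("a") + k)
        for g in clique:
            letters[g] += ch
    return letters


def ddct(
    table: pd.DataFrame,
    calibrator: str,
    target: str = "p38",
    reference: str = "beta_actin",
    alpha: float = 0.05,
) -> RelativeExpression:
    """Compute 2^-ddCt relative expression calibrated to one group.

    Samples missing the reference gene are excluded with a logged warning.
    With fewer than two groups (or fewer than two samples per group) the
    summary is returned without significance tests.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    genes = set(table["gene"])
    for gene in (target, reference):
        if gene not in genes:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    if calibrator not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator!r} absent from Ct table")

    # technical replicates average within (sample, gene)
    mean_ct = (
        table.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    lacking = mean_ct[mean_ct[reference].isna() | mean_ct[target].isna()]
    for sid in lacking["sample_id"]:
        log.warning("sample %s lacks target or reference Ct; excluded", sid)
    mean_ct = mean_ct.dropna(subset=[target, reference])
    if mean_ct.empty:
        raise ValueError("no sample carries both target and reference genes")

    per = mean_ct[["sample_id", "group"]].copy()
    per["dct"] = mean_ct[target] - mean_ct[reference]
    cal_mean = per.loc[per["group"] == calibrator, "dct"].mean()
    per["ddct"] = per["dct"] - cal_mean
    per["fold"] = np.exp2(-per["ddct"])

    stats_df = (
        per.groupby("group", sort=False)["fold"]
        .agg(n="count", mean_fold="mean", sd_fold=lambda x: x.std(ddof=1))
        .reset_index()
    )

    anova_p = None
    pairwise = None
    letters = {g: "a" for g in stats_df["group"]}
    groups = list(stats_df["group"])
    samples = [np.log2(per.loc[per["group"] == g, "fold"].to_numpy()) for g in groups]
    if len(groups) >= 2 and all(len(s) >= 2 for s in samples):
        # zero within-group variance (noiseless data) makes the test
        # statistics degenerate: identical means then carry p = 1, distinct
        # means p = 0, which is the limiting behaviour we want
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p = float(stats.f_oneway(*samples).pvalue)
            tk = stats.tukey_hsd(*samples)
        if math.isnan(anova_p):
            anova_p = 1.0
        rows = []
        nonsig: set[frozenset[str]] = set()
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p = float(tk.pvalue[i, j])
                if math.isnan(p):
                    p = 1.0
                rows.append({"group1": groups[i], "group2": groups[j], "pvalue": p})
                if p >= alpha:
                    nonsig.add(frozenset((groups[i], groups[j])))
        pairwise = pd.DataFrame(rows)
        order = sorted(groups, key=lambda g: -stats_df.set_index("group").loc[g, "mean_fold"])
        letters = _compact_letters(order, nonsig)
    stats_df["letter"] = stats_df["group"].map(letters)

    return RelativeExpression(
        per_sample=per,
        group_stats=stats_df,
        calibrator=calibrator,
        alpha=alpha,
        anova_pvalue=anova_p,
        pairwise=pairwise,
    )


def parental_divergence_A(
    rel: RelativeExpression, p1: str, p2: str
) -> float:
    """Combined cis+trans effect: A = log2(mean fold p1 / mean fold p2).

    This is the total expression divergence between the parental lines on
    the log2 scale, handed to the cis/trans decomposition.
    """
    m1, m2 = rel.group_mean(p1), rel.group_mean(p2)
    return math.log2(m1 / m2)
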