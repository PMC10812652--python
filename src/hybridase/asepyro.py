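"""Allele-specific expression from pyrosequencing counts.

In an F1 hybrid both parental alleles share one trans-acting environment,
so the log2 ratio of the two allelic transcript counts at a marker SNP
isolates the cis-regulatory effect, B = log2(n_P1 / n_P2).  The bias test
is the exact two-sided binomial test against 0.5 (the sum of outcome
probabilities no larger than the observed one), and the interval is the
Clopper-Pearson 95% CI -- counts can be small, so no normal approximation
is used anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "marker", "count_p1", "count_p2")


@dataclass(frozen=True)
class ASEResult:
    """Pooled allelic frequency and the derived cis effect.

    ``cis_effect_B`` equals ``log2(freq_p1 / (1 - freq_p1))`` when computed
    from the pooled frequency; a 0.5-read continuity correction is applied
    (and flagged) when either pooled allele count is zero, so the effect is
    never silently infinite.
    """

    freq_p1: float
    ci_low: float
    ci_high: float
    cis_effect_B: float
    pvalue_bias: float
    n_individuals: int
    total_reads: float
    pooling: str
    continuity_corrected: bool = False


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele count table lacks columns {missing}")
    if table.empty:
        raise ValueError("allele count table is empty")
    if table["marker"].nunique() != 1:
        raise ValueError("all rows must refer to the same marker SNP")
    c1 = table["count_p1"].to_numpy(dtype=float)
    c2 = table["count_p2"].to_numpy(dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("allele counts must be non-negative")
    if ((c1 + c2) < 1).any():
        raise ValueError("each retained row needs at least one read")
    return table


def estimate_ase(table: pd.DataFrame, pooling: str = "pooled") -> ASEResult:
    """Estimate the parent-1 allele frequency and cis effect at a marker.

    Parameters
    ----------
    table:
        Columns ``individual_id, marker, count_p1, count_p2`` (one row per
        individual).  Counts are normally integers; fractional expected
        counts from a noiseless forward simulation are accepted, in which
        case the binomial p-value and CI are computed on rounded totals.
    pooling:
        ``"pooled"`` (default) sums counts across individuals before
        computing the frequency -- this is the estimate a single pooled
        assay ratio corresponds to.  ``"per-individual-mean"`` averages
        per-individual frequencies and maps the mean through the odds
        transform; its p-value is a one-sample t test of the per-individual
        frequencies against 0.5.
    """
    table = _validate(table)
    c1 = table["count_p1"].to_numpy(dtype=float)
    c2 = table["count_p2"].to_numpy(dtype=float)
    n_ind = len(table)

    if pooling == "pooled":
        k, m = float(c1.sum()), float(c2.sum())
        total = k + m
        freq = k / total
        ki, ni = int(round(k)), int(round(k + m))
        bt = stats.binomtest(ki, ni, 0.5)
        ci = bt.proportion_ci(confidence_level=0.95, method="exact")
        corrected = k == 0 or m == 0
        if corrected:
            log.warning("zero pooled count on one allele; applying 0.5-read "
                        "continuity correction to the cis effect")
            b = math.log2((k + 0.5) / (m + 0.5))
        else:
            b = math.log2(k / m)
        return ASEResult(
            freq_p1=freq,
            ci_low=ci.low,
            ci_high=ci.high,
            cis_effect_B=b,
            pvalue_bias=bt.pvalue,
            n_individuals=n_ind,
            total_reads=total,
            pooling=pooling,
            continuity_corrected=corrected,
        )

    if pooling in ("per-individual-mean", "mean"):
        freqs = c1 / (c1 + c2)
        fbar = float(freqs.mean())
        corrected = fbar in (0.0, 1.0)
        if corrected:
            total = float((c1 + c2).sum())
            fbar_adj = min(max(fbar, 0.5 / total), 1 - 0.5 / total)
            b = math.log2(fbar_adj / (1 - fbar_adj))
        else:
            b = math.log2(fbar / (1 - fbar))
        if n_ind >= 2 and float(freqs.std(ddof=1)) > 0:
            t = stats.ttest_1samp(freqs, 0.5)
            p = float(t.pvalue)
            half = stats.t.ppf(0.975, n_ind - 1) * freqs.std(ddof=1) / math.sqrt(n_ind)
            lo, hi = max(0.0, fbar - half), min(1.0, fbar + half)
        else:
            p, lo, hi = (1.0 if fbar == 0.5 else float("nan")), fbar, fbar
        return ASEResult(
            freq_p1=fbar,
            ci_low=lo,
            ci_high=hi,
            cis_effect_B=b,
            pvalue_bias=p,
            n_individuals=n_ind,
            total_reads=float((c1 + c2).sum()),
            pooling="per-individual-mean",
            continuity_corrected=corrected,
        )

    raise ValueError(f"unknown pooling mode {pooling!r}")


def counts_from_peaks(
    peaks: pd.DataFrame, depth_scale: int
) -> pd.DataFrame:
    """Convert pyrogram peak-height pairs to integer allele counts.

    Peak heights are proportional to allele dosage; each pair is rescaled
    to sum to ``depth_scale`` using largest-remainder rounding (ties go to
    the parent-1 allele).  Rows with both heights zero are dropped with a
    logged warning.
    """
    if depth_scale < 1:
        raise ValueError(f"depth_scale must be >= 1, got {depth_scale}")
    required = {"individual_id", "peak_p1", "peak_p2"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table lacks columns {sorted(missing)}")
    rows = []
    for row in peaks.itertuples(index=False):
        h1, h2 = float(row.peak_p1), float(row.peak_p2)
        if h1 < 0 or h2 < 0:
            raise ValueError("peak heights must be non-negative")
        if h1 + h2 == 0:
            log.warning("dropping individual %s: both peak heights are zero",
                        row.individual_id)
            continue
        f1 = h1 / (h1 + h2) * depth_scale
        f2 = h2 / (h1 + h2) * depth_scale
        c1, c2 = int(math.floor(f1)), int(math.floor(f2))
        leftover = depth_scale - c1 - c2
        if leftover:  # 0 or 1 by construction
            if (f1 - c1) >= (f2 - c2):
                c1 += leftover
            else:
                c2 += leftover
        rows.append(
            {
                "individual_id": row.individual_id,
                "marker": getattr(row, "marker", "marker"),
                "count_p1": c1,
                "count_p2": c2,
                "group": getattr(row, "group", "HY"),
            }
        )
    return pd.DataFrame(
        rows, columns=["individual_id", "marker", "count_p1", "count_p2", "group"]
    )
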