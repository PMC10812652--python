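"""Dual-luciferase promoter-activity comparison.

Firefly luminescence reports the test promoter's activity; renilla from a
co-transfected control normalises for transfection efficiency and cell
number, so the per-well statistic is the firefly/renilla ratio.  The
promoter-activity fold between two constructs is, by default, the ratio of
group mean ratios; significance is a Welch t test on log ratios (ratios
are multiplicative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("construct", "well", "firefly", "renilla")


@dataclass(frozen=True)
class PromoterActivity:
    """Normalized activities of two promoter constructs and their ratio."""

    fold_p1_vs_p2: float
    pvalue: float | None
    p1_mean: float
    p1_sd: float
    p2_mean: float
    p2_sd: float
    n_p1: int
    n_p2: int
    method: str
    background_subtracted: bool = False


def promoter_activity(
    table: pd.DataFrame,
    p1: str,
    p2: str,
    background: str | None = None,
    method: str = "ratio-of-means",
) -> PromoterActivity:
    """Estimate the relative activity of two promoter constructs.

    Parameters
    ----------
    table:
        Columns ``construct, well, firefly, renilla``; wells with a
        non-positive readout are excluded with a logged warning.
    background:
        Optional empty-vector construct label whose mean ratio is
        subtracted from every well ratio before summarising.
    method:
        ``"ratio-of-means"`` (default) divides group mean ratios;
        ``"geometric"`` uses the ratio of geometric means (equivalently the
        exponentiated difference of mean log ratios).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"luminescence table lacks columns {missing}")
    if method not in ("ratio-of-means", "geometric"):
        raise ValueError(f"unknown method {method!r}")

    ok = (table["firefly"] > 0) & (table["renilla"] > 0)
    for well in table.loc[~ok, "well"]:
        log.warning("well %s has a non-positive readout; excluded", well)
    table = table.loc[ok].copy()
    if table.empty:
        raise ValueError("all wells excluded: no positive luminescence pairs")
    table["ratio"] = table["firefly"] / table["renilla"]

    subtracted = False
    if background is not None:
        bg = table.loc[table["construct"] == background, "ratio"]
        if not bg.empty:
            table["ratio"] = table["ratio"] - float(bg.mean())
            table = table.loc[table["ratio"] > 0]
            subtracted = True

    r1 = table.loc[table["construct"] == p1, "ratio"].to_numpy(dtype=float)
    r2 = table.loc[table["construct"] == p2, "ratio"].to_numpy(dtype=float)
    for label, arr in ((p1, r1), (p2, r2)):
        if arr.size == 0:
            raise ValueError(f"no retained wells for construct {label!r}")

    if method == "ratio-of-means":
        fold = float(r1.mean() / r2.mean())
    else:
        fold = float(math.exp(np.log(r1).mean() - np.log(r2).mean()))

    pvalue = None
    if len(r1) >= 2 and len(r2) >= 2:
        if np.log(r1).std(ddof=1) == 0 and np.log(r2).std(ddof=1) == 0:
            pvalue = 1.0 if math.isclose(r1.mean(), r2.mean()) else 0.0
        else:
            pvalue = float(
                stats.ttest_ind(np.log(r1), np.log(r2), equal_var=False).pvalue
            )

    return PromoterActivity(
        fold_p1_vs_p2=fold,
        pvalue=pvalue,
        p1_mean=float(r1.mean()),
        p1_sd=float(r1.std(ddof=1)) if len(r1) > 1 else 0.0,
        p2_mean=float(r2.mean()),
        p2_sd=float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
        n_p1=int(len(r1)),
        n_p2=int(len(r2)),
        method=method,
        background_subtracted=subtracted,
    )
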