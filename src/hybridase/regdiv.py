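"""Inheritance-mode classification and cis/trans decomposition.

Given parental expression divergence A (log2 P1/P2 from qPCR) and the
hybrid's allelic imbalance B (log2 of the allele-count ratio from
pyrosequencing), the trans component is defined by subtraction, T = A - B:
the part of the parental divergence not explained in cis.  There is no
direct trans assay in this design, so no independent trans test is
fabricated; trans nullity is judged from the point estimate and the A/B
evidence flags.

The hybrid's overall level is compared with the mid-parent value (MPV) and
both parents to call the inheritance mode: additive, dominant towards one
parent, or over/under-dominant (ELOD-Up = Expression Level Over
Dominance-Up, hybrid significantly above both parents; ELOD-Down the
mirror image).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .asepyro import ASEResult
from .qpcr import RelativeExpression

ADDITIVE = "additive"
DOMINANT_P1 = "dominant-P1"
DOMINANT_P2 = "dominant-P2"
ELOD_UP = "ELOD-Up"
ELOD_DOWN = "ELOD-Down"
AMBIGUOUS = "ambiguous"

CONSERVED = "conserved"
CIS_ONLY = "cis-only"
TRANS_ONLY = "trans-only"
ENHANCING = "cis+trans enhancing"
CIS_TRANS_COMPENSATORY = "cis×trans compensatory"
COMPENSATORY = "compensatory"

CATEGORIES = (
    CONSERVED,
    CIS_ONLY,
    TRANS_ONLY,
    ENHANCING,
    CIS_TRANS_COMPENSATORY,
    COMPENSATORY,
    AMBIGUOUS,
)


@dataclass(frozen=True)
class InheritanceCall:
    """Hybrid expression mode relative to the parents and their midpoint."""

    mode: str
    mpv: float
    hybrid_mean: float
    p1_mean: float
    p2_mean: float
    significance: dict[str, float] = field(default_factory=dict)
    tests_skipped: bool = False


@dataclass(frozen=True)
class CisTransResult:
    """The (A, B, T) decomposition and its regulatory category.

    ``evidence`` records, per component, the estimate, whether it was
    judged non-null, and which rule fired (significance test or magnitude
    threshold).
    """

    A: float
    B: float
    T: float
    category: str
    evidence: dict[str, dict] = field(default_factory=dict)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t p-value, with the zero-variance limit handled: identical
    samples give p = 1, separated constant samples give p = 0."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if math.isnan(p):
        p = 1.0 if math.isclose(float(x.mean()), float(y.mean())) else 0.0
    return p


def _sig_greater(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[bool, float]:
    """Welch t on log2 folds; returns (x significantly above y, p)."""
    p = _welch_p(x, y)
    return (p < alpha and float(x.mean()) > float(y.mean())), p


def _mpv_contrast_p(fh: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> float:
    """Test hybrid mean fold against the mid-parent value on the linear
    scale, propagating the uncertainty of all three group means
    (Welch-Satterthwaite df).  Unlike a one-sample test against the point
    estimate of the MPV, this contrast is unbiased under the null."""
    d = float(fh.mean() - (f1.mean() + f2.mean()) / 2.0)
    parts = [
        (fh.var(ddof=1) / len(fh), len(fh) - 1),
        (f1.var(ddof=1) / (4 * len(f1)), len(f1) - 1),
        (f2.var(ddof=1) / (4 * len(f2)), len(f2) - 1),
    ]
    var = sum(v for v, _ in parts)
    if var == 0:
        return 1.0 if math.isclose(d, 0.0, abs_tol=1e-12) else 0.0
    df = var**2 / sum(v**2 / max(k, 1) for v, k in parts)
    t = d / math.sqrt(var)
    return float(2.0 * stats.t.sf(abs(t), df))


def classify_inheritance(
    rel: RelativeExpression,
    hybrid: str,
    p1: str,
    p2: str,
    alpha: float = 0.05,
    epsilon: float = 0.5,
) -> InheritanceCall:
    """Classify the hybrid's expression mode against MPV and both parents.

    Welch t tests on log2 folds compare the hybrid with each parent; the
    mid-parent comparison is a linear-scale contrast against the average
    of the parental means (which is exact at the midpoint and calibrated
    under the null).  Significantly above both parents -> ELOD-Up; below
    both -> ELOD-Down; not distinguishable from
    the mid-parent value -> additive; indistinguishable from exactly one
    parent (and off the MPV) -> dominant towards that parent; conflicting
    patterns -> ambiguous.  With fewer than two samples in any group the
    tests are skipped and the decision falls back to point estimates with
    the log2 threshold ``epsilon``.
    """
    fh = rel.sample_folds(hybrid)
    f1 = rel.sample_folds(p1)
    f2 = rel.sample_folds(p2)
    m1, m2, mh = float(f1.mean()), float(f2.mean()), float(fh.mean())
    mpv = (m1 + m2) / 2.0

    tests_skipped = min(len(fh), len(f1), len(f2)) < 2
    sig: dict[str, float] = {}
    if tests_skipped:
        d1 = math.log2(mh / m1)
        d2 = math.log2(mh / m2)
        dm = math.log2(mh / mpv)
        above1, below1 = d1 > epsilon, d1 < -epsilon
        above2, below2 = d2 > epsilon, d2 < -epsilon
        diff1, diff2 = abs(d1) > epsilon, abs(d2) > epsilon
        diff_mpv = abs(dm) > epsilon
    else:
        lh, l1, l2 = np.log2(fh), np.log2(f1), np.log2(f2)
        above1, p_h1 = _sig_greater(lh, l1, alpha)
        above2, p_h2 = _sig_greater(lh, l2, alpha)
        below1, _ = _sig_greater(l1, lh, alpha)
        below2, _ = _sig_greater(l2, lh, alpha)
        p_mpv = _mpv_contrast_p(fh, f1, f2)
        sig = {"hybrid_vs_p1": p_h1, "hybrid_vs_p2": p_h2, "hybrid_vs_mpv": p_mpv}
        diff1 = p_h1 < alpha
        diff2 = p_h2 < alpha
        diff_mpv = p_mpv < alpha

    if above1 and above2:
        mode = ELOD_UP
    elif below1 and below2:
        mode = ELOD_DOWN
    elif not diff_mpv:
        mode = ADDITIVE
    elif not diff1 and diff2:
        mode = DOMINANT_P1
    elif not diff2 and diff1:
        mode = DOMINANT_P2
    else:
        mode = AMBIGUOUS

    return InheritanceCall(
        mode=mode,
        mpv=mpv,
        hybrid_mean=mh,
        p1_mean=m1,
        p2_mean=m2,
        significance=sig,
        tests_skipped=tests_skipped,
    )


def _component(
    value: float,
    pvalue: float | None,
    alpha: float,
    epsilon: float,
) -> dict:
    by_test = pvalue is not None and not math.isnan(pvalue) and pvalue < alpha
    by_magnitude = abs(value) > epsilon
    return {
        "estimate": value,
        "nonnull": by_test or by_magnitude,
        "rule": (
            "significance" if by_test else
            "magnitude" if by_magnitude else "null"
        ),
        "pvalue": pvalue,
    }


def decompose_cis_trans(
    A: float,
    ase: ASEResult | float,
    alpha: float = 0.05,
    epsilon: float = 0.5,
    a_pvalue: float | None = None,
) -> CisTransResult:
    """Decompose parental divergence A into cis (B) and trans (T = A - B).

    ``ase`` may be a full :class:`~hybridase.asepyro.ASEResult` (whose
    binomial bias p-value contributes cis-significance evidence) or a bare
    log2 value.  A component is non-null iff its test is significant at
    ``alpha`` (when a test exists) or its magnitude exceeds ``epsilon``
    log2 units.  Since trans has no direct measurement, T is flagged
    non-null when |T| > epsilon, or -- when both A and B carry tests --
    when exactly one of the two is significant (the subtraction then
    inherits the evidence).

    Categories: both components null -> conserved; cis only -> cis-only;
    trans only -> trans-only; same sign -> enhancing; opposite signs with
    residual divergence (A non-null) -> cis×trans compensatory; opposite
    signs cancelling (A null) -> compensatory; anything else -> ambiguous.
    """
    if isinstance(ase, ASEResult):
        b = ase.cis_effect_B
        b_pvalue: float | None = ase.pvalue_bias
    else:
        b = float(ase)
        b_pvalue = None
    if not math.isfinite(A):
        raise ValueError("A must be finite")
    t = A - b

    ev_a = _component(A, a_pvalue, alpha, epsilon)
    ev_b = _component(b, b_pvalue, alpha, epsilon)
    a_sig = ev_a["rule"] == "significance"
    b_sig = ev_b["rule"] == "significance"
    both_tested = a_pvalue is not None and b_pvalue is not None
    t_nonnull = abs(t) > epsilon or (both_tested and a_sig != b_sig)
    ev_t = {
        "estimate": t,
        "nonnull": t_nonnull,
        "rule": "magnitude" if abs(t) > epsilon else
        ("propagated" if t_nonnull else "null"),
        "pvalue": None,
    }

    b_nonnull, t_nn, a_nonnull = ev_b["nonnull"], t_nonnull, ev_a["nonnull"]
    if not b_nonnull and not t_nn:
        category = CONSERVED if not a_nonnull else AMBIGUOUS
    elif b_nonnull and not t_nn:
        category = CIS_ONLY
    elif t_nn and not b_nonnull:
        category = TRANS_ONLY
    elif b * t > 0:
        category = ENHANCING
    elif b * t < 0:
        category = CIS_TRANS_COMPENSATORY if a_nonnull else COMPENSATORY
    else:
        category = AMBIGUOUS

    return CisTransResult(
        A=A, B=b, T=t, category=category,
        evidence={"A": ev_a, "B": ev_b, "T": ev_t},
    )
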