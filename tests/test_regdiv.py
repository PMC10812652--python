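"""Inheritance-mode decision table and cis/trans decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridase.asepyro import estimate_ase
from hybridase.qpcr import RelativeExpression, ddct, parental_divergence_A
from hybridase.regdiv import (
    ADDITIVE,
    AMBIGUOUS,
    CIS_ONLY,
    CIS_TRANS_COMPENSATORY,
    COMPENSATORY,
    CONSERVED,
    DOMINANT_P1,
    DOMINANT_P2,
    ELOD_DOWN,
    ELOD_UP,
    TRANS_ONLY,
    classify_inheritance,
    decompose_cis_trans,
)
from hybridase.synth import (
    SimTruth,
    paper_truth,
    planted_category,
    simulate_ct_table,
    simulate_pyro_counts,
)


def _rel_from_means(means: dict[str, float], sd: float, n: int = 6,
                    seed: int = 0) -> RelativeExpression:
    """Build an expression summary with chosen group means on the log2 scale."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, m in means.items():
        folds = 2.0 ** (math.log2(m) + rng.normal(0, sd, size=n))
        rows += [{"sample_id": f"{g}{i}", "group": g, "dct": 0.0, "ddct": 0.0,
                  "fold": f} for i, f in enumerate(folds)]
    per = pd.DataFrame(rows)
    stats = per.groupby("group")["fold"].agg(
        n="count", mean_fold="mean", sd_fold="std").reset_index()
    stats["letter"] = "a"
    return RelativeExpression(per_sample=per, group_stats=stats,
                              calibrator="AR", alpha=0.05)


TINY, HUGE = 0.0, 2.0  # zero noise gives exact decision-table semantics


@pytest.mark.parametrize(
    "means,sd,expected",
    [
        ({"HY": 4.0, "NL": 2.0, "AR": 1.0}, TINY, ELOD_UP),
        ({"HY": 0.5, "NL": 2.0, "AR": 1.0}, TINY, ELOD_DOWN),
        ({"HY": 1.5, "NL": 2.0, "AR": 1.0}, TINY, ADDITIVE),   # at MPV
        ({"HY": 2.0, "NL": 2.0, "AR": 1.0}, TINY, DOMINANT_P1),
        ({"HY": 1.0, "NL": 2.0, "AR": 1.0}, TINY, DOMINANT_P2),
        ({"HY": 1.2, "NL": 1.2, "AR": 1.2}, HUGE, ADDITIVE),   # nothing sig
        ({"HY": 1.75, "NL": 2.0, "AR": 1.0}, TINY, AMBIGUOUS),
    ],
)
def test_inheritance_decision_table(means, sd, expected):
    rel = _rel_from_means(means, sd)
    call = classify_inheritance(rel, "HY", "NL", "AR")
    assert call.mode == expected
    assert call.mpv == pytest.approx((call.p1_mean + call.p2_mean) / 2)


def test_elod_up_at_study_means():
    truth = paper_truth(seed=8)
    rel = ddct(simulate_ct_table(truth, n_samples=20, sigma=0.1, seed=31),
               calibrator="AR")
    call = classify_inheritance(rel, "HY", "NL", "AR")
    assert call.mode == ELOD_UP
    assert not call.tests_skipped


def test_point_estimate_fallback_with_single_samples():
    rel = _rel_from_means({"HY": 4.0, "NL": 2.0, "AR": 1.0}, 0.0, n=1)
    call = classify_inheritance(rel, "HY", "NL", "AR")
    assert call.tests_skipped and call.mode == ELOD_UP


def test_parent_swap_antisymmetry():
    rel = _rel_from_means({"HY": 2.0, "NL": 2.0, "AR": 1.0}, TINY)
    fwd = classify_inheritance(rel, "HY", "NL", "AR")
    rev = classify_inheritance(rel, "HY", "AR", "NL")
    assert fwd.mode == DOMINANT_P1 and rev.mode == DOMINANT_P2
    assert fwd.mpv == rev.mpv


class TestDecompose:
    def test_printed_inputs_give_compensatory(self):
        res = decompose_cis_trans(0.92, 1.74)
        assert res.T == pytest.approx(-0.82, abs=1e-12)
        assert res.category == CIS_TRANS_COMPENSATORY

    def test_null_case(self):
        assert decompose_cis_trans(0.0, 0.0).category == CONSERVED

    def test_all_cis_limit(self):
        res = decompose_cis_trans(1.5, 1.5)
        assert res.T == 0.0 and res.category == CIS_ONLY

    def test_trans_only(self):
        assert decompose_cis_trans(1.5, 0.0).category == TRANS_ONLY

    def test_enhancing(self):
        assert decompose_cis_trans(2.0, 1.0).category == "cis+trans enhancing"

    def test_fully_compensatory_when_divergence_cancels(self):
        assert decompose_cis_trans(0.0, 1.5).category == COMPENSATORY

    def test_antisymmetry_under_parent_swap(self):
        fwd = decompose_cis_trans(0.92, 1.74)
        rev = decompose_cis_trans(-0.92, -1.74)
        assert rev.A == -fwd.A and rev.B == -fwd.B and rev.T == pytest.approx(-fwd.T)
        assert rev.category == fwd.category

    def test_t_identity_exact(self):
        for a, b in [(0.3, -1.1), (2.5, 0.7), (-0.4, -0.4)]:
            res = decompose_cis_trans(a, b)
            assert res.T == a - res.B


def test_noiseless_grid_recovers_planted_categories():
    """Full pipeline on noiseless data: 25/25 (cis, trans) cells recovered."""
    hits = 0
    for cis in (-2, -1, 0, 1, 2):
        for trans in (-2, -1, 0, 1, 2):
            truth = SimTruth(cis_effect=cis, trans_effect=trans,
                             hybrid_fold_vs_p2=1.5, promoter_activity_ratio=2.0,
                             seed=1)
            ase = estimate_ase(
                simulate_pyro_counts(truth, n_individuals=5, depth=300,
                                     noiseless=True))
            rel = ddct(simulate_ct_table(truth, n_samples=3, sigma=0.0),
                       calibrator="AR")
            a = parental_divergence_A(rel, "NL", "AR")
            res = decompose_cis_trans(a, ase)
            assert abs(res.A - (cis + trans)) < 1e-9
            assert abs(res.B - cis) < 1e-9
            assert abs(res.T - trans) < 1e-9
            hits += res.category == planted_category(cis, trans)
    assert hits == 25


def test_null_inheritance_type_i_error_controlled():
    """All groups equal: non-additive calls at most alpha + MC error."""
    truth = SimTruth(cis_effect=0.0, trans_effect=0.0, hybrid_fold_vs_p2=1.0,
                     promoter_activity_ratio=1.0)
    n_sim = 300
    nonadd = 0
    for s in range(n_sim):
        rel = ddct(simulate_ct_table(truth, n_samples=20, sigma=0.2,
                                     seed=5000 + s), calibrator="AR")
        call = classify_inheritance(rel, "HY", "NL", "AR")
        nonadd += call.mode != ADDITIVE
    # the additive call hinges on the MPV test at alpha = 0.05
    bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)
    assert nonadd / n_sim <= bound
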