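"""The synthetic generators: fixture invariants and forward-model behaviour."""

import math

import numpy as np
import pytest
from scipy import stats

from hybridase import seqvar, synth
from hybridase.asepyro import estimate_ase
from hybridase.qpcr import ddct
from hybridase.reporter import promoter_activity
from hybridase.synth import (
    SimTruth,
    make_paper_fixture,
    paper_truth,
    simulate_ct_table,
    simulate_luminescence,
    simulate_pyro_counts,
)


class TestPaperFixture:
    def test_variant_counts_and_positions(self, fx):
        assert len(fx.coding_variants) == 7
        assert len(fx.promoter_variants) == 8
        assert [v.position for v in fx.coding_variants] == [
            325, 601, 817, 841, 1142, 1270, 1357]
        assert [v.position for v in fx.promoter_variants] == [
            -314, -297, -241, -238, -236, -145, -138, -33]

    def test_cds_geometry_and_translation(self, fx):
        cds = fx.cds("NL")
        assert len(cds) == 1086
        assert len(seqvar.translate(cds)) == 361
        assert len(seqvar.translate(fx.cds("AR"))) == 361
        assert fx.utr5_length % 3 == 1  # frame choice putting sites on wobble

    def test_planted_motifs_nl_only(self, fx):
        nl = fx.haplotypes["NL_prom"].sequence
        ar = fx.haplotypes["AR_prom"].sequence
        for motif in fx.motifs:
            assert nl.count(motif.consensus) == 1
            assert ar.count(motif.consensus) == 0

    def test_parents_unambiguous_hybrid_iupac(self, fx):
        assert not fx.haplotypes["NL_cds"].is_ambiguous
        assert not fx.haplotypes["AR_cds"].is_ambiguous
        hy = fx.haplotypes["HY_cds"]
        assert hy.is_ambiguous
        # ambiguity only at the seven planted sites
        ambig = [hy.pos_of_index(i) for i, c in enumerate(hy.sequence)
                 if c not in "ACGT"]
        assert ambig == [v.position for v in fx.coding_variants]

    def test_deterministic_across_calls(self):
        a = make_paper_fixture()
        b = make_paper_fixture()
        assert all(
            a.haplotypes[k].sequence == b.haplotypes[k].sequence
            for k in a.haplotypes
        )


class TestSimTruth:
    def test_decomposition_identity_enforced(self):
        t = SimTruth(cis_effect=1.2, trans_effect=-0.7, hybrid_fold_vs_p2=1.5,
                     promoter_activity_ratio=2.0)
        assert math.log2(t.parental_fold) == pytest.approx(0.5, abs=1e-12)
        r = 2 ** 1.2
        assert t.allele_freq_p1 == pytest.approx(r / (1 + r), abs=1e-15)

    def test_paper_truth_frequency_is_77(self):
        t = paper_truth()
        assert t.allele_freq_p1 == pytest.approx(0.77, abs=1e-12)
        assert t.parental_fold == pytest.approx(1.48, abs=1e-12)


class TestPyroCounts:
    def test_degenerate_frequency_gives_full_depth(self):
        t = SimTruth(cis_effect=50, trans_effect=0, hybrid_fold_vs_p2=1,
                     promoter_activity_ratio=1, seed=1)
        assert t.allele_freq_p1 == pytest.approx(1.0)
        tab = simulate_pyro_counts(t, n_individuals=5, depth=100)
        assert (tab["count_p1"] == 100).all() and (tab["count_p2"] == 0).all()

    def test_pooled_frequency_within_exact_binomial_interval(self):
        t = paper_truth(seed=5)
        tab = simulate_pyro_counts(t, n_individuals=20, depth=500)
        k = tab["count_p1"].sum()
        n = 20 * 500
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.77)
        assert lo <= k <= hi

    def test_invalid_parameters_named(self):
        t = paper_truth()
        with pytest.raises(ValueError, match="depth"):
            simulate_pyro_counts(t, depth=0)
        with pytest.raises(ValueError, match="n_individuals"):
            simulate_pyro_counts(t, n_individuals=0)

    def test_seeded_reproducibility(self):
        t = paper_truth(seed=9)
        a = simulate_pyro_counts(t)
        b = simulate_pyro_counts(t)
        assert a.equals(b)


class TestCtTable:
    def test_noiseless_closed_form(self):
        t = SimTruth(cis_effect=1.0, trans_effect=0.0, hybrid_fold_vs_p2=1.0,
                     promoter_activity_ratio=1.0)
        assert t.parental_fold == 2.0
        tab = simulate_ct_table(t, n_samples=2, n_replicates=1, sigma=0.0)
        rel = ddct(tab, calibrator="AR")
        assert rel.group_mean("NL") == pytest.approx(2.0, abs=1e-12)
        # ddCt(P1 vs P2) = -1 exactly
        dct = tab[tab.gene == "p38"].groupby("group")["ct"].mean()
        assert dct["NL"] - dct["AR"] == pytest.approx(-1.0, abs=1e-12)

    def test_forward_inverse_consistency_at_printed_folds(self, study_truth):
        tab = simulate_ct_table(study_truth, n_samples=3, n_replicates=3,
                                sigma=0.0)
        rel = ddct(tab, calibrator="AR")
        assert rel.group_mean("HY") == pytest.approx(1.90, abs=1e-9)
        assert rel.group_mean("NL") == pytest.approx(1.48, abs=1e-9)
        assert rel.group_mean("AR") == pytest.approx(1.0, abs=1e-12)

    def test_unknown_group_label_rejected(self, study_truth):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_ct_table(study_truth, groups=["XX"])

    def test_monte_carlo_fold_recovery(self):
        t = paper_truth(seed=0)
        recovered = []
        for s in range(500):
            tab = simulate_ct_table(t, n_samples=3, n_replicates=3, sigma=0.2,
                                    seed=1000 + s, groups=["NL", "AR"])
            rel = ddct(tab, calibrator="AR")
            recovered.append(rel.group_mean("NL"))
        assert np.mean(recovered) == pytest.approx(1.48, rel=0.05)


class TestLuminescence:
    def test_noiseless_ratio_recovery(self, study_truth):
        tab = simulate_luminescence(study_truth, n_wells=3, cv=0.0)
        act = promoter_activity(tab, "NL", "AR")
        assert act.fold_p1_vs_p2 == pytest.approx(3.3, abs=1e-12)

    def test_null_ratio(self):
        t = SimTruth(cis_effect=0, trans_effect=0, hybrid_fold_vs_p2=1,
                     promoter_activity_ratio=1.0)
        tab = simulate_luminescence(t, n_wells=3, cv=0.0)
        act = promoter_activity(tab, "NL", "AR")
        assert act.fold_p1_vs_p2 == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_ratio_recovery(self):
        t = paper_truth(seed=0)
        folds = [
            promoter_activity(
                simulate_luminescence(t, n_wells=6, cv=0.15, seed=2000 + s),
                "NL", "AR",
            ).fold_p1_vs_p2
            for s in range(500)
        ]
        assert np.median(folds) == pytest.approx(3.3, rel=0.10)
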