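"""Three-test hierarchy and the seven-way regulatory decision table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from asecross import (
    AnalysisConfig,
    SimConfig,
    classify_regulatory,
    run_cistrans,
    simulate,
    test_hybrid_imbalance as hybrid_imbalance,
    test_parental_de as parental_de,
    test_trans_fisher as trans_fisher,
)
from asecross.core_io import Scope


def fisher_exact_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration (independent of scipy)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def logcomb(n_, k_):
        return (
            math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)
        )

    def prob(x):
        return math.exp(
            logcomb(r1, x) + logcomb(n - r1, c1 - x) - logcomb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestTransFisher:
    def test_balanced_table_p_one(self):
        assert trans_fisher(100, 100, 100, 100) == pytest.approx(1.0)
        assert trans_fisher(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        p = trans_fisher(10, 0, 0, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(fisher_exact_oracle([[10, 0], [0, 10]]), rel=1e-9)

    @pytest.mark.parametrize(
        "table", [[[12, 5], [3, 9]], [[40, 60], [55, 45]], [[1, 0], [0, 1]]]
    )
    def test_general_tables_match_enumeration(self, table):
        p = trans_fisher(table[0][0], table[0][1], table[1][0], table[1][1])
        assert p == pytest.approx(fisher_exact_oracle(table), rel=1e-8)

    def test_all_zero_table(self):
        assert trans_fisher(0, 0, 0, 0) == 1.0

    def test_fractional_counts_rounded_half_up(self):
        assert trans_fisher(9.5, 0.2, 0.4, 9.5) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            trans_fisher(-1, 2, 3, 4)


def classification_oracle(sig_p, sig_h, sig_t, ratio):
    """Hand-coded truth table, written directly from the category definitions."""
    flags = (sig_p, sig_h, sig_t)
    if flags == (False, False, False):
        return "conserved"
    if sum(flags) == 1:
        return "ambiguous"
    if flags == (True, True, False):
        return "cis_only"
    if flags == (True, False, True):
        return "trans_only"
    if flags == (False, True, True):
        return "compensatory"
    return "cis_plus_trans" if ratio >= 1 else "cis_by_trans"


class TestClassification:
    @pytest.mark.parametrize(
        "flags,lp,lh,expected",
        [
            ((True, True, False), 2.0, 1.0, "cis_only"),
            ((False, True, True), 0.0, 1.0, "compensatory"),
            ((True, True, True), 3.0, 1.0, "cis_plus_trans"),  # ratio 3
            ((True, True, True), 0.5, 1.0, "cis_by_trans"),  # ratio 0.5
            ((False, False, False), 0.0, 0.0, "conserved"),
            ((False, False, True), 0.0, 0.0, "ambiguous"),
            ((True, False, True), 1.0, 0.1, "trans_only"),
        ],
    )
    def test_worked_examples(self, flags, lp, lh, expected):
        assert classify_regulatory(*flags, lp, lh) == expected

    def test_exhaustive_against_oracle(self):
        """All 8 flag combinations x ratio regimes {<1, =1, >1}, incl. signs."""
        for flags in itertools.product([False, True], repeat=3):
            for lp, lh in [(0.5, 1.0), (1.0, 1.0), (3.0, 1.0), (-2.0, 1.0),
                           (2.0, -1.0), (-3.0, -1.0)]:
                got = classify_regulatory(*flags, lp, lh)
                assert got == classification_oracle(*flags, lp / lh)

    def test_ratio_exactly_one_goes_to_cis_plus_trans(self):
        assert classify_regulatory(True, True, True, 1.0, 1.0) == "cis_plus_trans"


class TestComponentTests:
    def test_identical_parental_counts_null(self, acfg):
        p = parental_de(
            np.array([200.0, 210.0]), np.array([205.0, 205.0]),
            np.zeros(2), np.zeros(2), acfg, dispersion=0.05,
        )
        assert p > 0.5

    def test_parental_all_zero(self, acfg):
        assert parental_de(
            np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2), acfg
        ) == 1.0

    def test_parental_fold_detected(self, acfg):
        p = parental_de(
            np.array([100.0, 110.0]), np.array([420.0, 395.0]),
            np.zeros(2), np.zeros(2), acfg, dispersion=0.01,
        )
        assert p < 0.01

    def test_hybrid_balanced_null(self, acfg):
        ac = pd.DataFrame({"A": [200.0, 190, 205, 210], "B": [205.0, 195, 200, 202]})
        p = hybrid_imbalance(ac, np.zeros(4), acfg, dispersion=0.01)
        assert p > 0.3

    def test_hybrid_imbalance_detected(self, acfg):
        ac = pd.DataFrame({"A": [100.0, 105, 98, 101], "B": [205.0, 195, 210, 202]})
        p = hybrid_imbalance(ac, np.zeros(4), acfg, dispersion=0.01)
        assert p < 1e-4

    def test_hybrid_missing_sample_still_fits(self, acfg):
        ac = pd.DataFrame({"A": [100.0, 105, 98], "B": [205.0, 195, 210]})
        p = hybrid_imbalance(ac, np.zeros(3), acfg, dispersion=0.01)
        assert np.isfinite(p) and p < 1e-3


@pytest.fixture(scope="module")
def cis_sim():
    cfg = SimConfig(
        n_genes=200, seed=4, base_mean=800.0, base_mean_log_sd=0.0,
        dispersion=0.005, dispersion_log_sd=0.0, sb_sd=0.0,
        cis_log2fc=1.5, log2fc_sd=0.0, prop_cis_only=0.3,
        prop_trans_only=0, prop_cis_plus_trans=0, prop_cis_by_trans=0,
        prop_compensatory=0, prop_po=0, prop_mg=0, prop_sex_reversed=0,
    )
    return simulate(cfg)


class TestRunCistrans:
    def test_calls_consistent_with_decision_table(self, cis_sim, acfg):
        scope = Scope(sex="F", tissue="head", cross_id="cross1")
        frame, props = run_cistrans(
            cis_sim.parental_counts, cis_sim.parental_meta, cis_sim.hybrid_ase,
            acfg, scope,
        )
        assert props.sum() == pytest.approx(1.0)
        a = acfg.alpha_fdr
        for _, row in frame.iterrows():
            ratio = (
                row["log2_parental"] / row["log2_hybrid"]
                if row["log2_hybrid"] != 0 else np.inf
            )
            expected = classification_oracle(
                bool(row["fdr_parental"] < a),
                bool(row["fdr_hybrid"] < a),
                bool(row["fdr_trans"] < a),
                ratio,
            )
            assert row["category"] == expected

    def test_null_genes_rarely_get_cis_calls(self, cis_sim, acfg):
        """False cis-involving calls on null genes must be rare: the H test
        compares alleles within samples, so replicate noise cannot mimic
        allelic imbalance.  (Parental replicate noise can leak into
        trans_only via the correlated P and Fisher tests, a known property
        of this test hierarchy, so trans_only is not bounded here.)"""
        scope = Scope(sex="F", tissue="head", cross_id="cross1")
        frame, _ = run_cistrans(
            cis_sim.parental_counts, cis_sim.parental_meta, cis_sim.hybrid_ase,
            acfg, scope,
        )
        truth = cis_sim.truth_frame().loc[frame.index]
        null_calls = frame.loc[truth["class_label"] == "null", "category"]
        cis_involving = null_calls.isin(
            ["cis_only", "cis_plus_trans", "cis_by_trans", "compensatory"]
        )
        assert cis_involving.mean() <= 0.02
        assert null_calls.value_counts().idxmax() == "conserved"

    def test_pooled_and_per_reciprocal_concordant_on_strong_cis(self, cis_sim, acfg):
        scope = Scope(sex="F", tissue="head", cross_id="cross1")
        pooled, _ = run_cistrans(
            cis_sim.parental_counts, cis_sim.parental_meta, cis_sim.hybrid_ase,
            acfg, scope,
        )
        axb, _ = run_cistrans(
            cis_sim.parental_counts, cis_sim.parental_meta, cis_sim.hybrid_ase,
            acfg, Scope(sex="F", tissue="head", cross_id="cross1", direction="AxB"),
            pooled_reciprocals=False,
        )
        truth = cis_sim.truth_frame()
        cis_genes = truth.index[truth["class_label"] == "cis_only"]
        cis_set = {"cis_only", "cis_plus_trans", "cis_by_trans"}
        common = pooled.index.intersection(axb.index).intersection(cis_genes)
        agree = (
            pooled.loc[common, "category"].isin(cis_set)
            == axb.loc[common, "category"].isin(cis_set)
        )
        assert agree.mean() >= 0.9
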