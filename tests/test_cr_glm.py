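"""NB GLM engine: fits, LRTs, BH adjustment, interaction and reversal models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special

from asecross import AnalysisConfig, bh_adjust, fit_nb
from asecross import test_cr_po_mg as cr_po_mg_lrt
from asecross.cr_glm import (
    moderated_dispersions,
    nested_lrt,
    test_interaction as interaction_lrt,
    test_reversal as reversal_lrt,
)


def _design_frame(cr, po, mg, sex=None, offset=None):
    n = len(cr)
    return pd.DataFrame(
        {
            "CR": cr,
            "PO": po,
            "MG": mg,
            "sex_code": sex if sex is not None else [0] * n,
            "tissue_code": [0] * n,
            "offset": offset if offset is not None else [0.0] * n,
            "sample_id": [f"s{i // 2}" for i in range(n)],
        }
    )


# the canonical 8-observation reciprocal design: (direction, allele) pairs
# AxB: A(0,0,0) B(1,1,0); BxA: A(0,1,1) B(1,0,1); two replicates each
CR8 = [0, 1, 0, 1, 0, 1, 0, 1]
PO8 = [0, 1, 1, 0, 0, 1, 1, 0]
MG8 = [0, 0, 1, 1, 0, 0, 1, 1]


def _nbll(y, mu, alpha):
    size = 1.0 / alpha
    return np.sum(
        special.gammaln(y + size) - special.gammaln(size) - special.gammaln(y + 1.0)
        + size * np.log(size / (size + mu)) + y * np.log(mu / (size + mu))
    )


class TestFitNb:
    def test_balanced_null_cr_coefficient_zero(self):
        y = np.full(8, 50.0)
        X = np.column_stack([np.ones(8), CR8, PO8, MG8])
        fit = fit_nb(y, X, np.zeros(8), dispersion=0.1)
        assert fit.converged and fit.skipped_reason is None
        assert abs(fit.coefficients[1]) < 1e-6

    def test_doubled_allele_recovers_ln2(self):
        """Every B-allele row is exactly twice its A partner; the cis
        coefficient must be ln 2, and must agree with a direct numerical
        maximization of the NB likelihood written independently here."""
        y = np.array([100.0, 200.0] * 4)
        X = np.column_stack([np.ones(8), CR8, PO8, MG8])
        fit = fit_nb(y, X, np.zeros(8), dispersion=0.1)
        assert fit.coefficients[1] == pytest.approx(np.log(2.0), abs=1e-4)

        def neg_ll(beta):
            mu = np.exp(X @ beta)
            return -_nbll(y, mu, 0.1)

        oracle = optimize.minimize(neg_ll, np.array([4.6, 0.5, 0.0, 0.0]),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-10,
                                            "maxiter": 5000})
        assert fit.coefficients[1] == pytest.approx(oracle.x[1], abs=1e-4)

    def test_insufficient_observations_skipped(self):
        y = np.full(5, 10.0)
        X = np.ones((5, 1))
        fit = fit_nb(y, X, np.zeros(5), dispersion=0.1)
        assert fit.skipped_reason == "insufficient design"

    def test_rank_deficient_skipped(self):
        y = np.full(8, 10.0)
        X = np.column_stack([np.ones(8), np.ones(8)])
        fit = fit_nb(y, X, np.zeros(8), dispersion=0.1)
        assert fit.skipped_reason == "rank-deficient design"


class TestCrPoMgTests:
    def test_balanced_null_deviance_explained_zero(self, acfg):
        design = _design_frame(CR8, PO8, MG8)
        res = cr_po_mg_lrt(np.full(8, 50.0), design, acfg, dispersion=0.1)
        assert res.deviance_explained_cr == pytest.approx(0.0, abs=1e-6)
        assert res.p_cr > 0.99

    def test_mg_only_signal_is_isolated(self, acfg):
        # MG=1 samples doubled; the orthogonal design must load this on MG
        y = np.where(np.array(MG8) == 1, 200.0, 100.0)
        design = _design_frame(CR8, PO8, MG8)
        res = cr_po_mg_lrt(y, design, acfg, dispersion=0.05)
        assert res.p_mg < 0.01
        assert res.p_cr > 0.5
        assert res.p_po > 0.5

    def test_cis_signal_detected(self, acfg):
        y = np.array([100.0, 300.0] * 4)
        design = _design_frame(CR8, PO8, MG8)
        res = cr_po_mg_lrt(y, design, acfg, dispersion=0.05)
        assert res.p_cr < 0.01
        assert res.deviance_explained_cr > 0

    def test_insufficient_design_reported(self, acfg):
        design = _design_frame(CR8[:5], PO8[:5], MG8[:5])
        res = cr_po_mg_lrt(np.full(5, 10.0), design, acfg)
        assert res.skipped_reason == "insufficient design"

    def test_continuity_adjustment_flagged(self, acfg):
        y = np.array([10.0, 0.0] * 4)
        design = _design_frame(CR8, PO8, MG8)
        res = cr_po_mg_lrt(y, design, acfg, dispersion=0.1)
        assert res.continuity_adjusted
        assert np.isfinite(res.p_cr)

    def test_nested_deviance_nonnegative(self, acfg):
        rng = np.random.default_rng(0)
        design = _design_frame(CR8, PO8, MG8)
        for _ in range(25):
            y = rng.negative_binomial(10, 10 / (10 + 100), size=8).astype(float)
            if y.sum() == 0:
                continue
            res = cr_po_mg_lrt(y, design, acfg)
            if res.skipped_reason is None:
                assert res.deviance_explained_cr >= 0


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # m=4: p*(m/i) = .04,.04,.04,.04 -> running minimum .04 everywhere
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_value(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, p):
        out = bh_adjust(p)
        assert np.all((out >= np.asarray(p) - 1e-12) & (out <= 1.0))
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestInteractionModels:
    def _two_sex_design(self):
        sex = [0] * 8 + [1] * 8
        return _design_frame(CR8 + CR8, PO8 + PO8, MG8 + MG8, sex=sex)

    def test_reversed_cis_detected_by_reversal_model(self, acfg):
        # F: B = 2x A; M: A = 2x B  -> CRsex aligns perfectly
        y = np.array([100.0, 200.0] * 4 + [200.0, 100.0] * 4)
        res = reversal_lrt(y, self._two_sex_design(), "sex", acfg, dispersion=0.05)
        assert res.p < 1e-4
        assert res.coefficient == pytest.approx(np.log(2.0), abs=0.05)

    def test_same_direction_cis_cancels_in_reversal(self, acfg):
        y = np.array([100.0, 200.0] * 8)
        res = reversal_lrt(y, self._two_sex_design(), "sex", acfg, dispersion=0.05)
        assert abs(res.coefficient) < 1e-6

    def test_interaction_detects_reversal(self, acfg):
        y = np.array([100.0, 200.0] * 4 + [200.0, 100.0] * 4)
        res = interaction_lrt(y, self._two_sex_design(), "sex", acfg, dispersion=0.05)
        assert res.p < 1e-4

    def test_equal_cis_no_interaction(self, acfg):
        y = np.array([100.0, 200.0] * 8)
        res = interaction_lrt(y, self._two_sex_design(), "sex", acfg, dispersion=0.05)
        assert res.p > 0.99

    def test_missing_factor_level_skipped(self, acfg):
        design = _design_frame(CR8, PO8, MG8)  # one sex only
        res = interaction_lrt(np.full(8, 10.0), design, "sex", acfg)
        assert res.skipped_reason == "factor level missing"


class TestDispersionModeration:
    def test_common_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        # intercept-only design so the tiled gene means are the exact fits
        X = np.ones((8, 1))
        alpha_true = 0.1
        size = 1.0 / alpha_true
        ys = rng.negative_binomial(size, size / (size + 200.0), size=(400, 8)).astype(float)
        mus = np.tile(ys.mean(axis=1)[:, None], (1, 8))
        alphas, common = moderated_dispersions(ys, mus, X, residual_df=7)
        assert 0.06 < common < 0.16
        assert np.all(alphas > 0)
        # shrinkage keeps per-gene values near the common one
        assert np.median(np.abs(np.log(alphas / common))) < 0.7
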