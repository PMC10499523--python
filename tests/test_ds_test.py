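"""Dirichlet-multinomial likelihood, fits, LRT, FDR scheme and DS calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom, multinomial

from spliceatlas.errors import ContractError, DegenerateInputError
from spliceatlas.ds_test import (
    ClusterTestResult,
    PairwiseResult,
    call_ds,
    classify_pattern,
    delta_psi,
    dm_loglik,
    eligibility,
    fit_dm,
    hierarchical_fdr,
    lrt,
    max_dpsi_per_junction,
)
from spliceatlas.junction_data import PSIMatrix
from .conftest import make_sheet


class TestDMLoglik:
    def test_two_junction_matches_beta_binomial(self):
        """With J=2 the DM collapses to a beta-binomial; cross-check scipy."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.uniform(0.1, 0.9)
            a = rng.uniform(0.5, 50)
            x1 = rng.integers(0, 20, size=4)
            x2 = rng.integers(0, 20, size=4)
            counts = np.vstack([x1, x2])
            want = betabinom.logpmf(
                x1, x1 + x2, a * p, a * (1 - p)
            ).sum()
            got = dm_loglik(counts, np.array([p, 1 - p]), a)
            assert got == pytest.approx(want, abs=1e-9)

    def test_single_draw_closed_form(self):
        assert dm_loglik(
            np.array([[1], [0]]), np.array([0.5, 0.5]), 2.0
        ) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_all_zero_counts_gives_zero(self):
        assert dm_loglik(np.zeros((3, 2)), np.ones(3) / 3, 5.0) == 0.0

    def test_large_concentration_approaches_multinomial(self):
        x = np.array([[3], [7], [10]])
        p = np.array([0.2, 0.3, 0.5])
        want = multinomial.logpmf(x[:, 0], 20, p)
        got = dm_loglik(x, p, 1e6)
        assert got == pytest.approx(want, abs=1e-4)

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            dm_loglik(np.array([[1.5], [0.2]]), np.array([0.5, 0.5]), 2.0)
        with pytest.raises(ContractError):
            dm_loglik(np.array([[-1], [2]]), np.array([0.5, 0.5]), 2.0)
        with pytest.raises(ContractError):
            dm_loglik(np.array([[1], [2]]), np.array([0.7, 0.7]), 2.0)


class TestFitDM:
    def test_multinomial_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.multinomial(10_000, [0.3, 0.7], size=4).T
        fit = fit_dm(x)
        assert fit.converged
        np.testing.assert_allclose(fit.proportions[0], [0.3, 0.7], atol=0.02)

    def test_always_zero_junction_gets_tiny_proportion(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.integers(400, 600, 6), np.zeros(6, dtype=int)])
        fit = fit_dm(x)
        assert fit.proportions[0][1] <= 1e-3

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_dm(np.zeros((2, 3), dtype=int))

    def test_pooled_concatenates_groups(self):
        rng = np.random.default_rng(3)
        a = rng.multinomial(100, [0.5, 0.5], size=3).T
        b = rng.multinomial(100, [0.5, 0.5], size=3).T
        pooled = fit_dm([a, b], pooled=True)
        direct = fit_dm(np.concatenate([a, b], axis=1))
        assert pooled.loglik == pytest.approx(direct.loglik, abs=1e-6)

    def test_fixed_concentration_respected(self):
        rng = np.random.default_rng(4)
        x = rng.multinomial(50, [0.4, 0.6], size=5).T
        fit = fit_dm(x, fixed_log_concentration=math.log(7.0))
        assert fit.concentration == pytest.approx(7.0)


class TestLRT:
    def test_identical_groups_give_p_near_one(self):
        x = np.array([[30, 31, 29, 30, 31, 29], [70, 69, 71, 70, 69, 71]])
        res = lrt(x, ["a"] * 3 + ["b"] * 3)
        assert res.stat == pytest.approx(0.0, abs=0.5)
        assert res.p > 0.5

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(5)
        a = rng.multinomial(200, [0.8, 0.2], size=4).T
        b = rng.multinomial(200, [0.3, 0.7], size=4).T
        res = lrt(np.concatenate([a, b], axis=1), ["a"] * 4 + ["b"] * 4)
        assert res.p < 1e-4

    def test_df_formula(self):
        rng = np.random.default_rng(6)
        x = rng.multinomial(100, [0.3, 0.3, 0.4], size=9).T
        res = lrt(x, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.df == (3 - 1) * (3 - 1)

    def test_stat_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.multinomial(60, [0.5, 0.5], size=6).T
            assert lrt(x, ["a"] * 3 + ["b"] * 3).stat >= 0.0


class TestEligibility:
    def test_single_sample_group_ineligible_pairwise(self):
        x = np.array([[50, 50, 50], [50, 50, 50]])
        el = eligibility(x, ["a", "a", "b"], min_samples_per_group=2)
        assert not el.eligible

    def test_rare_junction_excluded(self):
        x = np.array([[50, 50, 50, 50], [12, 0, 0, 0], [40, 40, 40, 40]])
        el = eligibility(x, ["a", "a", "b", "b"], min_samples_per_group=2)
        assert el.eligible
        assert list(el.junction_mask) == [True, False, True]

    def test_all_thresholds_met(self):
        x = np.full((2, 4), 20)
        el = eligibility(x, ["a", "a", "b", "b"], min_samples_per_group=2)
        assert el.eligible and el.junction_mask.all()


def _psi_fixture():
    sheet = make_sheet(["a1", "a2", "b1", "b2"])
    psi = pd.DataFrame(
        {
            "a1": [0.8, 0.2], "a2": [0.8, 0.2],
            "b1": [0.3, 0.7], "b2": [np.nan, np.nan],
        },
        index=["j1", "j2"],
    )
    return PSIMatrix(psi, sheet, pd.Series({"j1": "lc", "j2": "lc"}))


class TestDeltaPSI:
    def test_group_means(self):
        dp = delta_psi(_psi_fixture(), ["a1", "a2"], ["b1", "b2"])
        assert dp["j1"] == pytest.approx(0.5)

    def test_nan_aware_means(self):
        # b2 is undefined; the b mean uses b1 only
        dp = delta_psi(_psi_fixture(), ["a1", "a2"], ["b1", "b2"])
        assert dp["j2"] == pytest.approx(0.2 - 0.7)

    def test_antisymmetry(self):
        psi = _psi_fixture()
        ab = delta_psi(psi, ["a1", "a2"], ["b1", "b2"])
        ba = delta_psi(psi, ["b1", "b2"], ["a1", "a2"])
        pd.testing.assert_series_equal(ab, -ba)

    def test_all_undefined_group(self):
        sheet = make_sheet(["a1", "b1"])
        psi = PSIMatrix(
            pd.DataFrame({"a1": [0.5], "b1": [np.nan]}, index=["j"]),
            sheet, pd.Series({"j": "lc"}),
        )
        assert delta_psi(psi, ["a1"], ["b1"]).isna().all()


def _result(lc_id="lc1", p_multi=0.001, pairs=None):
    res = ClusterTestResult(lc_id=lc_id, junction_keys=("j1", "j2"), p_multi=p_multi)
    for (a, b), (p, p_adj, dpsi) in (pairs or {}).items():
        res.pairwise[(a, b)] = PairwiseResult(
            a, b, p, p_adj, pd.Series(dpsi), eligible=True
        )
    return res


class TestHierarchicalFDR:
    def test_nothing_selected_when_all_null(self):
        results = {f"lc{i}": _result(f"lc{i}", p_multi=1.0) for i in range(5)}
        out = hierarchical_fdr(results)
        assert not any(r.selected for r in out.values())

    def test_single_cluster_scale_is_identity(self):
        # R = m = 1: stage-2 level is q, so p_adj is the plain BH value
        res = _result(pairs={("a", "b"): (0.02, None, {"j1": 0.3, "j2": -0.3})})
        out = hierarchical_fdr({"lc1": res})
        assert out["lc1"].selected
        assert out["lc1"].pairwise[("a", "b")].p_adj == pytest.approx(0.02)

    def test_stage2_scaled_by_m_over_r(self):
        results = {
            "sig": _result("sig", 1e-4, {("a", "b"): (0.01, None, {"j1": 0.3})}),
            "null1": _result("null1", 0.9),
            "null2": _result("null2", 0.8),
            "null3": _result("null3", 0.7),
        }
        out = hierarchical_fdr(results)
        assert out["sig"].selected and not out["null1"].selected
        # m=4 tested, R=1 selected -> pairwise p scaled by 4
        assert out["sig"].pairwise[("a", "b")].p_adj == pytest.approx(0.04)

    def test_adjusted_at_least_raw(self):
        results = {
            f"lc{i}": _result(f"lc{i}", p_multi=0.001 * (i + 1),
                              pairs={("a", "b"): (0.01, None, {"j1": 0.5})})
            for i in range(4)
        }
        out = hierarchical_fdr(results)
        for r in out.values():
            assert r.p_multi_adj >= r.p_multi
            for pr in r.pairwise.values():
                if pr.p_adj is not None:
                    assert pr.p_adj >= pr.p


class TestCallDS:
    def base(self, md):
        pairs = {("a", "b"): (0.001, 0.01, md)}
        return _result(pairs=pairs)

    def test_thresholds_met(self):
        res = self.base({"j1": 0.25, "j2": 0.12})
        res.p_multi_adj = 0.01
        assert call_ds(res).is_ds

    def test_needs_two_junctions_at_010(self):
        res = self.base({"j1": 0.25, "j2": 0.05})
        res.p_multi_adj = 0.01
        assert not call_ds(res).is_ds

    def test_needs_one_junction_at_020(self):
        res = self.base({"j1": 0.15, "j2": 0.15})
        res.p_multi_adj = 0.01
        assert not call_ds(res).is_ds

    def test_condition_analysis_skips_condition1(self):
        res = self.base({"j1": 0.25, "j2": 0.12})
        res.p_multi = res.p_multi_adj = None  # no multi stage
        assert not call_ds(res, analysis="healthy").is_ds
        assert call_ds(res, analysis="condition").is_ds

    def test_max_dpsi_uses_significant_comparisons_only(self):
        res = _result(pairs={
            ("a", "b"): (0.001, 0.01, {"j1": 0.1, "j2": 0.1}),
            ("a", "c"): (0.5, 0.9, {"j1": 0.9, "j2": 0.9}),
        })
        md = max_dpsi_per_junction(res)
        assert md["j1"] == pytest.approx(0.1)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            md = {"j1": rng.uniform(0, 0.5), "j2": rng.uniform(0, 0.5)}
            res = self.base(md)
            res.p_multi_adj = 0.01
            if call_ds(res).is_ds:
                assert call_ds(res, dpsi_low=0.05, dpsi_high=0.1).is_ds


def _pattern_result(sig_pairs, dpsi_sign=1.0):
    types = ["B", "T", "NK", "Monocytes", "Neutrophils"]
    res = ClusterTestResult(lc_id="lc", junction_keys=("j1",))
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            key = tuple(sorted((a, b)))
            sig = key in sig_pairs or (key[1], key[0]) in sig_pairs
            res.pairwise[key] = PairwiseResult(
                key[0], key[1], 0.001 if sig else 0.9, 0.01 if sig else 0.9,
                pd.Series({"j1": dpsi_sign * (0.3 if key[0] in ("B", "NK", "T") else -0.3)}),
                eligible=True,
            )
    return res


class TestClassifyPattern:
    def test_cell_type_specific(self):
        sig = {tuple(sorted(("Neutrophils", t))) for t in ("B", "T", "NK", "Monocytes")}
        assert classify_pattern(_pattern_result(sig)) == "cell-type-specific:Neutrophils"

    def test_lineage_specific(self):
        sig = {tuple(sorted((l, m))) for l in ("B", "T", "NK")
               for m in ("Monocytes", "Neutrophils")}
        assert classify_pattern(_pattern_result(sig)) == "lineage-specific"

    def test_single_pair_is_other(self):
        assert classify_pattern(_pattern_result({("B", "T")})) == "other"
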