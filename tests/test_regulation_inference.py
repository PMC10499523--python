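"""Regulator filtering, correlation with PSI, and pattern clustering."""

import numpy as np
import pandas as pd
import pytest

from spliceatlas.errors import ContractError
from spliceatlas.regulation_inference import (
    ExpressionTable,
    RegulatorCorrelation,
    RegulatorSet,
    cluster_patterns,
    correlate,
    correlation_of_correlations,
    cross_dataset_regulator_correlation,
    filter_regulators,
)
from .conftest import make_sheet


def expr_table(values: dict, cell_types, dataset="DS1"):
    sids = [f"{dataset}_s{i}" for i in range(len(cell_types))]
    sheet = make_sheet(sids, dataset=dataset, cell_types=list(cell_types))
    counts = pd.DataFrame(values, index=sids).T
    counts.columns = sids
    counts.index.name = "gene_id"
    return ExpressionTable(counts.astype(np.int64), sheet)


CT = ["B", "B", "B", "NK", "NK", "NK"]


class TestExpressionTable:
    def test_rpm_columns_sum_to_million(self):
        t = expr_table({"g1": [10, 20, 30, 40, 50, 60], "g2": [90, 80, 70, 60, 50, 40]}, CT)
        np.testing.assert_allclose(t.normalized.sum(axis=0), 1e6)


class TestFilterRegulators:
    def make_pair(self, g1_a, g1_b):
        a = expr_table({"g1": g1_a, "bg": [1000] * 6}, CT, "DS1")
        b = expr_table({"g1": g1_b, "bg": [1000] * 6}, CT, "DS2")
        return {"DS1": a, "DS2": b}

    def test_constant_regulator_fails_anova(self):
        expr = self.make_pair([50] * 6, [50] * 6)
        kept = filter_regulators(expr, RegulatorSet("SF", frozenset({"g1"})), "DS1")
        assert kept == []

    def test_single_dataset_expression_excluded(self):
        expr = self.make_pair([500, 400, 600, 5, 4, 6], [0, 0, 0, 0, 0, 0])
        kept = filter_regulators(expr, RegulatorSet("SF", frozenset({"g1"})), "DS1")
        assert kept == []

    def test_strong_cell_type_signal_included(self):
        rng = np.random.default_rng(0)
        a = (np.r_[rng.normal(500, 10, 3), rng.normal(25, 3, 3)]).astype(int).tolist()
        expr = self.make_pair(a, [100] * 6)
        kept = filter_regulators(expr, RegulatorSet("SF", frozenset({"g1"})), "DS1")
        assert kept == ["g1"]

    def test_single_cell_type_is_contract_error(self):
        a = expr_table({"g1": [10] * 6}, ["B"] * 6, "DS1")
        b = expr_table({"g1": [10] * 6}, ["B"] * 6, "DS2")
        with pytest.raises(ContractError):
            filter_regulators({"DS1": a, "DS2": b},
                              RegulatorSet("SF", frozenset({"g1"})), "DS1")


class TestCorrelate:
    def make(self, expr_vals, psi_vals):
        t = expr_table({"reg": expr_vals, "bg": [10000] * 6}, CT)
        psi = pd.DataFrame({s: [v] for s, v in zip(t.counts.columns, psi_vals)},
                           index=["j1"])
        return t, psi

    def test_perfect_positive(self):
        psi_vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        # expression exactly proportional to PSI (depth equalized by bg gene)
        t, psi = self.make([round(1000 * v) for v in psi_vals], psi_vals)
        t.counts.loc["bg"] = 20000 - t.counts.loc["reg"]
        rc = correlate(t, psi, ["reg"], ["j1"])
        assert rc.r.loc["reg", "j1"] == pytest.approx(1.0, abs=1e-9)

    def test_perfect_negative(self):
        psi_vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        t, psi = self.make([round(1000 * (1 - v)) for v in psi_vals], psi_vals)
        t.counts.loc["bg"] = 20000 - t.counts.loc["reg"]
        rc = correlate(t, psi, ["reg"], ["j1"])
        assert rc.r.loc["reg", "j1"] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_is_missing_never_zero(self):
        t, psi = self.make([100] * 6, [0.5] * 6)
        t.counts.loc["bg"] = 20000 - t.counts.loc["reg"]
        rc = correlate(t, psi, ["reg"], ["j1"])
        assert np.isnan(rc.r.loc["reg", "j1"])

    def test_pairwise_deletion_of_undefined_psi(self):
        psi_vals = [0.1, 0.3, np.nan, 0.6, 0.8, np.nan]
        t, psi = self.make([100, 300, 999, 600, 800, 999], psi_vals)
        t.counts.loc["bg"] = 20000 - t.counts.loc["reg"]
        rc = correlate(t, psi, ["reg"], ["j1"])
        assert rc.r.loc["reg", "j1"] == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_defined_is_missing(self):
        t, psi = self.make([100, 300, 1, 1, 1, 1], [0.1, 0.9] + [np.nan] * 4)
        rc = correlate(t, psi, ["reg"], ["j1"])
        assert np.isnan(rc.r.loc["reg", "j1"])

    def test_independent_noise_stays_small(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            sids = [f"s{i}" for i in range(20)]
            sheet = make_sheet(sids, cell_types=["B"] * 20)
            counts = pd.DataFrame(
                {"reg": rng.integers(50, 150, 20), "bg": [5000] * 20},
                index=sids,
            ).T
            counts.index.name = "gene_id"
            t = ExpressionTable(counts, sheet)
            psi = pd.DataFrame({s: [rng.uniform(0, 1)] for s in sids}, index=["j"])
            r = correlate(t, psi, ["reg"], ["j"]).r.iloc[0, 0]
            hits += abs(r) < 0.5
        assert hits >= 38  # >= 95% expected


class TestClusterPatterns:
    def test_identical_profiles_share_cluster(self):
        rng = np.random.default_rng(2)
        sids = [f"s{i}" for i in range(8)]
        profiles = rng.uniform(0, 1, (6, 8))
        profiles[1] = profiles[0]
        psi = pd.DataFrame(profiles, index=[f"j{i}" for i in range(6)], columns=sids)
        t = ExpressionTable(
            pd.DataFrame(rng.integers(50, 500, (4, 8)),
                         index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
                         columns=sids),
            make_sheet(sids, cell_types=["B"] * 8),
        )
        rc = RegulatorCorrelation("SF", pd.DataFrame(
            0.0, index=[f"g{i}" for i in range(4)], columns=[f"j{i}" for i in range(6)]
        ))
        # fewer items than requested clusters: count is lowered with a warning
        with pytest.warns(UserWarning):
            cluster_patterns(rc, psi, t, n_clusters=10)
        # identical profiles land in the same cluster at any non-trivial cut
        rc = cluster_patterns(rc, psi, t, n_clusters=3)
        assert rc.junction_clusters["j0"] == rc.junction_clusters["j1"]

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(3)
        sids = [f"s{i}" for i in range(12)]
        base = np.zeros((30, 12))
        for b in range(3):
            profile = np.zeros(12)
            profile[b * 4:(b + 1) * 4] = 1.0
            base[b * 10:(b + 1) * 10] = profile + rng.normal(0, 0.01, (10, 12))
        psi = pd.DataFrame(base, index=[f"j{i}" for i in range(30)], columns=sids)
        t = ExpressionTable(
            pd.DataFrame(rng.integers(50, 500, (12, 12)),
                         index=pd.Index([f"g{i}" for i in range(12)], name="gene_id"),
                         columns=sids),
            make_sheet(sids, cell_types=["B"] * 12),
        )
        rc = RegulatorCorrelation("SF", pd.DataFrame(
            0.0, index=[f"g{i}" for i in range(12)], columns=list(psi.index)
        ))
        rc = cluster_patterns(rc, psi, t, n_clusters=3)
        labels = rc.junction_clusters
        for b in range(3):
            block = labels[[f"j{i}" for i in range(b * 10, (b + 1) * 10)]]
            assert block.nunique() == 1
        assert labels.nunique() == 3


class TestCrossDataset:
    def test_identical_tables_give_unit_correlations(self):
        cts = ["B", "CD4 T", "CD8 T", "NK", "Monocytes", "Neutrophils"]
        rng = np.random.default_rng(4)
        vals = {f"g{i}": rng.integers(10, 1000, 6).tolist() for i in range(5)}
        a = expr_table(vals, cts, "DS1")
        b = expr_table(vals, cts, "DS2")
        rs, frac = cross_dataset_regulator_correlation(a, b, [f"g{i}" for i in range(5)])
        np.testing.assert_allclose(rs.to_numpy(), 1.0)
        assert frac == pytest.approx(100.0)

    def test_constant_regulator_skipped(self):
        # constant in reads-per-million (uniform depth) in dataset a
        cts = ["B", "NK", "Monocytes", "Neutrophils", "B", "NK"]
        g2 = [1, 5, 9, 14, 2, 6]
        a = expr_table(
            {"g1": [10] * 6, "g2": g2, "bg": [989 - v for v in g2]}, cts, "DS1"
        )
        b = expr_table(
            {"g1": [20, 30, 40, 50, 60, 70], "g2": g2, "bg": [500] * 6}, cts, "DS2"
        )
        rs, _ = cross_dataset_regulator_correlation(a, b, ["g1", "g2"])
        assert "g1" not in rs.index and "g2" in rs.index


class TestCorrelationOfCorrelations:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.uniform(-1, 1, (4, 5)),
                         index=list("abcd"), columns=[f"j{i}" for i in range(5)])
        assert correlation_of_correlations(a, a) == pytest.approx(1.0)
        assert correlation_of_correlations(a, -a) == pytest.approx(-1.0)

    def test_too_few_shared_entries_undefined(self):
        a = pd.DataFrame([[0.5, np.nan]], index=["g"], columns=["j1", "j2"])
        b = pd.DataFrame([[np.nan, 0.5]], index=["g"], columns=["j1", "j2"])
        assert np.isnan(correlation_of_correlations(a, b))
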