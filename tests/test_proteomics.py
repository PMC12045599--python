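"""Protein-group IO, imputation, Welch enrichment calls (against textbook
formulas), proteome consolidation and chi-squared / Spearman statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invkit.errors import ConfigurationError
from invkit.proteomics_enrichment import (_pearson_chi2_2x2,
                                          consolidate_proteomes,
                                          contingency_enrichment,
                                          differential_enrichment,
                                          impute_missing, log2_transform,
                                          overlap_enrichment, QuantTable,
                                          rank_correlation, read_quant_table,
                                          tmd_count_enrichment,
                                          write_quant_table)
from invkit.synthetic_data import LfqSimConfig, simulate_lfq_experiment


def _toy_frame():
    return pd.DataFrame({
        "Protein IDs": ["P1", "P2", "P3", "CON__A", "REV__B"],
        "LFQ intensity inv_R1": [100.0, 0.0, 50.0, 10.0, 10.0],
        "LFQ intensity inv_R2": [110.0, 40.0, 55.0, 10.0, 10.0],
        "LFQ intensity ctrl_R1": [10.0, 35.0, 50.0, 10.0, 10.0],
        "LFQ intensity ctrl_R2": [12.0, 30.0, 0.0, 10.0, 10.0],
        "Potential contaminant": ["", "", "", "+", ""],
        "Reverse": ["", "", "", "", "+"],
        "Only identified by site": ["", "", "", "", ""],
    })


class TestReader:
    def test_flags_and_missing_convention(self):
        table = read_quant_table(_toy_frame())
        assert table.flags.loc["CON__A", "contaminant"]
        assert table.flags.loc["REV__B", "reverse"]
        assert np.isnan(table.values.loc["P2", "inv_R1"])   # 0 -> missing
        assert set(table.samples["condition"]) == {"inv", "ctrl"}
        assert table.filtered().values.shape[0] == 3

    def test_no_intensity_columns_rejected(self):
        with pytest.raises(ConfigurationError):
            read_quant_table(pd.DataFrame({"Protein IDs": ["P1"]}))

    def test_round_trip(self, tmp_path):
        table = read_quant_table(_toy_frame())
        path = tmp_path / "pg.txt"
        write_quant_table(table, path)
        again = read_quant_table(path)
        pd.testing.assert_frame_equal(table.values, again.values)
        pd.testing.assert_frame_equal(table.flags, again.flags)


class TestImputation:
    def _table(self, n_obs, n_miss, mu=25.0, sd=2.0, seed=0):
        rng = np.random.default_rng(seed)
        col = np.concatenate([rng.normal(mu, sd, n_obs),
                              np.full(n_miss, np.nan)])
        values = pd.DataFrame({"s_R1": col, "s_R2": rng.normal(mu, sd,
                                                               n_obs + n_miss)})
        samples = pd.DataFrame({"condition": ["s", "s"], "replicate": [1, 2]},
                               index=["s_R1", "s_R2"])
        flags = pd.DataFrame({"contaminant": False}, index=values.index)
        return QuantTable(values, samples, flags, is_log2=True)

    def test_downshifted_normal_distribution(self):
        table = self._table(10_000, 10_000)
        mu = table.values["s_R1"].mean()
        sd = table.values["s_R1"].std(ddof=1)
        imp = impute_missing(table, shift=1.8, width=0.3, seed=1)
        new = imp.values.loc[table.values["s_R1"].isna(), "s_R1"]
        assert new.mean() == pytest.approx(mu - 1.8 * sd, abs=0.05)
        assert new.std(ddof=1) == pytest.approx(0.3 * sd, abs=0.03)

    def test_observed_values_unchanged_and_deterministic(self):
        table = self._table(50, 20)
        imp1 = impute_missing(table, seed=9)
        imp2 = impute_missing(table, seed=9)
        pd.testing.assert_frame_equal(imp1.values, imp2.values)
        obs = table.values["s_R1"].notna()
        pd.testing.assert_series_equal(imp1.values.loc[obs, "s_R1"],
                                       table.values.loc[obs, "s_R1"])

    def test_complete_table_returned_unchanged(self):
        table = self._table(30, 0)
        imp = impute_missing(table, seed=2)
        pd.testing.assert_frame_equal(imp.values, table.values)

    def test_sample_with_too_few_observed_named_in_error(self):
        table = self._table(1, 10)
        with pytest.raises(ConfigurationError, match="s_R1"):
            impute_missing(table)

    def test_requires_log2(self):
        table = self._table(5, 0)
        table.is_log2 = False
        with pytest.raises(ConfigurationError):
            impute_missing(table)


def _quant_from_values(a_vals, b_vals):
    n = len(a_vals[0])
    cols = {}
    for i, col in enumerate(a_vals, 1):
        cols[f"LFQ intensity a_R{i}"] = col
    for i, col in enumerate(b_vals, 1):
        cols[f"LFQ intensity b_R{i}"] = col
    frame = pd.DataFrame({"Protein IDs": [f"P{j}" for j in range(n)], **cols})
    table = read_quant_table(frame)
    table.values = np.log2(table.values)
    table.is_log2 = True
    return table


class TestDifferentialEnrichment:
    def test_welch_p_matches_textbook_formula(self):
        a = np.array([25.0, 26.5, 24.8])
        b = np.array([22.1, 23.0, 22.5])
        table = _quant_from_values([2.0 ** np.array([v]) for v in a],
                                   [2.0 ** np.array([v]) for v in b])
        res = differential_enrichment(table, "a", "b").iloc[0]
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert res["p"] == pytest.approx(p, rel=1e-9)
        assert res["log2fc"] == pytest.approx(a.mean() - b.mean())
        assert res["class"] == "pink"

    def test_identical_groups_gray_with_p_one(self):
        vals = [np.array([8.0]), np.array([8.0])]
        table = _quant_from_values(vals, vals)
        res = differential_enrichment(table, "a", "b").iloc[0]
        assert res["log2fc"] == 0.0
        assert res["p"] == 1.0
        assert res["class"] == "gray"

    def test_class_rule_is_a_partition(self):
        quant, _, _ = simulate_lfq_experiment(LfqSimConfig(n_proteins=400,
                                                           seed=12))
        table = impute_missing(log2_transform(read_quant_table(quant)), seed=1)
        res = differential_enrichment(table, "pulldown", "control")
        assert res["class"].isin(["pink", "red", "blue", "gray"]).all()
        # boundary semantics: pink <=> FC>2 AND p<0.05
        pink = res["class"] == "pink"
        assert ((res["log2fc"] > 1) & (res["p"] < 0.05)).equals(pink)

    def test_spiked_set_recovery_and_null_calibration(self):
        cfg = LfqSimConfig(seed=42)
        quant, _, gt = simulate_lfq_experiment(cfg)
        table = impute_missing(log2_transform(read_quant_table(quant)), seed=7)
        res = differential_enrichment(table, "pulldown", "control")
        pink = set(res.loc[res["class"] == "pink", "protein"])
        recovery = len(pink & set(gt.enriched)) / len(gt.enriched)
        assert recovery >= 0.9
        nulls = res[~res["protein"].isin(gt.enriched)]
        assert (nulls["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestConsolidation:
    def _run(self, proteins, lfc=2.0):
        return pd.DataFrame({"protein": proteins, "log2fc": lfc,
                             "p": 0.01, "class": "pink"})

    def test_union_with_provenance(self):
        runs = {"wt": self._run(["A", "B", "C"]),
                "ki": self._run(["B", "C", "D"], lfc=3.0)}
        out = consolidate_proteomes(runs)
        assert sorted(out["protein"]) == ["A", "B", "C", "D"]
        flagged_both = out.set_index("protein")[["in_wt", "in_ki"]]
        assert flagged_both.loc["B"].all() and flagged_both.loc["C"].all()
        assert not flagged_both.loc["A", "in_ki"]
        # ranked by max fold enrichment
        assert out["max_log2fc"].is_monotonic_decreasing

    def test_single_run_identity_and_idempotence(self):
        run = self._run(["X", "Y"])
        once = consolidate_proteomes({"r": run})
        assert sorted(once["protein"]) == ["X", "Y"]
        ab = consolidate_proteomes({"a": run, "b": self._run(["Y", "Z"])})
        ba = consolidate_proteomes({"b": self._run(["Y", "Z"]), "a": run})
        pd.testing.assert_frame_equal(
            ab.sort_values("protein").reset_index(drop=True)[ab.columns],
            ba.sort_values("protein").reset_index(drop=True)[ab.columns])

    def test_random_runs_match_set_algebra_oracle(self, rng):
        universe = [f"P{i}" for i in range(60)]
        runs, oracle = {}, {}
        for name in "abc":
            members = list(rng.choice(universe, size=20, replace=False))
            runs[name] = self._run(members)
            oracle[name] = set(members)
        out = consolidate_proteomes(runs)
        assert set(out["protein"]) == oracle["a"] | oracle["b"] | oracle["c"]
        for name in "abc":
            got = set(out.loc[out[f"in_{name}"].fillna(False), "protein"])
            assert got == oracle[name]

    def test_duplicates_merged_with_warning(self):
        run = pd.DataFrame({"protein": ["A", "A"], "log2fc": [1.5, 2.5],
                            "p": 0.01, "class": "pink"})
        with pytest.warns(UserWarning, match="duplicate"):
            out = consolidate_proteomes({"r": run})
        assert len(out) == 1
        assert out["max_log2fc"].iloc[0] == 2.5


class TestContingency:
    def test_worked_2x2_example(self):
        """[[30, 70], [10, 90]] -> chi2 = 12.5 from the closed form."""
        assert _pearson_chi2_2x2(30, 70, 10, 90) == pytest.approx(12.5)
        bg = [f"P{i}" for i in range(200)]
        flag = pd.Series([True] * 30 + [False] * 70 + [True] * 10
                         + [False] * 90, index=bg)
        res = contingency_enrichment(bg[:100], bg, flag)
        assert res.chi2 == pytest.approx(12.5)
        assert res.p == pytest.approx(stats.chi2.sf(12.5, 1))
        assert res.direction == "enriched"

    def test_equal_proportions_give_zero(self):
        bg = [f"P{i}" for i in range(40)]
        flag = pd.Series(([True] * 5 + [False] * 15) * 2, index=bg)
        res = contingency_enrichment(bg[:20], bg, flag)
        assert res.chi2 == 0.0

    def test_matches_scipy_on_1000_random_tables(self, rng):
        """Closed form equals scipy's uncorrected Pearson statistic exactly."""
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 200, size=4)
            ours = _pearson_chi2_2x2(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency([[a, b], [c, d]],
                                         correction=False)[0]
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_zero_expected_count_rejected(self):
        bg = ["A", "B", "C", "D"]
        flag = pd.Series(False, index=bg)
        with pytest.raises(ConfigurationError):
            contingency_enrichment(["A"], bg, flag)

    def test_set_must_be_subset(self):
        with pytest.raises(ConfigurationError):
            contingency_enrichment(["Z"], ["A", "B"],
                                   pd.Series(True, index=["A", "B"]))

    def test_secreted_enrichment_power(self, rng):
        """Doubled annotation prevalence in a 600-protein set inside a
        2000-protein background is detected in >= 95% of simulations."""
        hits = 0
        for _ in range(100):
            flags = np.concatenate([rng.random(600) < 0.144,
                                    rng.random(1400) < 0.072])
            bg = [f"P{i}" for i in range(2000)]
            res = contingency_enrichment(bg[:600], bg,
                                         pd.Series(flags, index=bg))
            hits += res.p < 0.05
        assert hits >= 95

    def test_tmd_count_tables(self):
        bg = [f"P{i}" for i in range(100)]
        tmd = pd.Series([0] * 60 + [1] * 25 + [4] * 15, index=bg)
        out = tmd_count_enrichment(bg[:30], bg, tmd)
        assert set(out["tmd_count"]) == {0, 1, 4}

    def test_overlap_enrichment_both_directions(self):
        bg = [f"P{i}" for i in range(100)]
        a, b = set(bg[:40]), set(bg[20:50])
        out = overlap_enrichment(a, b, bg)
        assert out["overlap"] == 20
        assert out["fraction_of_a"] == pytest.approx(0.5)
        assert out["fraction_of_b"] == pytest.approx(20 / 30)


class TestRankCorrelation:
    def test_monotone_pairs(self):
        rho, _ = rank_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_rank_formula_example(self):
        """(1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6."""
        rho, _ = rank_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_independent_values_near_zero(self, rng):
        rho, _ = rank_correlation(rng.random(1000), rng.random(1000))
        assert abs(rho) < 0.1

    def test_too_few_pairs(self):
        with pytest.raises(ConfigurationError):
            rank_correlation([1, 2, 3], [3, 2, 1])
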