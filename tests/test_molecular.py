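import itertools

import numpy as np
import pandas as pd
import pytest

from fociquant import (
    CtTable,
    IntensityTable,
    abundance_ratio,
    compare_groups,
    ddct_fold_change,
    generate_ct_table,
    relative_intensity,
)


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "gene", "ct"])


class TestCtTableValidation:
    def test_missing_reference_gene_rejected(self):
        frame = ct_frame([("s1", "untreated", "r1", "IFNB1", 25.0)])
        with pytest.raises(ValueError, match="reference gene"):
            CtTable(frame, reference_gene="ACTB")

    def test_duplicate_sample_gene_rejected(self):
        frame = ct_frame([("s1", "untreated", "r1", "ACTB", 20.0),
                          ("s1", "untreated", "r1", "ACTB", 20.5)])
        with pytest.raises(ValueError, match="duplicate"):
            CtTable(frame)


class TestDdctFoldChange:
    def _table(self, target_cts, baseline_cts, ref_ct=20.0):
        rows = []
        for i, ct in enumerate(baseline_cts):
            sid = f"u{i}"
            rows += [(sid, "untreated", f"r{i}", "ACTB", ref_ct),
                     (sid, "untreated", f"r{i}", "IFNB1", ct)]
        for i, ct in enumerate(target_cts):
            sid = f"t{i}"
            rows += [(sid, "cGAMP", f"r{i}", "ACTB", ref_ct),
                     (sid, "cGAMP", f"r{i}", "IFNB1", ct)]
        return CtTable(ct_frame(rows))

    def test_worked_example(self):
        # dCt = 25 - 20 = 5; baseline mean dCt = 7; ddCt = -2; fold = 4
        table = self._table(target_cts=[25.0], baseline_cts=[27.0])
        folds = ddct_fold_change(table)
        row = folds.per_sample.set_index("sample_id").loc["t0"]
        assert row["dct"] == pytest.approx(5.0)
        assert row["ddct"] == pytest.approx(-2.0)
        assert row["fold_change"] == pytest.approx(4.0)

    def test_baseline_sample_at_baseline_mean_has_fold_one(self):
        table = self._table(target_cts=[25.0], baseline_cts=[27.0, 27.0])
        folds = ddct_fold_change(table)
        baseline = folds.per_sample[folds.per_sample["condition"] == "untreated"]
        np.testing.assert_allclose(baseline["fold_change"], 1.0)

    def test_generator_zero_noise_round_trip(self):
        table = generate_ct_table({"cGAMP": {"IFNB1": 8.0}}, n_replicates=3,
                                  ct_noise_sd=0.0, seed=0)
        folds = ddct_fold_change(table)
        treated = folds.per_condition.set_index(["condition", "gene"])
        assert treated.loc[("cGAMP", "IFNB1"), "fold_change_mean"] == pytest.approx(8.0)

    def test_global_sample_shift_leaves_folds_unchanged(self):
        table = self._table(target_cts=[25.0, 26.0], baseline_cts=[27.0, 26.5])
        reference = ddct_fold_change(table).per_sample["fold_change"].to_numpy()
        shifted = table.frame.copy()
        shifted.loc[shifted["sample_id"] == "t0", "ct"] += 3.0  # both genes of t0
        shifted_folds = ddct_fold_change(CtTable(shifted)).per_sample["fold_change"]
        np.testing.assert_allclose(shifted_folds.to_numpy(), reference, rtol=1e-12)

    def test_target_only_shift_changes_folds(self):
        table = self._table(target_cts=[25.0], baseline_cts=[27.0])
        reference = ddct_fold_change(table).per_sample.set_index("sample_id")
        shifted = table.frame.copy()
        shifted.loc[(shifted["sample_id"] == "t0") & (shifted["gene"] == "IFNB1"), "ct"] += 1.0
        result = ddct_fold_change(CtTable(shifted)).per_sample.set_index("sample_id")
        assert result.loc["t0", "fold_change"] == pytest.approx(
            reference.loc["t0", "fold_change"] / 2.0)

    def test_noisy_log2_fold_recovery(self):
        # Ct noise s.d. 0.2, n=3: recovered log2 folds within +/-0.5
        for seed, true_fold in zip(range(12), itertools.cycle([0.25, 1.0, 4.0, 16.0])):
            table = generate_ct_table({"cGAMP": {"g": true_fold}}, n_replicates=3,
                                      ct_noise_sd=0.2, seed=seed)
            folds = ddct_fold_change(table)
            mean_fold = (folds.per_condition.set_index(["condition", "gene"])
                         .loc[("cGAMP", "g"), "fold_change_mean"])
            assert abs(np.log2(mean_fold) - np.log2(true_fold)) <= 0.5


class TestRelativeIntensity:
    def _table(self):
        frame = pd.DataFrame({
            "lane_id": ["u1", "u2", "t1"],
            "condition": ["untreated", "untreated", "cGAMP"],
            "target_band_volume": [1000.0, 1000.0, 2000.0],
            "loading_control_volume": [1000.0, 1000.0, 1000.0],
        })
        return IntensityTable(frame)

    def test_worked_example(self):
        folds = relative_intensity(self._table())
        assert folds.per_sample.set_index("lane_id").loc["t1", "fold_change"] == pytest.approx(2.0)

    def test_reference_lane_relative_to_itself_is_one(self):
        folds = relative_intensity(self._table())
        reference = folds.per_sample[folds.per_sample["condition"] == "untreated"]
        np.testing.assert_allclose(reference["fold_change"], 1.0)

    def test_baseline_mean_relative_value_is_one(self, rng):
        frame = pd.DataFrame({
            "lane_id": [f"l{i}" for i in range(6)],
            "condition": ["untreated"] * 3 + ["treated"] * 3,
            "target_band_volume": rng.uniform(500, 3000, 6),
            "loading_control_volume": rng.uniform(800, 1200, 6),
        })
        folds = relative_intensity(IntensityTable(frame))
        baseline = folds.per_sample[folds.per_sample["condition"] == "untreated"]
        assert baseline["fold_change"].mean() == pytest.approx(1.0)

    def test_invariant_under_global_volume_rescaling(self, rng):
        frame = pd.DataFrame({
            "lane_id": [f"l{i}" for i in range(6)],
            "condition": ["untreated"] * 3 + ["treated"] * 3,
            "target_band_volume": rng.uniform(500, 3000, 6),
            "loading_control_volume": rng.uniform(800, 1200, 6),
        })
        base = relative_intensity(IntensityTable(frame)).per_sample["fold_change"]
        scaled_frame = frame.copy()
        scaled_frame[["target_band_volume", "loading_control_volume"]] *= 10.0
        scaled = relative_intensity(IntensityTable(scaled_frame)).per_sample["fold_change"]
        np.testing.assert_allclose(scaled.to_numpy(), base.to_numpy(), rtol=1e-12)

    def test_zero_loading_control_blocked(self):
        frame = pd.DataFrame({
            "lane_id": ["l1"], "condition": ["untreated"],
            "target_band_volume": [100.0], "loading_control_volume": [0.0],
        })
        with pytest.raises(ValueError, match="strictly positive"):
            IntensityTable(frame)


class TestAbundanceRatio:
    def test_worked_examples(self):
        assert abundance_ratio([8, 8, 8], [1, 1, 1]) == pytest.approx(8.0)
        assert abundance_ratio([3.5, 2.5], [3.5, 2.5]) == pytest.approx(1.0)

    def test_matches_direct_mean_ratio(self, rng):
        for _ in range(10):
            treated = rng.uniform(0.1, 10, size=5)
            untreated = rng.uniform(0.1, 10, size=4)
            assert abundance_ratio(treated, untreated) == pytest.approx(
                treated.mean() / untreated.mean(), rel=1e-12)

    def test_zero_untreated_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            abundance_ratio([1.0], [0.0])


def two_way_anova_by_hand(data):
    """Textbook balanced two-factor sum-of-squares decomposition."""
    y = data["_y"] if "_y" in data else data["fold_change"]
    grand = y.mean()
    a_levels = data["condition"].unique()
    b_levels = data["gene"].unique()
    n = len(data) / (len(a_levels) * len(b_levels))
    ss_a = sum(len(data[data["condition"] == a]) * (data[data["condition"] == a]
               ["fold_change"].mean() - grand) ** 2 for a in a_levels)
    ss_b = sum(len(data[data["gene"] == b]) * (data[data["gene"] == b]
               ["fold_change"].mean() - grand) ** 2 for b in b_levels)
    ss_cells = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = data[(data["condition"] == a) & (data["gene"] == b)]["fold_change"]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = data[(data["condition"] == a) & (data["gene"] == b)]["fold_change"]
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(data) - len(a_levels) * len(b_levels)
    return {
        "condition": (ss_a / df_a) / (ss_err / df_err),
        "gene": (ss_b / df_b) / (ss_err / df_err),
        "interaction": (ss_ab / df_ab) / (ss_err / df_err),
    }


def permutation_p_value(a, b, n_perm=2000, seed=0):
    """Two-sample permutation test on the difference of means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(np.mean(a) - np.mean(b))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


class _Folds:
    def __init__(self, frame):
        self.per_sample = frame
        self.per_condition = pd.DataFrame()
        self.baseline_condition = "untreated"


class TestCompareGroups:
    def _frame(self, values_by_cell, n=3):
        rows = []
        for (cond, gene), values in values_by_cell.items():
            for i, value in enumerate(values):
                rows.append({"sample_id": f"{cond}{gene}{i}", "condition": cond,
                             "replicate": f"r{i}", "gene": gene, "fold_change": value})
        return pd.DataFrame(rows)

    def test_identical_constant_groups_give_p_one(self):
        frame = self._frame({(c, g): [2.0, 2.0, 2.0]
                             for c in ("untreated", "cGAMP") for g in ("a", "b")})
        result = compare_groups(_Folds(frame), ["condition", "gene"])
        assert (result["tukey"]["p_adj"].astype(float) == 1.0).all()

    def test_separated_groups_rejected_and_permutation_oracle_agrees(self, rng):
        a = 1.0 + 0.01 * rng.standard_normal(6)
        b = 10.0 + 0.01 * rng.standard_normal(6)
        frame = self._frame({("untreated", "g"): a, ("cGAMP", "g"): b})
        result = compare_groups(_Folds(frame), ["condition"])
        p_adj = result["tukey"]["p_adj"].astype(float).iloc[0]
        assert p_adj < 0.001
        assert permutation_p_value(a, b) < 0.05

    def test_two_by_two_f_statistics_match_manual_decomposition(self, rng):
        frame = self._frame({(c, g): rng.uniform(0.5, 4.0, size=4)
                             for c in ("untreated", "cGAMP") for g in ("a", "b")})
        result = compare_groups(_Folds(frame), ["condition", "gene"])
        manual = two_way_anova_by_hand(frame)
        anova = result["anova"].set_index("term")
        assert anova.loc["C(condition)", "F"] == pytest.approx(manual["condition"], abs=1e-8)
        assert anova.loc["C(gene)", "F"] == pytest.approx(manual["gene"], abs=1e-8)
        assert anova.loc["C(condition):C(gene)", "F"] == pytest.approx(
            manual["interaction"], abs=1e-8)

    def test_design_validation(self):
        frame = self._frame({("untreated", "g"): [1.0, 1.1]})
        with pytest.raises(ValueError, match="at least 2 levels"):
            compare_groups(_Folds(frame), ["condition"])
        sparse = self._frame({("untreated", "g"): [1.0, 1.1],
                              ("cGAMP", "g"): [2.0]})
        with pytest.raises(ValueError, match="at least 2 replicates"):
            compare_groups(_Folds(sparse), ["condition"])
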