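"""ANOVA with eta-squared and Bonferroni post-hoc comparisons."""

import numpy as np
import pandas as pd
import pytest

from ctdcsim.stats import anova_eta, bonferroni_posthoc, field_observations


def _balanced_table(cell_means, n_per_cell=8, noise_sd=0.0, seed=0):
    """Factorial table from a dict {(levelA, levelB, ...): mean}."""
    rng = np.random.default_rng(seed)
    rows = []
    factors = None
    for levels, mu in cell_means.items():
        factors = [f"f{i}" for i in range(len(levels))]
        for _ in range(n_per_cell):
            row = dict(zip(factors, levels))
            row["y"] = mu + (rng.normal(scale=noise_sd) if noise_sd else 0.0)
            rows.append(row)
    return pd.DataFrame(rows), factors


class TestAnova:
    def test_constant_response_gives_zero_eta_everywhere(self):
        table, factors = _balanced_table(
            {(a, b): 5.0 for a in "xy" for b in "pq"}, n_per_cell=4
        )
        res = anova_eta(table, "y", factors)
        terms = res.table.drop(index="Residual")
        assert np.allclose(terms["eta_sq"].to_numpy(dtype=float), 0.0)

    def test_fully_determining_factor_has_eta_one(self):
        table, factors = _balanced_table({("a",): 1.0, ("b",): 3.0}, n_per_cell=10)
        res = anova_eta(table, "y", factors)
        assert res.table.loc["f0", "eta_sq"] == pytest.approx(1.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-20)

    def test_balanced_2x2_matches_hand_computation(self):
        """Cell means mu_ab on a balanced 2x2 design: SS_A = n_col *
        sum((rowmean - grand)^2) etc., eta^2 = SS/SS_total; compared against
        direct group-mean formulas."""
        mu = {("a", "p"): 1.0, ("a", "q"): 2.0, ("b", "p"): 4.0, ("b", "q"): 3.0}
        n = 6
        table, factors = _balanced_table(mu, n_per_cell=n, noise_sd=0.5, seed=42)
        res = anova_eta(table, "y", factors, ss_type=3)

        y = table["y"].to_numpy()
        grand = y.mean()
        ss_a = sum(
            2 * n * (table.loc[table.f0 == lv, "y"].mean() - grand) ** 2 for lv in "ab"
        )
        ss_b = sum(
            2 * n * (table.loc[table.f1 == lv, "y"].mean() - grand) ** 2 for lv in "pq"
        )
        cellm = table.groupby(["f0", "f1"])["y"].mean()
        ss_cells = sum(
            n * (cellm[k] - grand) ** 2 for k in cellm.index
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_total = float(np.sum((y - grand) ** 2))

        assert res.table.loc["f0", "sum_sq"] == pytest.approx(ss_a, rel=1e-8)
        assert res.table.loc["f1", "sum_sq"] == pytest.approx(ss_b, rel=1e-8)
        assert res.table.loc["f0:f1", "sum_sq"] == pytest.approx(ss_ab, rel=1e-8)
        assert res.table.loc["f0", "eta_sq"] == pytest.approx(ss_a / ss_total, rel=1e-8)
        assert res.ss_total == pytest.approx(ss_total, rel=1e-12)
        # balanced design: decomposition is exact
        assert res.additivity_gap < 1e-8

    def test_three_way_terms_present(self):
        mu = {
            (a, b, c): i * 0.5
            for i, (a, b, c) in enumerate(
                (a, b, c) for a in "xy" for b in "pq" for c in "123"
            )
        }
        table, factors = _balanced_table(mu, n_per_cell=3, noise_sd=0.1, seed=1)
        res = anova_eta(table, "y", factors)
        for term in ["f0", "f1", "f2", "f0:f1", "f0:f2", "f1:f2"]:
            assert term in res.table.index
        assert "f0:f1:f2" not in res.table.index  # pairwise interactions only
        etas = res.table.drop(index="Residual")["eta_sq"].to_numpy(dtype=float)
        assert np.all((etas >= 0) & (etas <= 1))
        assert etas.sum() <= 1.0 + 1e-9

    def test_ss_types_coincide_on_balanced_design(self):
        mu = {("a", "p"): 1.0, ("a", "q"): 2.5, ("b", "p"): 0.5, ("b", "q"): 3.0}
        table, factors = _balanced_table(mu, n_per_cell=5, noise_sd=0.3, seed=7)
        results = {t: anova_eta(table, "y", factors, ss_type=t) for t in (1, 2, 3)}
        for term in ["f0", "f1", "f0:f1"]:
            vals = [results[t].table.loc[term, "sum_sq"] for t in (1, 2, 3)]
            assert vals[0] == pytest.approx(vals[1], rel=1e-10)
            assert vals[1] == pytest.approx(vals[2], rel=1e-10)

    def test_row_permutation_invariance(self):
        mu = {("a", "p"): 1.0, ("a", "q"): 2.0, ("b", "p"): 4.0, ("b", "q"): 3.0}
        table, factors = _balanced_table(mu, n_per_cell=4, noise_sd=0.4, seed=3)
        res0 = anova_eta(table, "y", factors)
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        res1 = anova_eta(shuffled, "y", factors)
        pd.testing.assert_frame_equal(res0.table, res1.table)

    def test_response_rescaling_leaves_eta_unchanged(self):
        mu = {("a", "p"): 1.0, ("a", "q"): 2.0, ("b", "p"): 4.0, ("b", "q"): 3.0}
        table, factors = _balanced_table(mu, n_per_cell=4, noise_sd=0.4, seed=5)
        res0 = anova_eta(table, "y", factors)
        scaled = table.assign(y=table["y"] * 7.3)
        res1 = anova_eta(scaled, "y", factors)
        a = res0.table.drop(index="Residual")["eta_sq"].to_numpy(dtype=float)
        b = res1.table.drop(index="Residual")["eta_sq"].to_numpy(dtype=float)
        assert np.allclose(a, b, rtol=1e-10)
        # SS scale by c^2
        assert res1.ss_total == pytest.approx(res0.ss_total * 7.3**2, rel=1e-10)

    def test_single_level_factor_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0], "f0": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="level"):
            anova_eta(table, "y", ["f0"])

    def test_empty_cells_rejected_with_cell_list(self):
        table = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "f0": ["a", "a", "a", "b", "b", "b"],
                "f1": ["p", "p", "q", "p", "p", "p"],  # cell (b, q) empty
            }
        )
        with pytest.raises(ValueError, match="empty cells"):
            anova_eta(table, "y", ["f0", "f1"])


class TestBonferroni:
    def test_number_of_comparisons(self):
        table = pd.DataFrame(
            {
                "y": np.arange(20, dtype=float),
                "g": np.repeat(list("abcd"), 5),
            }
        )
        out = bonferroni_posthoc(table, "y", "g")
        assert len(out) == 4 * 3 // 2
        assert out.attrs["per_comparison_alpha"] == pytest.approx(0.05 / 6)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        table = pd.DataFrame(
            {"y": np.concatenate([base, base]), "g": ["a"] * 30 + ["b"] * 30}
        )
        out = bonferroni_posthoc(table, "y", "g")
        row = out.iloc[0]
        assert row["ci_low"] <= 0.0 <= row["ci_high"]
        assert not row["significant"]

    def test_widely_separated_groups_significant(self):
        """Two groups 10 pooled SDs apart at n=50 per group."""
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(10.0, 1.0, 50)
        table = pd.DataFrame({"y": np.concatenate([a, b]), "g": ["a"] * 50 + ["b"] * 50})
        out = bonferroni_posthoc(table, "y", "g")
        row = out.iloc[0]
        assert row["significant"]
        # direct t statistic from group summaries
        se = np.sqrt(((a.var(ddof=1) * 49 + b.var(ddof=1) * 49) / 98) * (2 / 50))
        assert abs(row["t"]) == pytest.approx(abs(a.mean() - b.mean()) / se, rel=1e-10)

    def test_single_level_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            bonferroni_posthoc(table, "y", "g")

    def test_uses_model_mse_when_anova_given(self):
        mu = {("a", "p"): 1.0, ("a", "q"): 2.0, ("b", "p"): 4.0, ("b", "q"): 3.0}
        table, factors = _balanced_table(mu, n_per_cell=6, noise_sd=0.5, seed=11)
        res = anova_eta(table, "y", factors)
        out = bonferroni_posthoc(table, "y", "f0", anova=res)
        assert len(out) == 1
        # the pooled SE uses the model residual MS, not the one-way variance
        se_expected = np.sqrt(res.mse * (1 / 12 + 1 / 12))
        assert out.iloc[0]["se"] == pytest.approx(se_expected, rel=1e-12)


class TestFieldObservations:
    def test_table_shape_and_factors(self, head_system, parc, sampler):
        from ctdcsim.fem import make_montage_preset
        from ctdcsim.roi import rasterize_field

        frames = []
        for preset in ("celnik", "hd4x1"):
            sol = head_system.solve(
                make_montage_preset(preset, head_system.mesh.outer_radius)
            )
            fv = rasterize_field(sol, parc.affine, parc.shape, sampler=sampler)
            frames.append(
                field_observations(
                    fv, parc, montage=preset, max_voxels_per_lobule=40, seed=1
                )
            )
        obs = pd.concat(frames, ignore_index=True)
        assert set(obs["montage"]) == {"celnik", "hd4x1"}
        assert obs["lobule"].nunique() == 28
        assert np.isfinite(obs["Enorm"]).all()
        res = anova_eta(obs, "Enorm", ["lobule", "montage"])
        etas = res.table.drop(index="Residual")["eta_sq"].to_numpy(dtype=float)
        assert np.all((etas >= 0) & (etas <= 1))
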