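"""ANOVA decompositions, heritability, and correlations.

The balanced-design sums of squares are checked against a brute-force
deviation-sum oracle and against statsmodels' OLS decomposition.
"""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_table
from ilqtl.anova import (combined_anova, correlation_matrix, heritability,
                         separate_anova)


def brute_force_one_way(groups: list[np.ndarray]):
    """SS_G and SS_E straight from the definitions."""
    y = np.concatenate(groups)
    grand = y.mean()
    ss_g = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_e = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return ss_g, ss_e


def brute_force_two_way(cube: np.ndarray):
    """Balanced two-way SS from cell deviations; cube[i, j, r]."""
    a, b, r = cube.shape
    grand = cube.mean()
    gm = cube.mean(axis=(1, 2))
    tm = cube.mean(axis=(0, 2))
    cm = cube.mean(axis=2)
    ss_g = b * r * ((gm - grand) ** 2).sum()
    ss_t = a * r * ((tm - grand) ** 2).sum()
    ss_gt = r * ((cm - gm[:, None] - tm[None, :] + grand) ** 2).sum()
    ss_e = ((cube - cm[:, :, None]) ** 2).sum()
    return ss_g, ss_t, ss_gt, ss_e


def long_from_cube(cube, treatments=("control", "75mM", "150mM")):
    a, b, r = cube.shape
    rows = []
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append({"line_id": f"L{i}", "treatment": treatments[j],
                             "replicate": k + 1, "trait": "Y",
                             "value": cube[i, j, k]})
    return pd.DataFrame(rows)


class TestSeparateAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_lines, r = rng.integers(3, 8), rng.integers(2, 5)
        groups = [rng.normal(10, 2, r) for _ in range(n_lines)]
        table = balanced_table({f"L{i}": {"control": list(g)}
                                for i, g in enumerate(groups)})
        res = separate_anova(table, "Y", "control")
        ss_g, ss_e = brute_force_one_way(groups)
        assert res.terms.loc["G", "ss"] == pytest.approx(ss_g, abs=1e-10)
        assert res.terms.loc["error", "ss"] == pytest.approx(ss_e, abs=1e-10)

    def test_hand_computed_three_by_three(self):
        # groups (1,2,3), (2,3,4), (6,7,8): grand = 4, SS_G = 42, SS_E = 6
        table = balanced_table({"A": {"c": [1, 2, 3]},
                                "B": {"c": [2, 3, 4]},
                                "C": {"c": [6, 7, 8]}})
        res = separate_anova(table, "Y", "c")
        assert res.terms.loc["G", "ss"] == pytest.approx(42.0)
        assert res.terms.loc["error", "ss"] == pytest.approx(6.0)
        assert res.r_squared == pytest.approx(42 / 48)

    def test_all_identical_values_degenerate(self):
        table = balanced_table({l: {"c": [5.0, 5.0, 5.0]} for l in "ABC"})
        res = separate_anova(table, "Y", "c")
        assert res.terms.loc["G", "ss"] == 0.0
        assert res.r_squared == 0.0

    def test_two_identical_groups_give_p_one(self):
        table = balanced_table({"A": {"c": [1.0, 2.0, 3.0]},
                                "B": {"c": [1.0, 2.0, 3.0]}})
        res = separate_anova(table, "Y", "c")
        assert res.terms.loc["G", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.terms.loc["G", "p"] == pytest.approx(1.0)

    def test_cv_percent_definition(self):
        rng = np.random.default_rng(9)
        table = balanced_table({f"L{i}": {"c": list(rng.normal(50, 5, 3))}
                                for i in range(5)})
        res = separate_anova(table, "Y", "c")
        assert res.cv_percent == pytest.approx(
            100 * math.sqrt(res.ms_error) / res.grand_mean)


class TestCombinedAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cube = rng.normal(10, 2, size=(6, 3, 3))
        res = combined_anova(long_from_cube(cube), "Y")
        expect = brute_force_two_way(cube)
        for term, ss in zip(("G", "T", "G:T", "error"), expect):
            assert res.terms.loc[term, "ss"] == pytest.approx(ss, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(4)
        cube = rng.normal(0, 1, size=(5, 3, 2))
        df = long_from_cube(cube).rename(columns={"line_id": "G",
                                                  "treatment": "T"})
        fit = smf.ols("value ~ C(G) + C(T) + C(G):C(T)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        res = combined_anova(long_from_cube(cube), "Y")
        assert res.terms.loc["G", "ss"] == pytest.approx(
            ref.loc["C(G)", "sum_sq"], rel=1e-8)
        assert res.terms.loc["G:T", "ss"] == pytest.approx(
            ref.loc["C(G):C(T)", "sum_sq"], rel=1e-8)

    def test_total_ss_identity(self):
        rng = np.random.default_rng(7)
        cube = rng.normal(10, 3, size=(8, 3, 3))
        res = combined_anova(long_from_cube(cube), "Y")
        total = ((cube - cube.mean()) ** 2).sum()
        assert res.terms["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_no_treatment_effect_means_zero_t_ss(self):
        rng = np.random.default_rng(3)
        base = rng.normal(10, 2, size=(5, 1, 3))
        cube = np.repeat(base, 3, axis=1)  # identical across treatments
        res = combined_anova(long_from_cube(cube), "Y")
        assert res.terms.loc["T", "ss"] == pytest.approx(0.0, abs=1e-10)

    def test_replicate_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        cube = rng.normal(0, 1, size=(4, 3, 3))
        table = long_from_cube(cube)
        shuffled = table.copy()
        shuffled["replicate"] = shuffled.groupby(
            ["line_id", "treatment"])["replicate"].transform(
                lambda s: s.sample(frac=1, random_state=1).to_numpy())
        a = combined_anova(table, "Y").terms["ss"]
        b = combined_anova(shuffled, "Y").terms["ss"]
        assert np.allclose(a, b)

    def test_missing_cell_strict_raises_tolerant_warns(self):
        rng = np.random.default_rng(2)
        cube = rng.normal(0, 1, size=(4, 3, 3))
        table = long_from_cube(cube)
        table = table[~((table.line_id == "L0")
                        & (table.treatment == "75mM"))]
        with pytest.raises(ValueError, match="unbalanced"):
            combined_anova(table, "Y")
        with pytest.warns(UserWarning, match="unbalanced"):
            res = combined_anova(table, "Y", strict_balance=False)
        assert res.terms.loc["G", "ss"] > 0


class TestHeritability:
    def test_closed_form(self):
        table = balanced_table({"A": {"c": [1, 2, 3]}, "B": {"c": [2, 3, 4]},
                                "C": {"c": [6, 7, 8]}})
        res = separate_anova(table, "Y", "c")
        hb = heritability(res, r=3)
        ms_g, ms_e = 21.0, 1.0
        assert hb.hb_percent == pytest.approx(100 * (1 - ms_e / ms_g))
        # variance-component route agrees with the mean-square shortcut
        assert hb.sigma2_p == pytest.approx(hb.sigma2_g + hb.sigma2_e / 3)

    def test_truncation_when_ms_g_below_ms_e(self):
        table = balanced_table({"A": {"c": [1.0, 5.0, 3.0]},
                                "B": {"c": [3.0, 1.0, 5.0]}})
        hb = heritability(separate_anova(table, "Y", "c"), r=3)
        assert hb.sigma2_g == 0.0
        assert hb.hb_percent == 0.0

    def test_requires_separate_model(self):
        rng = np.random.default_rng(0)
        cube = rng.normal(0, 1, size=(3, 3, 2))
        comb = combined_anova(long_from_cube(cube), "Y")
        with pytest.raises(ValueError):
            heritability(comb, r=2)


def test_genotype_f_test_type_one_error():
    """Under the null the G-term F test rejects at ~ the nominal 5% rate."""
    rng = np.random.default_rng(314159)
    sims, n_lines, r = 1000, 10, 3
    hits = 0
    for _ in range(sims):
        values = rng.normal(0.0, 1.0, (n_lines, r))
        table = pd.DataFrame({
            "line_id": np.repeat([f"L{i}" for i in range(n_lines)], r),
            "treatment": "c",
            "replicate": np.tile(np.arange(1, r + 1), n_lines),
            "trait": "Y", "value": values.ravel()})
        res = separate_anova(table, "Y", "c")
        hits += res.terms.loc["G", "p"] < 0.05
    assert abs(hits / sims - 0.05) <= 0.02


class TestCorrelations:
    def _table(self, rng, n=30):
        rows = []
        shl = rng.normal(9, 1.5, n)
        rl = rng.normal(10, 1.5, n)
        for i in range(n):
            for trait, v in (("ShL", shl[i]), ("RL", rl[i]),
                             ("SL", shl[i] + rl[i]), ("NEG", -shl[i])):
                rows.append({"line_id": f"L{i}", "treatment": "control",
                             "replicate": 1, "trait": trait, "value": v})
        return pd.DataFrame(rows)

    def test_diagonal_is_one_and_symmetry(self, rng):
        r, p = correlation_matrix(self._table(rng), "control",
                                  ["ShL", "RL", "SL"])
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T.to_numpy())

    def test_component_sum_strongly_positive(self, rng):
        r, _ = correlation_matrix(self._table(rng), "control",
                                  ["ShL", "RL", "SL"])
        assert r.loc["ShL", "SL"] > 0.5

    def test_anticorrelated_pair_negative(self, rng):
        r, _ = correlation_matrix(self._table(rng), "control",
                                  ["ShL", "NEG"])
        assert r.loc["ShL", "NEG"] == pytest.approx(-1.0)

    def test_zero_variance_trait_is_missing(self, rng):
        table = self._table(rng)
        table.loc[table["trait"] == "RL", "value"] = 7.0
        with pytest.warns(UserWarning):
            r, _ = correlation_matrix(table, "control", ["ShL", "RL"])
        assert math.isnan(r.loc["ShL", "RL"])
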