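"""Reaction-phenotyping arithmetic, correlation attribution, group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyp2b11kit.phenotyping import (
    DOG_LIVER_CYP_ABUNDANCE,
    diplotype_association,
    extrapolate_to_microsomes,
    group_compare,
    holm_sidak,
    spearman_corr,
    specific_activity,
)


class TestSpecificActivity:
    def test_basic_rate(self):
        assert specific_activity(100, 10, 1) == pytest.approx(10.0)

    def test_zero_metabolite(self):
        assert specific_activity(0, 10, 1) == 0.0

    def test_homogeneity(self):
        assert specific_activity(2 * 50, 2 * 5, 1) == pytest.approx(specific_activity(50, 5, 1))

    @pytest.mark.parametrize("amount,time,cat", [(1, 0, 1), (1, 1, 0), (1, -2, 1), (-1, 1, 1)])
    def test_invalid_inputs(self, amount, time, cat):
        with pytest.raises(ValueError):
            specific_activity(amount, time, cat)


class TestExtrapolation:
    def test_two_isoform_fractions_from_hepatic_abundances(self):
        # equal per-pmol rates: fractions follow the 79 vs 125 pmol/mg abundances
        df = extrapolate_to_microsomes({"CYP2B11": 1.0, "CYP3A12": 1.0})
        fr = dict(zip(df["cyp"], df["fraction"]))
        assert fr["CYP2B11"] == pytest.approx(79 / 204)
        assert fr["CYP3A12"] == pytest.approx(125 / 204)

    def test_zero_abundance_isoform_contributes_nothing(self):
        df = extrapolate_to_microsomes({"a": 1.0, "b": 1.0}, {"a": 10.0, "b": 0.0})
        fr = dict(zip(df["cyp"], df["fraction"]))
        assert fr["b"] == 0.0 and fr["a"] == 1.0

    def test_fractions_sum_to_one_and_scale_invariant(self):
        rates = {k: i + 1.0 for i, k in enumerate(DOG_LIVER_CYP_ABUNDANCE)}
        df1 = extrapolate_to_microsomes(rates)
        df2 = extrapolate_to_microsomes({k: 7.3 * v for k, v in rates.items()})
        assert df1["fraction"].sum() == pytest.approx(1.0)
        assert np.allclose(df1["fraction"], df2["fraction"])

    def test_linearity_in_abundance(self):
        ab = {"a": 10.0, "b": 5.0}
        base = extrapolate_to_microsomes({"a": 2.0, "b": 3.0}, ab).set_index("cyp")
        ab2 = {"a": 20.0, "b": 5.0}
        doubled = extrapolate_to_microsomes({"a": 2.0, "b": 3.0}, ab2).set_index("cyp")
        assert doubled.loc["a", "microsomal_rate"] == pytest.approx(2 * base.loc["a", "microsomal_rate"])
        assert doubled.loc["b", "microsomal_rate"] == pytest.approx(base.loc["b", "microsomal_rate"])

    def test_missing_abundance_for_active_isoform(self):
        with pytest.raises(KeyError, match="CYPX"):
            extrapolate_to_microsomes({"CYPX": 1.0}, {"CYP2B11": 79.0})

    def test_percent_of_pool(self):
        df = extrapolate_to_microsomes({"a": 1.0}, {"a": 50.0}, pooled_rate=100.0)
        assert df.loc[0, "percent_of_pool"] == pytest.approx(50.0)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rs_up, _ = spearman_corr(x, [2.0, 3.0, 5.0, 7.0, 11.0])
        rs_dn, _ = spearman_corr(x, [11.0, 7.0, 5.0, 3.0, 2.0])
        assert rs_up == pytest.approx(1.0)
        assert rs_dn == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        rs, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rs) and np.isnan(p)

    @pytest.mark.parametrize("n", [5, 7])
    def test_exact_p_matches_enumeration(self, n):
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        rs, p = spearman_corr(x, y)
        # independent oracle: loop scipy.spearmanr over every pairing of y
        obs = abs(stats.spearmanr(x, y).statistic)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            count += abs(r) >= obs - 1e-12
            total += 1
        assert rs == pytest.approx(stats.spearmanr(x, y).statistic)
        assert p == pytest.approx(count / total)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=15)
        y = 0.8 * x + rng.normal(size=15)
        rs, p = spearman_corr(x, y)
        t = rs * np.sqrt(13 / (1 - rs**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=13))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2, 3], [1, 2, 3])


class TestGroupCompare:
    def test_holm_sidak_closed_form(self):
        adj = holm_sidak([0.01, 0.04, 0.30])
        expected = [1 - 0.99**3, 1 - 0.96**2, 0.30]
        assert np.allclose(adj, expected)

    def test_log_t_equals_t_on_logs(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        b = 3.0 * a  # multiplicative shift
        res = group_compare({"A": a, "B": b}, test="log_t")
        t, p = stats.ttest_ind(np.log(a), np.log(b))
        assert res["statistic"] == pytest.approx(float(t))
        assert res["p_value"] == pytest.approx(float(p))

    def test_identical_groups_mannwhitney(self):
        res = group_compare({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}, test="mannwhitney")
        assert res["p_value"] == pytest.approx(1.0)

    def test_nonpositive_under_log_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            group_compare({"A": [1.0, 0.0], "B": [1.0, 2.0]}, test="log_t")

    def test_anova_with_adjusted_pairwise(self):
        rng = np.random.default_rng(6)
        groups = {"g1": rng.lognormal(0, 0.2, 5), "g2": rng.lognormal(1, 0.2, 5),
                  "g3": rng.lognormal(0, 0.2, 5)}
        res = group_compare(groups, test="anova_holm_sidak")
        assert res["p_value"] < 0.05
        assert set(res["pairwise"]) == {"g1 vs g2", "g1 vs g3", "g2 vs g3"}
        for pair in res["pairwise"].values():
            assert pair["adjusted_p"] >= pair["raw_p"] - 1e-12


class TestDiplotypeAssociation:
    @staticmethod
    def cohort(rng, n_ref=5, n_carrier=10, carrier_protein_scale=0.3, noise=0.1):
        rows = []
        for i in range(n_ref + n_carrier):
            carrier = i >= n_ref
            mrna = rng.lognormal(0, noise)
            protein = mrna * (carrier_protein_scale if carrier else 1.0) * rng.lognormal(0, noise)
            rows.append({
                "liver_id": f"L{i}", "diplotype": "H1/H2" if carrier else "H1/H1",
                "protein": protein, "mrna": mrna, "protein_mrna_ratio": protein / mrna,
            })
        return pd.DataFrame(rows)

    def test_reduced_translation_detected(self):
        rng = np.random.default_rng(9)
        livers = self.cohort(rng)
        res = diplotype_association(livers, ["protein_mrna_ratio", "mrna"])
        row = res.set_index("phenotype").loc["protein_mrna_ratio"]
        assert row["carrier_median"] == pytest.approx(0.3 * row["ref_median"], rel=0.35)
        assert row["p_value"] < 0.05
        assert res.set_index("phenotype").loc["mrna", "p_value"] > 0.05

    def test_identical_groups_p_one(self):
        livers = pd.DataFrame({
            "liver_id": list("abcdef"),
            "diplotype": ["H1/H1"] * 3 + ["H1/H2"] * 3,
            "ratio": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        })
        res = diplotype_association(livers, ["ratio"])
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_permutation_type_i_error(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=15)
        n_rep = 1000
        rejections = 0
        for _ in range(n_rep):
            labels = np.array(["H1/H1"] * 5 + ["H1/H2"] * 10)
            rng.shuffle(labels)
            df = pd.DataFrame({"liver_id": range(15), "diplotype": labels, "v": values})
            p = diplotype_association(df, ["v"]).loc[0, "p_value"]
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.03  # exact test is conservative-to-nominal

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"liver_id": [1], "diplotype": ["H1/H1"], "v": [1.0]})
        with pytest.raises(ValueError):
            diplotype_association(df, ["v"])
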