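"""Allele frequencies, EM phasing, LD, diplotype arithmetic, group tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cyp2b11kit import popgen
from cyp2b11kit.popgen import (
    DiplotypeCounts,
    breed_group_compare,
    em_phase,
    haplotype_freqs_from_diplotypes,
    ld_r2,
    mann_whitney_u,
    round_half_up,
    wilson_ci,
)
from cyp2b11kit.variants import GenotypeCall, HaplotypeSet

from conftest import grid_search_two_site, make_two_snp_panel, two_site_loglik


def wilson_closed_form(k, n, conf=0.95):
    """Textbook score-interval formula, independent of the implementation path."""
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    return center - half, center + half


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (26, 26, 0.87, 1.00),  # fixed on all chromosomes
            (5, 26, 0.09, 0.38),   # low-frequency variant
            (0, 26, 0.00, None),
        ],
    )
    def test_printed_bounds_at_two_decimals(self, k, n, lo, hi):
        est = wilson_ci(k, n)
        assert round(est.ci_low, 2) == lo
        if hi is not None:
            assert round(est.ci_high, 2) == hi

    def test_matches_closed_form(self):
        for k in (0, 1, 5, 13, 21, 26):
            est = wilson_ci(k, 26)
            lo, hi = wilson_closed_form(k, 26)
            assert est.ci_low == pytest.approx(max(lo, 0.0), abs=1e-12)
            assert est.ci_high == pytest.approx(min(hi, 1.0), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(k=st.integers(0, 200), n=st.integers(1, 200))
    def test_bounds_bracket_the_estimate(self, k, n):
        if k > n:
            k = n
        est = wilson_ci(k, n)
        assert 0.0 <= est.ci_low <= est.p_hat <= est.ci_high <= 1.0


class TestAlleleFrequencies:
    def test_missing_excluded_pairwise(self, two_snp_variants):
        vA, vB = two_snp_variants
        panel = [
            GenotypeCall("d1", {vA.id: ("A", "A"), vB.id: ("C", "T")}),
            GenotypeCall("d2", {vA.id: (".", "."), vB.id: ("C", "C")}),
        ]
        freqs = popgen.allele_frequencies(panel, two_snp_variants)
        assert freqs[vA.id].n == 2 and freqs[vA.id].k == 2
        assert freqs[vB.id].n == 4 and freqs[vB.id].k == 1


class TestEmPhase:
    def test_all_homozygous_read_off_directly(self, two_snp_variants):
        panel = make_two_snp_panel({(0, 0): 3, (2, 2): 1}, two_snp_variants)
        res = em_phase(panel, two_snp_variants)
        freqs = res.haplotypes.frequencies["em"]
        by_alleles = {
            "".join(res.haplotypes.haplotypes[lab]): f for lab, f in freqs.items()
        }
        assert by_alleles == pytest.approx({"GC": 0.75, "AT": 0.25})
        assert res.converged

    def test_single_het_site_unambiguous(self, two_snp_variants):
        panel = make_two_snp_panel({(1, 0): 1}, two_snp_variants)
        res = em_phase(panel, two_snp_variants, prune_threshold=0.0)
        freqs = sorted(res.haplotypes.frequencies["em"].values())
        assert freqs == pytest.approx([0.5, 0.5])

    def test_fixed_point_matches_grid_search_oracle(self, two_snp_variants):
        # counts chosen so the double heterozygote makes phase genuinely
        # ambiguous and the MLE is interior
        counts = {(0, 0): 20, (1, 0): 14, (0, 1): 9, (1, 1): 12, (2, 0): 4,
                  (0, 2): 3, (2, 1): 2, (1, 2): 3, (2, 2): 1}
        panel = make_two_snp_panel(counts, two_snp_variants)
        res = em_phase(panel, two_snp_variants, prune_threshold=0.0)
        em_f = {"".join(a): res.haplotypes.frequencies["em"][lab]
                for lab, a in res.haplotypes.haplotypes.items()}
        em_vec = np.array([em_f.get(h, 0.0) for h in ("GC", "GT", "AC", "AT")])
        grid_vec, grid_ll = grid_search_two_site(counts)
        assert np.allclose(em_vec, grid_vec, atol=2e-3)
        assert two_site_loglik(em_vec, counts) >= grid_ll - 1e-6

    def test_loglik_monotone_and_missing_marginalised(self, two_snp_variants):
        vA, vB = two_snp_variants
        panel = make_two_snp_panel({(1, 1): 5, (0, 0): 5, (2, 2): 2}, two_snp_variants)
        panel.append(GenotypeCall("miss", {vA.id: ("G", "A"), vB.id: (".", ".")}))
        res = em_phase(panel, two_snp_variants)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-9)
        assert "miss" in res.diplotypes

    def test_empty_panel_rejected(self, two_snp_variants):
        with pytest.raises(ValueError):
            em_phase([], two_snp_variants)


class TestLd:
    def test_complete_linkage_in_greyhound_pool(self, hapset, variants):
        res = ld_r2(hapset, "greyhound", "#3", "#5", variants)
        assert res.r2 == pytest.approx(1.0)
        assert res.displayed_r2_percent == 100

    def test_independent_sites_have_zero_d(self, variants):
        pool = HaplotypeSet(
            site_order=["#3", "#5"],
            haplotypes={
                "a": ("TCA", "TG"), "b": ("TCA", "CA"),
                "c": ("TCCA", "TG"), "d": ("TCCA", "CA"),
            },
            counts={"p": {"a": 9, "b": 3, "c": 3, "d": 1}},  # p(AB) = pA * pB
        )
        res = ld_r2(pool, "p", "#3", "#5", variants)
        assert res.D == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_never_cooccurring_rare_variants(self, hapset, variants):
        # variant alleles of #4 (3/90) and #5 (16/90) sit on disjoint
        # haplotypes, so D = -pA*pB; frozen from direct hand arithmetic:
        # D^2 / (pA qA pB qB) with pA=1/30, pB=8/45
        res = ld_r2(hapset, "other_breeds", "#4", "#5", variants)
        assert res.D < 0
        assert res.r2 == pytest.approx(0.0074557, abs=1e-6)
        assert res.displayed_r2_percent == 1

    def test_monomorphic_site_gives_sentinel(self, hapset, variants):
        res = ld_r2(hapset, "greyhound", "#8", "#5", variants)  # #8 fixed in Greyhounds
        assert not res.defined
        assert res.displayed_r2_percent is None

    def test_invariant_under_label_permutation(self, hapset, variants):
        relabeled = HaplotypeSet(
            site_order=hapset.site_order,
            haplotypes={f"X{i}": v for i, v in enumerate(hapset.haplotypes.values())},
            counts={"greyhound": {
                f"X{i}": hapset.counts["greyhound"][lab]
                for i, lab in enumerate(hapset.haplotypes)
            }},
        )
        a = ld_r2(hapset, "greyhound", "#3", "#9", variants)
        b = ld_r2(relabeled, "greyhound", "#3", "#9", variants)
        assert a.r2 == pytest.approx(b.r2)


class TestDiplotypeArithmetic:
    @pytest.mark.parametrize(
        "population,haplotype,percent",
        [
            ("Greyhound (NGA)", "H2", 26),
            ("Greyhound (NGA)", "H3", 18),  # 63/360 = 17.5 rounds half-up
            ("Greyhound (AKC)", "H3", 59),
            ("Beagle", "H2", 25),
            ("Mixed-breed", "H2", 21),
        ],
    )
    def test_published_percents(self, diplotype_counts, population, haplotype, percent):
        freqs = haplotype_freqs_from_diplotypes(diplotype_counts[population])
        assert freqs[haplotype]["percent"] == percent

    def test_all_homozygous_single_haplotype(self):
        dc = DiplotypeCounts("p", {("H1", "H1"): 7})
        freqs = haplotype_freqs_from_diplotypes(dc)
        assert freqs["H1"]["percent"] == 100
        assert freqs["H1"]["frequency"] == 1.0

    def test_frequencies_sum_to_one(self, diplotype_counts):
        for dc in diplotype_counts.values():
            total = sum(d["frequency"] for d in haplotype_freqs_from_diplotypes(dc).values())
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_round_half_up_convention(self):
        assert round_half_up(17.5) == 18
        assert round_half_up(17.49) == 17
        assert round_half_up(0.5) == 1


class TestGroupCompare:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4)
        y = rng.normal(1.0, size=4)
        _, p = mann_whitney_u(x, y)
        # enumerate all C(8,4) group assignments of the pooled sample
        pooled = np.concatenate([x, y])
        obs_u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        n = len(x)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            xa = pooled[list(idx)]
            ya = np.delete(pooled, list(idx))
            u = stats.mannwhitneyu(xa, ya, alternative="two-sided").statistic
            dev_obs = abs(obs_u - n * (len(pooled) - n) / 2)
            if abs(u - n * (len(pooled) - n) / 2) >= dev_obs - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_breed_group_compare_interface(self):
        freqs = {"b1": 0.02, "b2": 0.01, "b3": 0.0, "s1": 0.1, "s2": 0.2, "s3": 0.05}
        groups = {k: ("sighthound" if k.startswith("s") else "other") for k in freqs}
        res = breed_group_compare(freqs, groups, "sighthound", "other")
        assert res.mean_a > res.mean_b
        assert 0 < res.p_value <= 1
        with pytest.raises(ValueError):
            breed_group_compare({"a": 1.0, "s1": 1.0, "s2": 2.0},
                                {"a": "other", "s1": "sighthound", "s2": "sighthound"},
                                "sighthound", "other")

    def test_type_i_error_calibration(self):
        # no true difference: rejection rate at alpha=0.05 should be near 0.05
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=19)
            y = rng.normal(size=45)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
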