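"""Classical association statistics: ORs, genetic models, HWE, tests, Bonferroni."""

import math

import pytest
from scipy.stats import hypergeom

from xcc import datasets
from xcc.classic_assoc import (
    bonferroni,
    chi2_or_fisher,
    collapse_genotypes,
    hwe_chi2,
    odds_ratio,
    se_dose_summary,
)
from xcc.tables_io import ContingencyTable2x2 as T
from xcc.tables_io import GenotypeCounts, SNPDef, ValidationError

SNP = SNPDef("rs13397", "G", "A")


class TestOddsRatio:
    def test_hla_allele_table(self):
        res = odds_ratio(T(42, 222, 15, 331))
        assert res.or_hat == pytest.approx(4.17, abs=0.005)

    def test_unit_table(self):
        assert odds_ratio(T(10, 10, 10, 10)).or_hat == 1.0

    def test_hand_computed_woolf_interval(self):
        # ln OR = -0.7937, SE = 0.1638
        res = odds_ratio(T(131, 158, 220, 120))
        assert res.or_hat == pytest.approx(0.452, abs=0.001)
        assert res.ci_low == pytest.approx(0.328, abs=0.002)
        assert res.ci_high == pytest.approx(0.623, abs=0.002)

    def test_zero_cell_is_infinite_with_continuity_interval(self):
        res = odds_ratio(T(6, 258, 0, 346))
        assert math.isinf(res.or_hat)
        assert res.continuity_applied
        assert 0 < res.ci_low < res.ci_high < math.inf

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(T(0, 0, 5, 5))

    @pytest.mark.parametrize("cells", [(3, 7, 11, 13), (50, 20, 30, 60), (1, 2, 3, 4)])
    def test_group_swap_inverts_exactly(self, cells):
        t = T(*cells)
        assert odds_ratio(t.swapped_groups()).or_hat == pytest.approx(
            1.0 / odds_ratio(t).or_hat, rel=1e-12
        )


class TestCollapseGenotypes:
    def _counts(self, pop, snp):
        gmap = datasets.genotype_counts_map()
        return gmap[(pop, "case", snp)], gmap[(pop, "control", snp)]

    def test_french_rs13397_dominant_major_exposure(self):
        case, ctrl = self._counts("French", "rs13397")
        t = collapse_genotypes(case, ctrl, "dominant_minor", exposure="major")
        assert t.cells == (131, 158, 220, 120)
        assert odds_ratio(t).or_hat == pytest.approx(0.45, abs=0.005)

    def test_tunisian_rs1059702_dominant_major_exposure(self):
        case, ctrl = self._counts("Tunisian", "rs1059702")
        t = collapse_genotypes(case, ctrl, "dominant_minor", exposure="major")
        assert odds_ratio(t).or_hat == pytest.approx(0.67, abs=0.005)

    def test_allelic_model_counts_chromosomes(self):
        case, ctrl = self._counts("Tunisian", "rs13397")
        t = collapse_genotypes(case, ctrl, "allelic")
        assert t.cells == (60, 178, 55, 207)

    def test_recessive_on_all_homozygote_cohort(self):
        g1 = GenotypeCounts(SNP, 5, 0, 3)
        g2 = GenotypeCounts(SNP, 7, 0, 1)
        t = collapse_genotypes(g1, g2, "recessive_minor")
        assert t.cells == (3, 5, 1, 7)

    @pytest.mark.parametrize("model", ["dominant_minor", "recessive_minor"])
    @pytest.mark.parametrize("exposure", ["minor", "major"])
    def test_individual_conservation(self, model, exposure):
        case, ctrl = self._counts("French", "rs1059703")
        t = collapse_genotypes(case, ctrl, model, exposure=exposure)
        assert t.a + t.b == case.total
        assert t.c + t.d == ctrl.total

    def test_snp_mismatch_rejected(self):
        g1 = GenotypeCounts(SNP, 1, 1, 1)
        g2 = GenotypeCounts(SNPDef("rs1059703", "T", "C"), 1, 1, 1)
        with pytest.raises(ValidationError):
            collapse_genotypes(g1, g2, "allelic")


class TestHWE:
    def test_exact_equilibrium_half(self):
        assert hwe_chi2(GenotypeCounts(SNP, 25, 50, 25)).chi2 == pytest.approx(0, abs=1e-12)

    def test_exact_equilibrium_skewed(self):
        assert hwe_chi2(GenotypeCounts(SNP, 81, 18, 1)).chi2 == pytest.approx(0, abs=1e-12)

    def test_published_control_counts_fail_equilibrium(self):
        """The Tunisian control genotype distribution shows a strong
        homozygote excess (chi2 ~ 29), far above the 3.84 cut."""
        res = hwe_chi2(GenotypeCounts(SNP, 92, 23, 16))
        assert res.chi2 == pytest.approx(28.99, abs=0.05)
        assert not res.passes_005

    def test_monomorphic_rejected(self):
        with pytest.raises(ValidationError):
            hwe_chi2(GenotypeCounts(SNP, 10, 0, 0))

    def test_invariant_to_allele_relabeling(self):
        g = GenotypeCounts(SNP, 92, 23, 16)
        flipped = GenotypeCounts(SNPDef("rs13397", "A", "G"), 16, 23, 92)
        assert hwe_chi2(g).chi2 == pytest.approx(hwe_chi2(flipped).chi2, rel=1e-12)


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate all tables with the observed
    margins and sum hypergeometric probabilities <= that of the observed table."""
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    p_obs = hypergeom.pmf(a, n, m1, n1)
    total = 0.0
    for x in range(max(0, m1 - n2), min(m1, n1) + 1):
        p = hypergeom.pmf(x, n, m1, n1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestChi2OrFisher:
    def test_null_table(self):
        res = chi2_or_fisher(T(10, 10, 10, 10))
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_small_table_routes_to_fisher_and_matches_enumeration(self):
        res = chi2_or_fisher(T(3, 0, 0, 3))
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(3, 0, 0, 3), abs=1e-12)

    @pytest.mark.parametrize("cells", [(4, 1, 1, 6), (2, 8, 7, 3), (5, 5, 0, 9)])
    def test_fisher_branch_equals_oracle(self, cells):
        res = chi2_or_fisher(T(*cells))
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(*cells), abs=1e-9)

    def test_large_table_uses_chi2(self):
        res = chi2_or_fisher(T(50, 50, 25, 75))
        assert res.method == "chi2_yates"
        assert res.p_value < 0.01

    def test_yates_flag_recorded(self):
        assert chi2_or_fisher(T(50, 50, 25, 75), yates=False).method == "chi2"


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(1.6e-5, 22, 35.2e-5), (0.002, 22, 0.044), (0.9, 22, 1.0)],
    )
    def test_published_corrections(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_capped(self):
        assert bonferroni(0.01, 3) <= bonferroni(0.02, 3) <= bonferroni(0.02, 5)
        assert bonferroni(bonferroni(0.5, 10), 1) == 1.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestSharedEpitopeDose:
    def test_small_example(self):
        pairs = [("SE", "non"), ("SE", "SE"), ("non", "non")]
        assert se_dose_summary(pairs, {"SE"}) == (1, 1, 3)

    def test_empty(self):
        assert se_dose_summary([], {"SE"}) == (0, 0, 0)

    def test_published_tunisian_dose_frequencies(self):
        """132 individuals with 66 single-SE and 12 double-SE carriers give the
        published 50.00% / 9.09% dose frequencies."""
        pairs = (
            [("SE", "non")] * 66 + [("SE", "SE")] * 12 + [("non", "non")] * 54
        )
        n_single, n_double, n_total = se_dose_summary(pairs, {"SE"})
        assert (n_single, n_double, n_total) == (66, 12, 132)
        assert 100 * n_single / n_total == pytest.approx(50.00, abs=0.005)
        assert 100 * n_double / n_total == pytest.approx(9.09, abs=0.005)

    def test_matches_packaged_dose_table(self):
        df = datasets.load_se_dose().set_index("population")
        assert df.loc["Tunisian", "n_single_dose"] == 66
        assert df.loc["French", "n_double_dose"] == 35
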