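"""EM haplotype frequencies, pairwise LD, and haplotype association."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize

from xcc.haplotype import (
    HaplotypeTable,
    em_haplotype_freq,
    haplotype_association,
    ld_matrix,
    ld_pair,
    marginalize_haplotypes,
)
from xcc.synth import CohortSpec, simulate_cohort
from xcc.tables_io import CohortGenotypes, SNPDef, ValidationError

S1 = SNPDef("s1", "A", "C")
S2 = SNPDef("s2", "G", "T")


def cohort_from_pairs(snps, genotypes, group="case"):
    return CohortGenotypes(
        list(snps),
        [(f"s{i}", group, tuple(g)) for i, g in enumerate(genotypes)],
    )


def direct_likelihood_oracle(snps, genotypes):
    """Independent maximizer of the unphased multinomial likelihood.

    Enumerates compatible ordered haplotype pairs per individual directly and
    maximizes over the simplex through a softmax parametrization with
    multi-start BFGS; shares no code with the EM implementation.
    """
    haps = ["".join(c) for c in itertools.product(*[s.alleles for s in snps])]

    def compatible(pair_of_haps, genotype):
        for k, (x, y) in enumerate(genotype):
            got = sorted((pair_of_haps[0][k], pair_of_haps[1][k]))
            if got != sorted((x, y)):
                return False
        return True

    pair_sets = []
    for g in genotypes:
        pairs = [
            (i, j)
            for i, j in itertools.product(range(len(haps)), repeat=2)
            if compatible((haps[i], haps[j]), g)
        ]
        pair_sets.append(pairs)

    def neg_loglik(z):
        f = np.exp(z - z.max())
        f = f / f.sum()
        ll = 0.0
        for pairs in pair_sets:
            ll += math.log(sum(f[i] * f[j] for i, j in pairs))
        return -ll

    best = None
    rng = np.random.default_rng(0)
    for start in range(8):
        z0 = np.zeros(len(haps)) if start == 0 else rng.normal(size=len(haps))
        res = optimize.minimize(neg_loglik, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    f = f / f.sum()
    return dict(zip(haps, f))


class TestEM:
    def test_all_homozygous_is_direct_counting(self):
        genotypes = [
            [("A", "A"), ("G", "G")],
            [("A", "A"), ("G", "G")],
            [("C", "C"), ("T", "T")],
            [("A", "A"), ("T", "T")],
        ]
        tab = em_haplotype_freq(cohort_from_pairs((S1, S2), genotypes))
        assert tab.freq("AG") == pytest.approx(0.5, abs=1e-9)
        assert tab.freq("CT") == pytest.approx(0.25, abs=1e-9)
        assert tab.freq("AT") == pytest.approx(0.25, abs=1e-9)
        assert tab.n_iter <= 2

    def test_single_snp_recovers_allele_frequencies(self):
        genotypes = [[("A", "A")], [("A", "C")], [("A", "C")], [("C", "C")]]
        tab = em_haplotype_freq(cohort_from_pairs((S1,), genotypes))
        assert tab.freq("A") == pytest.approx(0.5, abs=1e-9)

    def test_phase_ambiguous_toy_set_matches_direct_maximizer(self):
        """20 individuals with double heterozygotes: EM must land on the same
        likelihood maximum as an independent simplex optimizer."""
        genotypes = (
            [[("A", "C"), ("G", "T")]] * 6
            + [[("A", "A"), ("G", "G")]] * 7
            + [[("C", "C"), ("T", "T")]] * 4
            + [[("A", "C"), ("G", "G")]] * 2
            + [[("A", "A"), ("G", "T")]] * 1
        )
        cohort = cohort_from_pairs((S1, S2), genotypes)
        tab = em_haplotype_freq(cohort, n_restarts=5, seed=0)
        oracle = direct_likelihood_oracle((S1, S2), genotypes)
        for hap, f in oracle.items():
            assert tab.freq(hap) == pytest.approx(f, abs=0.002), hap

    def test_recovery_from_generating_frequencies(self):
        truth = {"AG": 0.5, "AT": 0.2, "CG": 0.2, "CT": 0.1}
        spec = CohortSpec((S1, S2), truth, {}, 500, 500, seed=9)
        tab = em_haplotype_freq(simulate_cohort(spec))
        for hap, f in truth.items():
            assert tab.freq(hap) == pytest.approx(f, abs=0.03)

    def test_loglik_trace_is_monotone(self, french_like_risk_spec):
        tab = em_haplotype_freq(simulate_cohort(french_like_risk_spec))
        trace = np.array(tab.loglik_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-9)

    def test_frequencies_sum_to_one(self, french_like_risk_spec):
        tab = em_haplotype_freq(simulate_cohort(french_like_risk_spec))
        assert sum(tab.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_snp_permutation_permutes_labels(self, snp_panel, french_like_freqs):
        spec = CohortSpec(snp_panel, french_like_freqs, {}, 300, 300, seed=4)
        cohort = simulate_cohort(spec)
        tab = em_haplotype_freq(cohort)
        perm = cohort.subset_snps(["rs1059702", "rs13397", "rs1059703"])
        tab_perm = em_haplotype_freq(perm)
        for hap, f in tab.freqs.items():
            assert tab_perm.freq(hap[2] + hap[0] + hap[1]) == pytest.approx(f, abs=1e-6)

    def test_missing_genotypes_are_complete_case(self):
        genotypes = [
            [("A", "A"), ("G", "G")],
            [("A", "A"), None],
            [("C", "C"), ("T", "T")],
        ]
        tab = em_haplotype_freq(cohort_from_pairs((S1, S2), genotypes))
        assert tab.n_individuals == 2

    def test_no_complete_individual_is_error(self):
        with pytest.raises(ValidationError):
            em_haplotype_freq(cohort_from_pairs((S1, S2), [[("A", "A"), None]]))


class TestLD:
    def _table(self, freqs):
        return HaplotypeTable((S1, S2), freqs, 0.0, 1, True, 100)

    def test_independent_frequencies_give_zero(self):
        # p_AG = p_A * p_G exactly
        tab = self._table({"AG": 0.35, "AT": 0.35, "CG": 0.15, "CT": 0.15})
        ld = ld_pair(tab)
        assert ld.D == pytest.approx(0.0, abs=1e-12)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_two_complementary_haplotypes_are_perfect_ld(self):
        ld = ld_pair(self._table({"AG": 0.6, "CT": 0.4}))
        assert ld.D_prime == pytest.approx(1.0, abs=1e-12)
        assert ld.r2 == pytest.approx(1.0, abs=1e-12)

    def test_direct_formula_evaluation(self):
        ld = ld_pair(self._table({"AG": 0.5, "AT": 0.1, "CG": 0.1, "CT": 0.3}))
        assert ld.D == pytest.approx(0.14, abs=1e-12)
        assert ld.r2 == pytest.approx(0.14**2 / (0.6 * 0.4 * 0.6 * 0.4), abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValidationError):
            ld_pair(self._table({"AG": 0.7, "AT": 0.3}))

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4))
        tab = self._table(dict(zip(["AG", "AT", "CG", "CT"], f)))
        ld = ld_pair(tab)
        assert 0.0 <= ld.D_prime <= 1.0
        assert 0.0 <= ld.r2 <= 1.0
        assert ld.r2 <= ld.D_prime**2 + 1e-12  # r2 = 1 forces D' = 1

    def test_marginalized_triple_matches_pairwise_reestimation(
        self, snp_panel, french_like_freqs
    ):
        spec = CohortSpec(snp_panel, french_like_freqs, {}, 500, 500, seed=21)
        cohort = simulate_cohort(spec)
        tri = em_haplotype_freq(cohort)
        pairwise = {tuple(s.snp_id for s in ld.snp_pair): ld for ld in ld_matrix(cohort)}
        for ids in itertools.combinations([s.snp_id for s in snp_panel], 2):
            from_tri = ld_pair(marginalize_haplotypes(tri, list(ids)))
            assert from_tri.r2 == pytest.approx(pairwise[ids].r2, abs=0.02)


class TestHaplotypeAssociation:
    def test_rare_haplotype_filtered(self, snp_panel):
        freqs = {"GTC": 0.58, "ATC": 0.2, "GCC": 0.2, "ACT": 0.02}
        spec = CohortSpec(snp_panel, freqs, {}, 400, 400, seed=6)
        cohort = simulate_cohort(spec)
        res = haplotype_association(cohort.subset_group("case"), cohort.subset_group("control"))
        assert "ACT" not in {r.haplotype for r in res}

    def test_risk_haplotype_recovered_with_label(self, french_like_risk_spec):
        cohort = simulate_cohort(french_like_risk_spec)
        res = {r.haplotype: r for r in haplotype_association(
            cohort.subset_group("case"), cohort.subset_group("control"))}
        atc = res["ATC"]
        assert atc.effect_label == "Risk"
        assert 2.0 < atc.or_hat < 6.5

    def test_null_cohorts_keep_each_haplotype_na_in_most_runs(self, null_battery):
        """With identical generating case/control frequencies every haplotype
        should stay unlabelled (NA) in at least 90% of the 200 replicate
        runs, checked per haplotype."""
        rejections, n_rep, _n_tests, _n_rej = null_battery
        for hap, k in rejections.items():
            assert k / n_rep <= 0.10, (hap, k)

    def test_empty_group_rejected(self, snp_panel):
        spec = CohortSpec(snp_panel, {"GTC": 1.0}, {}, 5, 5, seed=0)
        cohort = simulate_cohort(spec)
        with pytest.raises(ValidationError):
            haplotype_association(cohort.subset_group("case"),
                                  cohort.subset_group("nosuch"))
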