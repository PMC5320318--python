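"""Synthetic cohorts and study collections with known truth.

The raw per-individual genotypes behind the packaged count tables were never
released, so every individual-level pipeline stage is exercised on simulated
data whose generating parameters mirror the published structure: two-group
(case/control) cohorts of diploid female individuals typed at L X-linked
biallelic SNPs drawn from specified haplotype frequencies, and collections of
allele-count 2x2 studies with a specified true log OR and between-study
variance.

Disease model for cohorts: each haplotype copy multiplies the disease odds,
i.e. case haplotype frequencies are the control frequencies tilted by
exp(log OR) and renormalized — the implicit model of chromosome-level 2x2
haplotype tests. Missingness is MCAR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meta import MetaStudy, study_from_table
from .tables_io import CohortGenotypes, ContingencyTable2x2, SNPDef, ValidationError


@dataclass(frozen=True)
class CohortSpec:
    snps: tuple[SNPDef, ...]
    control_hap_freqs: dict[str, float]
    hap_log_or: dict[str, float]     # log odds ratio vs the reference haplotype
    n_cases: int
    n_controls: int
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.control_hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"control haplotype frequencies sum to {total}, not 1")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        for hap in self.control_hap_freqs:
            if len(hap) != len(self.snps):
                raise ValidationError(f"haplotype {hap!r} has wrong length")
            for allele, snp in zip(hap, self.snps):
                if allele not in snp.alleles:
                    raise ValidationError(f"haplotype {hap!r}: {allele!r} not an allele of {snp.snp_id}")


@dataclass(frozen=True)
class MetaSimSpec:
    k_studies: int
    true_log_or: float
    tau2: float
    study_sizes: tuple[tuple[int, int], ...]   # (n_case_alleles, n_control_alleles)
    base_allele_freq: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValidationError("tau2 must be non-negative")
        if len(self.study_sizes) != self.k_studies:
            raise ValidationError("study_sizes must list one (case, control) pair per study")
        if any(nc <= 0 or nk <= 0 for nc, nk in self.study_sizes):
            raise ValidationError("study sizes must be positive")
        if not 0 < self.base_allele_freq < 1:
            raise ValidationError("base_allele_freq must lie in (0, 1)")


def case_hap_freqs(spec: CohortSpec) -> dict[str, float]:
    """Control frequencies tilted by exp(log OR) and renormalized."""
    tilted = {
        h: f * float(np.exp(spec.hap_log_or.get(h, 0.0)))
        for h, f in spec.control_hap_freqs.items()
    }
    total = sum(tilted.values())
    return {h: f / total for h, f in tilted.items()}


def simulate_cohort(spec: CohortSpec) -> CohortGenotypes:
    """Draw a case/control cohort of unphased diploid genotypes.

    Each individual receives two independent haplotype draws from her group's
    distribution (HWE within group); phase is then discarded by storing the
    unordered per-SNP allele pair, and genotypes are masked MCAR at
    ``missing_rate``. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    haps = list(spec.control_hap_freqs)
    freqs = {
        "control": np.array([spec.control_hap_freqs[h] for h in haps]),
        "case": np.array([case_hap_freqs(spec)[h] for h in haps]),
    }
    samples = []
    counter = 0
    for group, n in (("case", spec.n_cases), ("control", spec.n_controls)):
        draws = rng.choice(len(haps), size=(n, 2), p=freqs[group])
        if spec.missing_rate > 0:
            mask = rng.random((n, len(spec.snps))) < spec.missing_rate
        else:
            mask = np.zeros((n, len(spec.snps)), dtype=bool)
        for i in range(n):
            h1, h2 = haps[draws[i, 0]], haps[draws[i, 1]]
            gts = []
            for j, snp in enumerate(spec.snps):
                if mask[i, j]:
                    gts.append(None)
                    continue
                pair = (h1[j], h2[j])
                if pair[0] != snp.allele_major and pair[1] == snp.allele_major:
                    pair = (pair[1], pair[0])
                gts.append(pair)
            counter += 1
            samples.append((f"S{counter:05d}", group, tuple(gts)))
    return CohortGenotypes(list(spec.snps), samples)


def simulate_meta_studies(spec: MetaSimSpec) -> list[MetaStudy]:
    """Draw k allele-count case-control studies around a common true log OR.

    Per-study effects are Normal(true_log_or, tau2); the control exposure
    probability is ``base_allele_freq`` and the case probability follows from
    the study's odds; all four cells are binomial draws.
    """
    rng = np.random.default_rng(spec.seed)
    thetas = spec.true_log_or + math.sqrt(spec.tau2) * rng.standard_normal(spec.k_studies)
    p_ctrl = spec.base_allele_freq
    odds_ctrl = p_ctrl / (1 - p_ctrl)
    studies = []
    for k, (n_case, n_ctrl) in enumerate(spec.study_sizes):
        odds_case = odds_ctrl * float(np.exp(thetas[k]))
        p_case = odds_case / (1 + odds_case)
        a = int(rng.binomial(n_case, p_case))
        c = int(rng.binomial(n_ctrl, p_ctrl))
        table = ContingencyTable2x2(a, n_case - a, c, n_ctrl - c)
        studies.append(study_from_table(f"sim{k + 1}", table))
    return studies
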