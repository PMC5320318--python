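"""Classical case-control association statistics.

Odds ratios with Woolf (log-scale) confidence intervals, genetic-model
collapsing of genotype counts, the chi-square / Fisher testing rule with Yates
correction, the Hardy-Weinberg equilibrium chi-square, Bonferroni correction,
and shared-epitope dose summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy import stats

from .tables_io import (
    ContingencyTable2x2,
    GenotypeCounts,
    ValidationError,
    genotype_to_allele_counts,
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile

GeneticModel = Literal["allelic", "dominant_minor", "recessive_minor"]
GENETIC_MODELS: tuple[GeneticModel, ...] = ("allelic", "dominant_minor", "recessive_minor")


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float | None
    method: Literal["chi2", "chi2_yates", "fisher"]


@dataclass(frozen=True)
class ORResult:
    or_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    continuity_applied: bool


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    passes_005: bool  # chi2 < 3.84, the conventional 5% cut at 1 df


def chi2_or_fisher(t: ContingencyTable2x2, yates: bool = True) -> TestResult:
    """Pearson chi-square when all expected cells are >= 5, else Fisher exact.

    The applied rule is recorded in ``method``. ``yates`` applies the
    continuity correction to the chi-square branch only.
    """
    a, b, c, d = t.cells
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")
    n = n1 + n2
    exp = [n1 * (a + c) / n, n1 * (b + d) / n, n2 * (a + c) / n, n2 * (b + d) / n]
    if min(exp) >= 5:
        obs = [[a, b], [c, d]]
        chi2, p, _df, _e = stats.chi2_contingency(obs, correction=yates)
        return TestResult(float(p), float(chi2), "chi2_yates" if yates else "chi2")
    _odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(p), None, "fisher")


def odds_ratio(t: ContingencyTable2x2) -> ORResult:
    """Sample odds ratio (a*d)/(b*c) with a 95% Woolf interval.

    A zero cell leaves the point estimate at 0 or inf (display convention) and
    computes the interval from the +0.5 Haldane-Anscombe table instead.
    """
    a, b, c, d = t.cells
    if a + b == 0 or c + d == 0:
        raise ValidationError("each group must have at least one observation")
    test = chi2_or_fisher(t)
    if min(a, b, c, d) > 0:
        or_hat = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = math.log(or_hat)
        return ORResult(
            or_hat, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se),
            test.p_value, f"woolf+{test.method}", False,
        )
    if a * d == 0 and b * c == 0:
        raise ValidationError("odds ratio undefined: zero on both diagonals")
    or_hat = math.inf if b * c == 0 else 0.0
    ac, bc_, cc, dc = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((ac * dc) / (bc_ * cc))
    se = math.sqrt(1 / ac + 1 / bc_ + 1 / cc + 1 / dc)
    return ORResult(
        or_hat, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se),
        test.p_value, f"woolf+{test.method}", True,
    )


def collapse_genotypes(
    g_case: GenotypeCounts,
    g_control: GenotypeCounts,
    model: GeneticModel,
    exposure: Literal["minor", "major"] = "minor",
) -> ContingencyTable2x2:
    """Collapse genotype counts of both groups into a model-specific 2x2 table.

    ``allelic`` counts chromosomes; ``dominant_minor`` splits minor-allele
    carriers vs major homozygotes; ``recessive_minor`` splits minor homozygotes
    vs major-allele carriers. ``exposure="major"`` flips which column counts as
    exposed (e.g. major-homozygote-as-exposure under the dominant model), which
    inverts the odds ratio.
    """
    if g_case.snp.snp_id != g_control.snp.snp_id:
        raise ValidationError("case and control counts refer to different SNPs")
    snp = g_case.snp
    if model == "allelic":
        ca, co = genotype_to_allele_counts(g_case), genotype_to_allele_counts(g_control)
        pairs = ((ca.n_minor, ca.n_major), (co.n_minor, co.n_major))
        label = f"{snp.allele_minor} allele"
    elif model == "dominant_minor":
        pairs = (
            (g_case.n_het + g_case.n_hom_minor, g_case.n_hom_major),
            (g_control.n_het + g_control.n_hom_minor, g_control.n_hom_major),
        )
        label = f"{snp.allele_minor} carrier"
    elif model == "recessive_minor":
        pairs = (
            (g_case.n_hom_minor, g_case.n_hom_major + g_case.n_het),
            (g_control.n_hom_minor, g_control.n_hom_major + g_control.n_het),
        )
        label = f"{snp.allele_minor}{snp.allele_minor} homozygote"
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    (a, b), (c, d) = pairs
    if exposure == "major":
        a, b, c, d = b, a, d, c
        label = f"not {label}"
    return ContingencyTable2x2(a, b, c, d, label_exposure=label, label_groups=("case", "control"))


def hwe_chi2(g: GenotypeCounts) -> HWEResult:
    """Hardy-Weinberg chi-square (1 df) against expectations from the observed
    allele frequency. Undefined for monomorphic counts."""
    n = g.total
    if n < 1:
        raise ValidationError("need at least one individual")
    alleles = genotype_to_allele_counts(g)
    if alleles.n_major == 0 or alleles.n_minor == 0:
        raise ValidationError(f"{g.snp.snp_id}: monomorphic; HWE undefined")
    p = alleles.n_major / alleles.total
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (g.n_hom_major, g.n_het, g.n_hom_minor)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(chi2, 1, chi2 < 3.84)


def bonferroni(p: float, m: int) -> float:
    """min(1, m*p) for a batch of m hypotheses."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, m * p)


def se_dose_summary(
    individual_allele_pairs: Iterable[tuple[str, str]], se_set: set[str]
) -> tuple[int, int, int]:
    """Count individuals carrying exactly one / exactly two alleles from
    ``se_set`` (shared-epitope dose); returns (n_single, n_double, n_total)."""
    n_single = n_double = n_total = 0
    for pair in individual_allele_pairs:
        if len(pair) != 2:
            raise ValidationError("each individual must carry exactly two allele labels")
        dose = sum(1 for a in pair if a in se_set)
        n_total += 1
        if dose == 1:
            n_single += 1
        elif dose == 2:
            n_double += 1
    return (n_single, n_double, n_total)
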