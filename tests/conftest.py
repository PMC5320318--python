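import math

import pytest

from xcc.tables_io import SNPDef
from xcc.synth import CohortSpec


@pytest.fixture(scope="session")
def snp_panel() -> tuple[SNPDef, SNPDef, SNPDef]:
    """The three-SNP X-linked panel used throughout (major/minor as observed
    in the Tunisian/French control groups)."""
    return (
        SNPDef("rs13397", "G", "A"),
        SNPDef("rs1059703", "T", "C"),
        SNPDef("rs1059702", "C", "T"),
    )


@pytest.fixture(scope="session")
def french_like_freqs() -> dict[str, float]:
    """Control haplotype frequencies shaped like the French cohort: four
    common haplotypes (GTC .68, ATC .09, GCC .06, GTT .04) and the remaining
    mass split over the other four."""
    rest = (1.0 - 0.68 - 0.09 - 0.06 - 0.04) / 4
    return {
        "GTC": 0.68, "ATC": 0.09, "GCC": 0.06, "GTT": 0.04,
        "GCT": rest, "ATT": rest, "ACC": rest, "ACT": rest,
    }


@pytest.fixture(scope="session")
def null_battery(snp_panel):
    """200 replicate cohorts simulated under identical case/control haplotype
    frequencies (n=500/500), run through the haplotype association pipeline.

    Returns (per-haplotype rejection counts, number of replicates, total
    number of tests performed, total rejections).
    """
    from xcc.haplotype import haplotype_association
    from xcc.synth import simulate_cohort

    freqs = {"GTC": 0.56, "ATC": 0.15, "GCC": 0.14, "GTT": 0.15}
    n_rep = 200
    rejections = {h: 0 for h in freqs}
    n_tests = n_rej = 0
    for s in range(n_rep):
        spec = CohortSpec(snp_panel, freqs, {}, 500, 500, seed=1000 + s)
        cohort = simulate_cohort(spec)
        for r in haplotype_association(
            cohort.subset_group("case"), cohort.subset_group("control")
        ):
            n_tests += 1
            if r.effect_label != "NA":
                n_rej += 1
                rejections[r.haplotype] += 1
    return rejections, n_rep, n_tests, n_rej


@pytest.fixture
def french_like_risk_spec(snp_panel, french_like_freqs) -> CohortSpec:
    """Cohort spec with a four-fold odds tilt on the ATC haplotype, at the
    published French sample sizes."""
    return CohortSpec(
        snps=snp_panel,
        control_hap_freqs=french_like_freqs,
        hap_log_or={"ATC": math.log(4.0)},
        n_cases=289,
        n_controls=340,
        seed=1,
    )
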