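"""EM haplotype-frequency estimation, pairwise LD, and haplotype association.

Phase is unobserved in diploid genotype data: an individual heterozygous at k
of the L sites is compatible with 2^(k-1) unordered haplotype pairs. Under
random pairing of haplotypes within a group (the Hardy-Weinberg assumption at
the haplotype level) the multilocus genotype likelihood is a mixture over
those pairs, and the classical EM iteration applies:

  E-step: distribute each individual's unit mass over its compatible pairs
          (h, h') proportionally to 2^[h != h'] * f_h * f_h';
  M-step: re-estimate each frequency from the expected chromosome counts.

The log-likelihood is non-decreasing at every iteration; with
double-heterozygote-heavy data the surface can be multimodal, so seeded random
restarts are available and the best final log-likelihood wins (earliest
restart on ties).

Pairwise linkage disequilibrium (D, D', r^2) is computed from an estimated
two-SNP haplotype table; per-haplotype case-control association compares
expected chromosome counts between groups with the conventional "ignore
haplotypes rarer than 5%" filter.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .classic_assoc import chi2_or_fisher, odds_ratio
from .tables_io import CohortGenotypes, ContingencyTable2x2, SNPDef, ValidationError


@dataclass(frozen=True)
class HaplotypeTable:
    snps: tuple[SNPDef, ...]
    freqs: dict[str, float]          # L-character allele string -> frequency
    loglik: float
    n_iter: int
    converged: bool
    n_individuals: int               # complete-case individuals used
    loglik_trace: tuple[float, ...] = ()   # per-iteration log-likelihoods

    def freq(self, hap: str) -> float:
        return self.freqs.get(hap, 0.0)


@dataclass(frozen=True)
class LDStats:
    snp_pair: tuple[SNPDef, SNPDef]
    D: float
    D_prime: float
    r2: float


@dataclass(frozen=True)
class HaplotypeAssocResult:
    haplotype: str
    freq_case: float
    freq_control: float
    or_hat: float
    ci_low: float
    ci_high: float
    p_value: float
    effect_label: Literal["Risk", "Protector", "NA"]


def _complete_patterns(cohort: CohortGenotypes) -> Counter:
    """Multiset of complete multilocus genotypes (tuple of allele pairs)."""
    patterns: Counter = Counter()
    for _sid, _grp, gts in cohort.samples:
        if all(gt is not None for gt in gts):
            patterns[tuple(gts)] += 1
    return patterns


def _hap_universe(snps: list[SNPDef]) -> list[str]:
    return ["".join(combo) for combo in itertools.product(*[s.alleles for s in snps])]


def _compatible_pairs(pattern: tuple, hap_index: dict[str, int]) -> list[tuple[int, int, int]]:
    """Unordered haplotype pairs (i, j, c) consistent with a genotype pattern;
    c = 2 for heterozygous pairs, 1 for homozygous."""
    het_sites = [k for k, pair in enumerate(pattern) if pair[0] != pair[1]]
    base1 = [pair[0] for pair in pattern]
    base2 = [pair[1] for pair in pattern]
    pairs: set[tuple[int, int]] = set()
    if not het_sites:
        h = "".join(base1)
        return [(hap_index[h], hap_index[h], 1)]
    # fix the first het site's allocation to enumerate unordered pairs once
    for flips in itertools.product([False, True], repeat=len(het_sites) - 1):
        h1, h2 = base1[:], base2[:]
        for site, flip in zip(het_sites[1:], flips):
            if flip:
                h1[site], h2[site] = h2[site], h1[site]
        i, j = hap_index["".join(h1)], hap_index["".join(h2)]
        pairs.add((min(i, j), max(i, j)))
    return [(i, j, 1 if i == j else 2) for i, j in sorted(pairs)]


def _em_run(
    patterns: Counter,
    pair_lists: list[list[tuple[int, int, int]]],
    counts: np.ndarray,
    f0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool, tuple[float, ...]]:
    f = f0.copy()
    n_chrom = 2 * sum(patterns.values())
    loglik = -math.inf
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        new = np.zeros_like(f)
        ll = 0.0
        for n_g, pairs in zip(counts, pair_lists):
            denom = sum(c * f[i] * f[j] for i, j, c in pairs)
            if denom <= 0:
                # pattern unreachable under current frequencies; restart mass uniformly
                weights = [(i, j, 1.0 / len(pairs)) for i, j, _c in pairs]
                ll = -math.inf
            else:
                weights = [(i, j, c * f[i] * f[j] / denom) for i, j, c in pairs]
                ll += n_g * math.log(denom)
            for i, j, w in weights:
                new[i] += n_g * w
                new[j] += n_g * w
        new /= n_chrom
        trace.append(ll)
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol or abs(ll - loglik) < tol:
            return f, ll, it, True, tuple(trace)
        loglik = ll
    return f, loglik, max_iter, False, tuple(trace)


def em_haplotype_freq(
    cohort: CohortGenotypes,
    init: Literal["uniform", "random"] = "uniform",
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 0,
) -> HaplotypeTable:
    """Maximum-likelihood haplotype frequencies from unphased diploid genotypes.

    Individuals missing a genotype at any panel SNP are excluded
    (complete-case). ``n_restarts`` adds seeded random re-initializations on
    top of the base ``init``; the run with the best final log-likelihood wins.
    """
    snps = list(cohort.snps)
    if not snps:
        raise ValidationError("empty SNP panel")
    patterns = _complete_patterns(cohort)
    if not patterns:
        raise ValidationError("no individual with complete genotypes at the panel SNPs")
    haps = _hap_universe(snps)
    hap_index = {h: i for i, h in enumerate(haps)}
    keys = list(patterns)
    counts = np.array([patterns[k] for k in keys], dtype=float)
    pair_lists = [_compatible_pairs(k, hap_index) for k in keys]

    rng = np.random.default_rng(seed)
    inits: list[np.ndarray] = []
    if init == "uniform":
        inits.append(np.full(len(haps), 1.0 / len(haps)))
    elif init == "random":
        inits.append(rng.dirichlet(np.ones(len(haps))))
    else:
        raise ValueError(f"unknown init {init!r}")
    for _ in range(n_restarts):
        inits.append(rng.dirichlet(np.ones(len(haps))))

    best = None
    for f0 in inits:
        run = _em_run(patterns, pair_lists, counts, f0, tol, max_iter)
        if best is None or run[1] > best[1]:  # strict: ties keep the earliest restart
            best = run
    f, ll, n_iter, converged, trace = best  # type: ignore[misc]
    f = f / f.sum()  # guard rounding drift
    return HaplotypeTable(
        snps=tuple(snps),
        freqs={h: float(f[i]) for h, i in hap_index.items()},
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_individuals=int(sum(patterns.values())),
        loglik_trace=trace,
    )


def marginalize_haplotypes(table: HaplotypeTable, snp_ids: list[str]) -> HaplotypeTable:
    """Sum a haplotype table down to a sub-panel of its SNPs."""
    idx = {s.snp_id: k for k, s in enumerate(table.snps)}
    take = [idx[s] for s in snp_ids]
    freqs: dict[str, float] = {}
    for hap, f in table.freqs.items():
        key = "".join(hap[k] for k in take)
        freqs[key] = freqs.get(key, 0.0) + f
    return HaplotypeTable(
        snps=tuple(table.snps[k] for k in take),
        freqs=freqs,
        loglik=math.nan,
        n_iter=table.n_iter,
        converged=table.converged,
        n_individuals=table.n_individuals,
    )


def ld_pair(table: HaplotypeTable) -> LDStats:
    """D, D' and r^2 for a two-SNP haplotype table.

    Conventions: D is computed on the major-major haplotype; D' = |D| / D_max
    with D_max the tightest frequency bound in the direction of D.
    """
    if len(table.snps) != 2:
        raise ValidationError("ld_pair needs a table over exactly two SNPs")
    s1, s2 = table.snps
    p_a = sum(f for h, f in table.freqs.items() if h[0] == s1.allele_major)
    p_b = sum(f for h, f in table.freqs.items() if h[1] == s2.allele_major)
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise ValidationError("monomorphic SNP: LD undefined")
    p_ab = table.freq(s1.allele_major + s2.allele_major)
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats((s1, s2), d, min(d_prime, 1.0), min(r2, 1.0))


def ld_matrix(cohort: CohortGenotypes, **em_kwargs) -> list[LDStats]:
    """Pairwise LD for every SNP pair, each from its own two-SNP EM fit."""
    out = []
    ids = [s.snp_id for s in cohort.snps]
    for i, j in itertools.combinations(range(len(ids)), 2):
        sub = cohort.subset_snps([ids[i], ids[j]])
        out.append(ld_pair(em_haplotype_freq(sub, **em_kwargs)))
    return out


def haplotype_association(
    case: CohortGenotypes,
    control: CohortGenotypes,
    min_freq: float = 0.05,
    alpha: float = 0.05,
    **em_kwargs,
) -> list[HaplotypeAssocResult]:
    """Per-haplotype case-control association on EM-estimated frequencies.

    EM on the pooled sample defines the haplotype set; EM per group gives the
    group frequencies. Haplotypes below ``min_freq`` in both groups are
    dropped. Each retained haplotype is tested haplotype-vs-all-others on a
    2x2 of expected chromosome counts (2n * freq, rounded); labels follow the
    usual Risk / Protector / NA convention at the ``alpha`` level.
    """
    if not case.samples or not control.samples:
        raise ValidationError("both groups must be nonempty")
    pooled = CohortGenotypes(list(case.snps), list(case.samples) + list(control.samples))
    t_pool = em_haplotype_freq(pooled, **em_kwargs)
    t_case = em_haplotype_freq(case, **em_kwargs)
    t_ctrl = em_haplotype_freq(control, **em_kwargs)
    results = []
    order = sorted(t_pool.freqs, key=lambda h: -t_pool.freqs[h])
    for hap in order:
        fc, fk = t_case.freq(hap), t_ctrl.freq(hap)
        if fc < min_freq and fk < min_freq:
            continue
        n2c, n2k = 2 * t_case.n_individuals, 2 * t_ctrl.n_individuals
        a = round(n2c * fc)
        b = n2c - a
        c = round(n2k * fk)
        d = n2k - c
        table = ContingencyTable2x2(a, b, c, d, label_exposure=hap)
        orr = odds_ratio(table)
        p = chi2_or_fisher(table, yates=False).p_value
        if p < alpha and orr.or_hat > 1:
            label: Literal["Risk", "Protector", "NA"] = "Risk"
        elif p < alpha and orr.or_hat < 1:
            label = "Protector"
        else:
            label = "NA"
        results.append(
            HaplotypeAssocResult(hap, fc, fk, orr.or_hat, orr.ci_low, orr.ci_high, p, label)
        )
    return results
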