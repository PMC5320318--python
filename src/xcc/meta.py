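"""Fixed-effect (inverse-variance) and DerSimonian-Laird random-effects
meta-analysis of per-study allele-count 2x2 tables.

Per study the effect is the log odds ratio with the Woolf variance
1/a + 1/b + 1/c + 1/d (+0.5 continuity on all four cells when any is zero).
Heterogeneity is summarized by Cochran's Q (chi-square, k-1 df),
I^2 = max(0, (Q - df)/Q) and the DL moment estimator
tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w). The pooled
log OR is the weighted mean with weights 1/v (fixed) or 1/(v + tau^2)
(random); significance is the normal Z test.

Model selection (``pool_auto``) uses the standard rule: random effects when
I^2 exceeds the threshold (default 50%), fixed effects otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats

from .tables_io import AlleleCounts, ContingencyTable2x2, ResultRecord, ValidationError

Z95 = 1.959963984540054


@dataclass(frozen=True)
class MetaStudy:
    study_id: str
    table: ContingencyTable2x2       # cases exposed/other, controls exposed/other
    log_or: float
    var_log_or: float
    continuity_applied: bool


@dataclass(frozen=True)
class MetaResult:
    model: Literal["fixed_iv", "random_dl"]
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p_z: float
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float
    weights: tuple[float, ...]       # normalized to sum 1
    model_auto_selected: bool = False


def study_from_table(study_id: str, table: ContingencyTable2x2) -> MetaStudy:
    """Attach log OR and Woolf variance to a 2x2 table; +0.5 continuity on all
    cells when any cell is zero."""
    a, b, c, d = table.cells
    if a + b == 0 or c + d == 0:
        raise ValidationError(f"{study_id}: a group has zero total")
    continuity = min(a, b, c, d) == 0
    if continuity:
        af, bf, cf, df_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        af, bf, cf, df_ = float(a), float(b), float(c), float(d)
    log_or = math.log((af * df_) / (bf * cf))
    var = 1 / af + 1 / bf + 1 / cf + 1 / df_
    return MetaStudy(study_id, table, log_or, var, continuity)


def study_from_alleles(
    study_id: str,
    case_alleles: AlleleCounts,
    control_alleles: AlleleCounts,
    exposed_allele: str,
) -> MetaStudy:
    """Orient per-group allele counts so ``exposed_allele`` is the exposure."""
    snp = case_alleles.snp
    if exposed_allele not in snp.alleles:
        raise ValidationError(f"{study_id}: {exposed_allele!r} is not an allele of {snp.snp_id}")
    if exposed_allele == snp.allele_major:
        a, b = case_alleles.n_major, case_alleles.n_minor
        c, d = control_alleles.n_major, control_alleles.n_minor
    else:
        a, b = case_alleles.n_minor, case_alleles.n_major
        c, d = control_alleles.n_minor, control_alleles.n_major
    table = ContingencyTable2x2(a, b, c, d, label_exposure=f"{snp.snp_id}:{exposed_allele}")
    return study_from_table(study_id, table)


def heterogeneity(studies: Sequence[MetaStudy]) -> tuple[float, int, float, float]:
    """Cochran's Q, its df, the chi-square p, and I^2."""
    if len(studies) < 2:
        raise ValidationError("heterogeneity needs at least two studies")
    w = [1.0 / s.var_log_or for s in studies]
    mu = sum(wi * s.log_or for wi, s in zip(w, studies)) / sum(w)
    q = sum(wi * (s.log_or - mu) ** 2 for wi, s in zip(w, studies))
    df = len(studies) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p_q, i2


def _pool(studies: Sequence[MetaStudy], tau2: float, model: str, auto: bool) -> MetaResult:
    w = [1.0 / (s.var_log_or + tau2) for s in studies]
    sw = sum(w)
    mu = sum(wi * s.log_or for wi, s in zip(w, studies)) / sw
    se = 1.0 / math.sqrt(sw)
    z = mu / se
    p_z = 2.0 * float(stats.norm.sf(abs(z)))
    if len(studies) >= 2:
        q, df, p_q, i2 = heterogeneity(studies)
    else:
        q, df, p_q, i2 = 0.0, 0, 1.0, 0.0
    return MetaResult(
        model=model,  # type: ignore[arg-type]
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - Z95 * se),
        ci_high=math.exp(mu + Z95 * se),
        z=z,
        p_z=p_z,
        Q=q,
        df=df,
        p_Q=p_q,
        I2=i2,
        tau2=tau2,
        weights=tuple(wi / sw for wi in w),
        model_auto_selected=auto,
    )


def pool_fixed(studies: Sequence[MetaStudy]) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    if not studies:
        raise ValidationError("no studies to pool")
    return _pool(studies, 0.0, "fixed_iv", False)


def dl_tau2(studies: Sequence[MetaStudy]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    q, df, _p, _i2 = heterogeneity(studies)
    w = [1.0 / s.var_log_or for s in studies]
    c = sum(w) - sum(wi * wi for wi in w) / sum(w)
    return max(0.0, (q - df) / c)


def pool_random_dl(studies: Sequence[MetaStudy]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    When Q <= df the moment estimate is truncated to tau^2 = 0 and the result
    coincides exactly with :func:`pool_fixed`.
    """
    if len(studies) < 2:
        raise ValidationError("random-effects pooling needs at least two studies")
    return _pool(studies, dl_tau2(studies), "random_dl", False)


def pool_auto(studies: Sequence[MetaStudy], i2_threshold: float = 0.5) -> MetaResult:
    """Fixed effects when I^2 <= threshold, DL random effects otherwise."""
    _q, _df, _p_q, i2 = heterogeneity(studies)
    if i2 > i2_threshold:
        res = pool_random_dl(studies)
    else:
        res = pool_fixed(studies)
    return MetaResult(**{**res.__dict__, "model_auto_selected": True})


def forest_table(result: MetaResult, studies: Sequence[MetaStudy]) -> list[ResultRecord]:
    """Tabular forest plot: per-study OR, 95% CI and weight %, plus the pooled row."""
    rows = []
    for s, w in zip(studies, result.weights):
        rows.append(
            ResultRecord(
                "forest",
                {
                    "study": s.study_id,
                    "or": math.exp(s.log_or),
                    "ci_low": math.exp(s.log_or - Z95 * math.sqrt(s.var_log_or)),
                    "ci_high": math.exp(s.log_or + Z95 * math.sqrt(s.var_log_or)),
                    "weight_pct": 100.0 * w,
                },
            )
        )
    rows.append(
        ResultRecord(
            "forest",
            {
                "study": f"pooled ({result.model})",
                "or": result.pooled_or,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "weight_pct": 100.0,
            },
        )
    )
    return rows
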