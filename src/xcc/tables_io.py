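"""Domain types and readers/writers for count-level and individual-level data.

Everything downstream (association tests, EM phasing, meta-analysis) operates on
the small set of containers defined here: per-SNP genotype or allele counts for a
(population, group) cell, 2x2 contingency tables, and per-individual unphased
genotype matrices with case/control labels.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

VALID_ALLELES = frozenset("ACGT")
MISSING = "."


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


@dataclass(frozen=True)
class SNPDef:
    """A biallelic SNP with a fixed major/minor allele orientation."""

    snp_id: str
    allele_major: str
    allele_minor: str
    chromosome_label: str = "X"

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValidationError(f"{self.snp_id}: major and minor alleles are identical")
        for a in (self.allele_major, self.allele_minor):
            if a not in VALID_ALLELES:
                raise ValidationError(f"{self.snp_id}: invalid allele {a!r}")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_major, self.allele_minor)


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts (hom-major, het, hom-minor) for one group at one SNP."""

    snp: SNPDef
    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self) -> None:
        for n in (self.n_hom_major, self.n_het, self.n_hom_minor):
            if n < 0:
                raise ValidationError(f"{self.snp.snp_id}: negative genotype count")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor


@dataclass(frozen=True)
class AlleleCounts:
    snp: SNPDef
    n_major: int
    n_minor: int

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValidationError(f"{self.snp.snp_id}: negative allele count")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-group 2x2 count table; the atom of every odds-ratio statistic.

    Layout: group 1 (a exposed, b unexposed), group 2 (c exposed, d unexposed).
    """

    a: int
    b: int
    c: int
    d: int
    label_exposure: str = "exposed"
    label_groups: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        for n in (self.a, self.b, self.c, self.d):
            if n < 0:
                raise ValidationError("negative cell in 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swapped_groups(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.c, self.d, self.a, self.b,
            label_exposure=self.label_exposure,
            label_groups=(self.label_groups[1], self.label_groups[0]),
        )


Genotype = tuple[str, str] | None


@dataclass
class CohortGenotypes:
    """Per-individual unphased diploid genotypes at an ordered SNP panel.

    ``samples`` holds (sample_id, group, genotypes) with one genotype slot per
    SNP; each genotype is an order-normalized allele pair (major allele first)
    or ``None`` for missing.
    """

    snps: list[SNPDef]
    samples: list[tuple[str, str, tuple[Genotype, ...]]]

    def __post_init__(self) -> None:
        for sid, _group, gts in self.samples:
            if len(gts) != len(self.snps):
                raise ValidationError(f"sample {sid}: wrong number of genotype slots")
            for snp, gt in zip(self.snps, gts):
                if gt is None:
                    continue
                for allele in gt:
                    if allele not in snp.alleles:
                        raise ValidationError(
                            f"sample {sid}: allele {allele!r} not in {snp.snp_id} ({snp.alleles})"
                        )

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for _sid, g, _gts in self.samples:
            seen.setdefault(g, None)
        return list(seen)

    def subset_group(self, group: str) -> "CohortGenotypes":
        return CohortGenotypes(self.snps, [s for s in self.samples if s[1] == group])

    def subset_snps(self, snp_ids: Sequence[str]) -> "CohortGenotypes":
        idx = {snp.snp_id: i for i, snp in enumerate(self.snps)}
        try:
            take = [idx[s] for s in snp_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown SNP {exc.args[0]!r}") from None
        snps = [self.snps[i] for i in take]
        samples = [
            (sid, group, tuple(gts[i] for i in take)) for sid, group, gts in self.samples
        ]
        return CohortGenotypes(snps, samples)

    def genotype_counts(self, snp_id: str, group: str) -> GenotypeCounts:
        (snp,) = [s for s in self.snps if s.snp_id == snp_id]
        i = self.snps.index(snp)
        n_maj = n_het = n_min = 0
        for _sid, g, gts in self.samples:
            if g != group or gts[i] is None:
                continue
            k = sum(1 for a in gts[i] if a == snp.allele_minor)
            if k == 0:
                n_maj += 1
            elif k == 1:
                n_het += 1
            else:
                n_min += 1
        return GenotypeCounts(snp, n_maj, n_het, n_min)


@dataclass
class ResultRecord:
    """A flat named-statistics row, serializable to TSV and JSON."""

    analysis: str
    values: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# counts dialect
# ---------------------------------------------------------------------------

_COUNT_COLS = ["population", "group", "snp", "n_hom_major", "n_het", "n_hom_minor"]
_ALLELE_META_COLS = ["allele_major", "allele_minor", "chrom"]


def _split_header(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_genotype_counts(
    path: str | Path,
    snp_defs: Mapping[str, SNPDef] | None = None,
) -> list[tuple[str, str, GenotypeCounts]]:
    """Read the long-format genotype-counts dialect.

    Header columns ``population group snp n_hom_major n_het n_hom_minor`` are
    required; ``allele_major allele_minor chrom`` are optional and, when
    absent, SNP definitions must be supplied via ``snp_defs``.
    """
    path = Path(path)
    out: list[tuple[str, str, GenotypeCounts]] = []
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = _split_header(lines[0])
    for col in _COUNT_COLS:
        if col not in header:
            raise ParseError(f"{path}: missing column {col!r}")
    has_alleles = all(c in header for c in _ALLELE_META_COLS[:2])
    col = {name: header.index(name) for name in header}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split_header(line)
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        try:
            counts = [int(fields[col[c]]) for c in _COUNT_COLS[3:]]
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer count") from None
        snp_id = fields[col["snp"]]
        if has_alleles:
            snp = SNPDef(
                snp_id,
                fields[col["allele_major"]],
                fields[col["allele_minor"]],
                fields[col["chrom"]] if "chrom" in col else "X",
            )
        elif snp_defs is not None and snp_id in snp_defs:
            snp = snp_defs[snp_id]
        else:
            raise ParseError(f"{path}:{lineno}: no allele columns and no SNP definition for {snp_id!r}")
        out.append((fields[col["population"]], fields[col["group"]], GenotypeCounts(snp, *counts)))
    return out


def write_genotype_counts(
    records: Iterable[tuple[str, str, GenotypeCounts]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_COUNT_COLS + _ALLELE_META_COLS) + "\n")
        for pop, group, g in records:
            fh.write(
                "\t".join(
                    [
                        pop, group, g.snp.snp_id,
                        str(g.n_hom_major), str(g.n_het), str(g.n_hom_minor),
                        g.snp.allele_major, g.snp.allele_minor, g.snp.chromosome_label,
                    ]
                )
                + "\n"
            )


def genotype_to_allele_counts(g: GenotypeCounts) -> AlleleCounts:
    """Collapse diploid genotype counts to chromosome-level allele counts.

    Conserves 2N chromosomes: n_major + n_minor == 2 * g.total.
    """
    if g.total == 0:
        raise ValidationError(f"{g.snp.snp_id}: cannot derive allele counts from zero individuals")
    return AlleleCounts(g.snp, 2 * g.n_hom_major + g.n_het, 2 * g.n_hom_minor + g.n_het)


# ---------------------------------------------------------------------------
# cohort TSV
# ---------------------------------------------------------------------------


def _normalize_pair(pair: tuple[str, str], snp: SNPDef) -> tuple[str, str]:
    # major-first normalization: "A/G" and "G/A" are the same unphased genotype
    a, b = pair
    if a == snp.allele_major or (b != snp.allele_major and a <= b):
        return (a, b)
    return (b, a)


def infer_snp_defs(
    snp_ids: Sequence[str],
    raw_samples: Sequence[tuple[str, str, list[tuple[str, str] | None]]],
    chromosome_label: str = "X",
) -> list[SNPDef]:
    """Assign major/minor per SNP from CONTROL-group allele frequencies.

    Falls back to all samples when no control group is present; ties broken
    lexicographically so the orientation is deterministic.
    """
    defs = []
    for j, snp_id in enumerate(snp_ids):
        pool = [s for s in raw_samples if s[1] == "control"] or list(raw_samples)
        counts: Counter[str] = Counter()
        for _sid, _grp, gts in pool:
            if gts[j] is not None:
                counts.update(gts[j])
        # include alleles seen only outside controls so biallelic validation is global
        observed: Counter[str] = Counter()
        for _sid, _grp, gts in raw_samples:
            if gts[j] is not None:
                observed.update(gts[j])
        alleles = sorted(observed)
        if len(alleles) > 2:
            raise ValidationError(f"{snp_id}: more than two alleles observed: {alleles}")
        if len(alleles) < 2:
            raise ValidationError(f"{snp_id}: monomorphic in the input; cannot orient alleles")
        ordered = sorted(alleles, key=lambda a: (-counts[a], a))
        defs.append(SNPDef(snp_id, ordered[0], ordered[1], chromosome_label))
    return defs


def read_cohort_tsv(
    path: str | Path, snp_defs: Mapping[str, SNPDef] | None = None
) -> CohortGenotypes:
    """Read a per-individual genotype matrix (``sample_id group snp1 ...``).

    Genotypes are written ``X/Y`` or ``.`` for missing. Major/minor orientation
    comes from ``snp_defs`` when given, else is inferred from control-group
    allele frequencies.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = _split_header(lines[0])
    if header[:2] != ["sample_id", "group"]:
        raise ParseError(f"{path}: header must start with 'sample_id\\tgroup'")
    snp_ids = header[2:]
    raw: list[tuple[str, str, list[tuple[str, str] | None]]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split_header(line)
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        gts: list[tuple[str, str] | None] = []
        for tok in fields[2:]:
            if tok == MISSING:
                gts.append(None)
                continue
            parts = tok.split("/")
            if len(parts) != 2 or not all(parts):
                raise ParseError(f"{path}:{lineno}: bad genotype token {tok!r}")
            gts.append((parts[0], parts[1]))
        raw.append((fields[0], fields[1], gts))
    if snp_defs is not None:
        defs = []
        for s in snp_ids:
            if s not in snp_defs:
                raise ValidationError(f"{path}: no SNP definition supplied for {s!r}")
            defs.append(snp_defs[s])
    else:
        defs = infer_snp_defs(snp_ids, raw)
    samples = [
        (sid, grp, tuple(None if gt is None else _normalize_pair(gt, snp)
                         for gt, snp in zip(gts, defs)))
        for sid, grp, gts in raw
    ]
    return CohortGenotypes(defs, samples)


def write_cohort_tsv(cohort: CohortGenotypes, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["sample_id", "group"] + [s.snp_id for s in cohort.snps]) + "\n")
        for sid, group, gts in cohort.samples:
            toks = [MISSING if gt is None else f"{gt[0]}/{gt[1]}" for gt in gts]
            fh.write("\t".join([sid, group] + toks) + "\n")


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------


def read_vcf_minimal(path: str | Path, groups: Mapping[str, str]) -> CohortGenotypes:
    """Read biallelic SNP records from a VCF (GT only) into a cohort.

    Phase separators are accepted but phase is discarded (downstream EM assumes
    unphased data); half-calls and ``./.`` become missing. Multi-allelic
    records are skipped. Every VCF sample must appear in ``groups``.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    for sid in sample_ids:
        if sid not in groups:
            raise ValidationError(f"VCF sample {sid!r} absent from the group map")
    snps: list[SNPDef] = []
    per_snp_calls: list[list[Genotype]] = []
    for rec in vf.fetch() if vf.index is not None else vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue  # multi-allelic or ALT-less records are out of contract
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_ALLELES or alt not in VALID_ALLELES:
            continue
        snp = SNPDef(rec.id or f"{rec.chrom}:{rec.pos}", ref, alt, rec.chrom)
        calls: list[Genotype] = []
        for sid in sample_ids:
            gt = rec.samples[sid].get("GT")
            if gt is None or len(gt) != 2 or any(x is None for x in gt):
                calls.append(None)
                continue
            pair = tuple(ref if x == 0 else alt for x in gt)
            calls.append(_normalize_pair(pair, snp))  # type: ignore[arg-type]
        snps.append(snp)
        per_snp_calls.append(calls)
    samples = [
        (sid, groups[sid], tuple(per_snp_calls[j][i] for j in range(len(snps))))
        for i, sid in enumerate(sample_ids)
    ]
    return CohortGenotypes(snps, samples)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _fmt(v: object) -> str:
    if isinstance(v, float):
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        if math.isnan(v):
            return "nan"
        return f"{v:.6g}"
    return str(v)


def write_records_tsv(records: Sequence[ResultRecord], path: str | Path) -> None:
    """One record per row; union of keys in first-seen order; floats at 6 sig digits."""
    cols: list[str] = []
    for rec in records:
        for k in rec.values:
            if k not in cols:
                cols.append(k)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["analysis"] + cols) + "\n")
        for rec in records:
            fh.write("\t".join([rec.analysis] + [_fmt(rec.values.get(c, "")) for c in cols]) + "\n")


def write_records_json(records: Sequence[ResultRecord], path: str | Path) -> None:
    grouped: dict[str, list[dict[str, object]]] = {}
    for rec in records:
        row = {
            k: ("inf" if isinstance(v, float) and math.isinf(v) and v > 0
                else "-inf" if isinstance(v, float) and math.isinf(v)
                else float(f"{v:.6g}") if isinstance(v, float) else v)
            for k, v in rec.values.items()
        }
        grouped.setdefault(rec.analysis, []).append(row)
    Path(path).write_text(json.dumps(grouped, indent=1) + "\n")
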