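"""Loaders for the packaged count-table fixtures.

The raw per-individual genotypes behind the case-control cohorts were never
released; what is packaged here are the published count-level summaries
(genotype, allele, HLA-allele and shared-epitope dose counts, plus the
per-study allele tables of the replication meta-analysis), transcribed to TSV.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .tables_io import GenotypeCounts, SNPDef, read_genotype_counts

SNP_PANEL = ["rs13397", "rs1059703", "rs1059702"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("xcc").joinpath("data", name)))


def _read_tsv(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t", comment="#")


def load_genotype_counts() -> list[tuple[str, str, GenotypeCounts]]:
    """All per-(population, group, SNP) genotype counts."""
    return read_genotype_counts(_data_path("genotype_counts.tsv"))


def genotype_counts_map() -> dict[tuple[str, str, str], GenotypeCounts]:
    """Same records keyed by (population, group, snp_id)."""
    return {(pop, grp, g.snp.snp_id): g for pop, grp, g in load_genotype_counts()}


def load_allele_counts() -> pd.DataFrame:
    return _read_tsv("allele_counts.tsv")


def load_hla_counts() -> pd.DataFrame:
    """HLA-DRB1 allele-group counts, Tunisian vs French RA cases."""
    return _read_tsv("hla_drb1_counts.tsv")


def load_meta_counts() -> pd.DataFrame:
    """Per-study allele-level 2x2 tables for the pooled analyses."""
    return _read_tsv("meta_allele_counts.tsv")


def load_se_dose() -> pd.DataFrame:
    return _read_tsv("se_dose.tsv")


def snp_defs() -> dict[str, SNPDef]:
    return {g.snp.snp_id: g.snp for _pop, _grp, g in load_genotype_counts()}
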