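"""Bundled reference data: published endogenous virgin-olive-oil peptides.

The package ships, as plain text, the characterised VOO peptide set — 19
database-search identifications and 8 de novo sequences — together with the
published per-protein roll-up, activity-profile values (parameters A and B),
predicted digestion fragments and measured assay results for the synthesised
candidates.  These serve as worked inputs and as regression surfaces for the
pipeline; columns keep the identification-report layout.

Rows of the activity and digestion tables carry a consistency flag: a few
printed values contradict the row's own inputs (swapped or misaligned
columns in the source tables) and are marked ``consistent = 0`` /
``rule_consistent = 0`` so that exact-reproduction checks can skip known
transcription artifacts while keeping the printed values available verbatim.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .reports import PeptideRecord, read_report

__all__ = [
    "voo_db_records",
    "voo_denovo_records",
    "voo_activity_reference",
    "voo_digestion_reference",
    "voo_assay_reference",
    "voo_protein_reference",
    "voo_sequences",
    "SELECTED_FOR_SYNTHESIS",
    "ACTIVE_PEPTIDES",
]

#: The nine sequences selected for synthesis and in-vitro testing.
SELECTED_FOR_SYNTHESIS = (
    "LDTANEMNQLDLQFR", "VVLQDTSNNVNQLD", "IFSGGESSGQPR", "QDTSNNVNQLDDIPRR",
    "VCGEAFGKA", "NALLCSNS", "CPANGFY", "CCYSVY", "DCHYFL",
)

#: The five peptides with measured ACE-inhibitory and antioxidant activity.
ACTIVE_PEPTIDES = ("VCGEAFGKA", "NALLCSNS", "CPANGFY", "CCYSVY", "DCHYFL")


def _data_path(name: str):
    return resources.as_file(resources.files("oleopep.data").joinpath(name))


def _read_tsv(name: str) -> pd.DataFrame:
    with _data_path(name) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def voo_db_records() -> List[PeptideRecord]:
    """The 19 database-search identifications as parsed records."""
    with _data_path("voo_peaksdb_report.tsv") as p:
        return read_report(p, flavour="db")


def voo_denovo_records() -> List[PeptideRecord]:
    """The 8 de novo identifications as parsed records."""
    with _data_path("voo_denovo_report.tsv") as p:
        return read_report(p, flavour="denovo")


def voo_activity_reference() -> pd.DataFrame:
    """Published activity profiles: dataset, peptide, activity, count, A, B."""
    df = _read_tsv("voo_activity_reference.tsv")
    for col in ("count", "A", "B"):
        df[col] = pd.to_numeric(df[col].replace("", pd.NA))
    df["consistent"] = df["consistent"].astype(int).astype(bool)
    return df


def voo_digestion_reference() -> pd.DataFrame:
    """Published per-enzyme digestion fragments in hyphen-joined notation."""
    df = _read_tsv("voo_digestion_reference.tsv")
    df["rule_consistent"] = df["rule_consistent"].astype(int).astype(bool)
    return df


def voo_assay_reference() -> pd.DataFrame:
    """Measured IC50 (µM) and TEAC of the synthesised candidates (ND = NaN)."""
    df = _read_tsv("voo_assay_reference.tsv")
    for col in ("ic50_uM", "ic50_sd", "teac", "teac_sd"):
        df[col] = pd.to_numeric(df[col].replace("ND", pd.NA))
    return df


def voo_protein_reference() -> pd.DataFrame:
    """Published protein roll-up (score, supporting-peptide count, area)."""
    df = _read_tsv("voo_protein_reference.tsv")
    for col in ("protein_neg10lgP", "n_peptides", "cover_percent", "area"):
        df[col] = pd.to_numeric(df[col])
    return df


def voo_sequences() -> List[str]:
    """All 27 reference sequences (bare, db then de novo order)."""
    return [r.bare_sequence for r in voo_db_records()] + [
        r.bare_sequence for r in voo_denovo_records()
    ]
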