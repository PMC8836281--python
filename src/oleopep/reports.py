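"""Reading, filtering and protein roll-up of peptide identification reports.

Two report flavours are supported, mirroring the exports of database-search
and de novo sequencing engines:

* ``db`` — database-search rows carry a ``-10lgP`` peptide-spectrum-match
  significance score (−10·log10 of the match p-value).
* ``denovo`` — de novo rows carry per-residue local-confidence percentages
  and their mean, the ALC (average local confidence).

Acceptance filtering follows the published screen: score above threshold
(−10 lgP ≥ 30, i.e. p ≤ 0.001, for database hits; ALC ≥ 90 % for de novo),
charge state ≥ +2, and replication in at least two individual samples.
Protein abundance is the plain sum of supporting-peptide areas, with
not-detected areas counted as zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pandas as pd

from .peptide import Peptide, parse_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideRecord",
    "ProteinRollup",
    "FilterPolicy",
    "AlcResult",
    "read_report",
    "write_report",
    "records_to_frame",
    "compute_alc",
    "neg10lgP_from_p",
    "apply_filters",
    "rollup_proteins",
    "rollups_to_json",
]


@dataclass(frozen=True)
class PeptideRecord:
    """One identification-report row.

    Exactly one of ``neg10lgP`` (db flavour) / ``alc_percent`` (denovo
    flavour) is set.  ``area`` is ``None`` when the report prints "ND".
    """

    peptide: Peptide
    observed_mz: float
    z: int
    sample_id: str = "s1"
    neg10lgP: Optional[float] = None
    alc_percent: Optional[float] = None
    local_confidence: Tuple[float, ...] = ()
    observed_mass: Optional[float] = None
    rt: Optional[float] = None
    ppm: Optional[float] = None
    area: Optional[float] = None
    accessions: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.neg10lgP is None) == (self.alc_percent is None):
            raise ValueError(
                "exactly one of neg10lgP / alc_percent must be set "
                f"(got {self.neg10lgP!r}, {self.alc_percent!r})"
            )
        if self.local_confidence:
            if len(self.local_confidence) != len(self.peptide):
                raise ValueError(
                    f"local confidence length {len(self.local_confidence)} != "
                    f"peptide length {len(self.peptide)} for {self.peptide}"
                )
            if not all(0 <= c <= 100 for c in self.local_confidence):
                raise ValueError("local confidence entries must be in [0, 100]")

    @property
    def flavour(self) -> str:
        return "db" if self.neg10lgP is not None else "denovo"

    @property
    def bare_sequence(self) -> str:
        return self.peptide.sequence


@dataclass(frozen=True)
class ProteinRollup:
    """Per-protein aggregate over its supporting peptide records."""

    accession: str
    protein_neg10lgP: float
    n_supporting: int
    total_area: float
    coverage_percent: Optional[float] = None
    supporting: Tuple[PeptideRecord, ...] = ()


@dataclass(frozen=True)
class FilterPolicy:
    """Acceptance thresholds for identification records."""

    min_neg10lgP: float = 30.0
    min_alc: float = 90.0
    min_samples: int = 2
    min_charge: int = 2
    #: key sample replication on the modification-stripped sequence, so that
    #: e.g. oxidised and unmodified forms of one peptide pool their evidence
    strip_modifications: bool = True

    def __post_init__(self) -> None:
        if min(self.min_neg10lgP, self.min_alc, self.min_samples, self.min_charge) < 0:
            raise ValueError("thresholds must be non-negative")


class AlcResult(NamedTuple):
    """Mean local confidence, unrounded and rounded for table comparison."""

    mean: float
    rounded: int


def compute_alc(local_confidence: Sequence[float], rounding: str = "floor") -> AlcResult:
    """Average local confidence of a de novo sequence.

    The mean of the per-residue confidence percentages, plus an integer
    rendering for comparison with printed report values.  ``rounding`` is
    ``"floor"`` (truncation, the default — it reproduces the most printed
    values) or ``"half_up"``.
    """
    if not local_confidence:
        raise ValueError("local confidence list is empty")
    mean = sum(local_confidence) / len(local_confidence)
    if rounding == "floor":
        rounded = math.floor(mean)
    elif rounding == "half_up":
        rounded = math.floor(mean + 0.5)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return AlcResult(mean, rounded)


def neg10lgP_from_p(p_value: float) -> float:
    """−10·log10(p): the report significance score for a match p-value."""
    if not 0 < p_value <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p_value}")
    return -10.0 * math.log10(p_value)


# -- report I/O -------------------------------------------------------------

_COLUMN_ALIASES = {
    "peptide": "peptide", "sequence": "peptide",
    "-10lgp": "neg10lgP", "neg10lgp": "neg10lgP", "-10 lgp": "neg10lgP",
    "alc (%)": "alc_percent", "alc": "alc_percent", "alc_percent": "alc_percent",
    "local confidence (%)": "local_confidence", "local_confidence": "local_confidence",
    "m/z": "observed_mz", "mz": "observed_mz", "observed_mz": "observed_mz",
    "mass": "observed_mass", "observed_mass": "observed_mass",
    "z": "z", "charge": "z",
    "rt": "rt", "ppm": "ppm", "area": "area",
    "sample": "sample_id", "sample_id": "sample_id",
    "accession": "accessions", "accessions": "accessions",
}

_MANDATORY = {"db": {"peptide", "neg10lgP", "observed_mz", "z"},
              "denovo": {"peptide", "local_confidence", "observed_mz", "z"}}


class SchemaError(ValueError):
    """Report header does not satisfy the column contract."""


def _normalise_columns(df: pd.DataFrame, extra_aliases: Optional[Mapping[str, str]]) -> pd.DataFrame:
    aliases = dict(_COLUMN_ALIASES)
    if extra_aliases:
        aliases.update({k.lower(): v for k, v in extra_aliases.items()})
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in aliases:
            renames[col] = aliases[key]
    return df.rename(columns=renames)


def _parse_area(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "ND", "nd", "NA"):
        return None
    return float(s)


def read_report(
    path,
    flavour: str,
    column_aliases: Optional[Mapping[str, str]] = None,
) -> List[PeptideRecord]:
    """Read a delimited-text identification report (CSV/TSV autodetected).

    Raises :class:`SchemaError` listing any missing mandatory columns, and
    ``ValueError`` for row-level problems (e.g. a local-confidence string
    whose length does not match the sequence).
    """
    if flavour not in ("db", "denovo"):
        raise ValueError(f"flavour must be 'db' or 'denovo', got {flavour!r}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df = _normalise_columns(df, column_aliases)
    missing = _MANDATORY[flavour] - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    records: List[PeptideRecord] = []
    for i, row in df.iterrows():
        peptide = parse_sequence(row["peptide"].strip())
        kwargs: dict = dict(
            peptide=peptide,
            observed_mz=float(row["observed_mz"]),
            z=int(row["z"]),
        )
        if flavour == "db":
            kwargs["neg10lgP"] = float(row["neg10lgP"])
        else:
            conf = tuple(float(x) for x in str(row["local_confidence"]).split())
            if len(conf) != len(peptide):
                raise ValueError(
                    f"row {i}: local confidence has {len(conf)} entries for "
                    f"{len(peptide)}-residue peptide {peptide}"
                )
            kwargs["local_confidence"] = conf
            kwargs["alc_percent"] = (
                float(row["alc_percent"]) if row.get("alc_percent", "") != ""
                else compute_alc(conf).mean
            )
        for name in ("observed_mass", "rt", "ppm"):
            if name in df.columns and str(row[name]).strip() != "":
                kwargs[name] = float(row[name])
        if "area" in df.columns:
            kwargs["area"] = _parse_area(row["area"])
        if "sample_id" in df.columns and str(row["sample_id"]).strip() != "":
            kwargs["sample_id"] = str(row["sample_id"]).strip()
        if "accessions" in df.columns and str(row["accessions"]).strip() != "":
            kwargs["accessions"] = tuple(str(row["accessions"]).split(":"))
        records.append(PeptideRecord(**kwargs))
    return records


def records_to_frame(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    """Render records to a DataFrame in the report column layout."""
    rows = []
    for r in records:
        rows.append({
            "peptide": str(r.peptide),
            "neg10lgP": r.neg10lgP,
            "alc_percent": r.alc_percent,
            "local_confidence": " ".join(f"{c:g}" for c in r.local_confidence),
            "observed_mz": r.observed_mz,
            "observed_mass": r.observed_mass,
            "z": r.z,
            "rt": r.rt,
            "ppm": r.ppm,
            "area": "ND" if r.area is None else f"{r.area:g}",
            "sample_id": r.sample_id,
            "accessions": ":".join(r.accessions),
        })
    return pd.DataFrame(rows)


def write_report(records: Sequence[PeptideRecord], path, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# -- filtering --------------------------------------------------------------

def apply_filters(
    records: Sequence[PeptideRecord], policy: FilterPolicy = FilterPolicy()
) -> List[PeptideRecord]:
    """Apply the acceptance screen, preserving input order.

    A record is retained iff its flavour score passes (−10 lgP or ALC),
    charge ≥ ``min_charge``, and its sequence occurs in at least
    ``min_samples`` distinct samples.  Mixing flavours in one call is a usage
    error.
    """
    if not records:
        return []
    flavours = {r.flavour for r in records}
    if len(flavours) > 1:
        raise ValueError("apply_filters requires records of a single flavour")

    def seq_key(r: PeptideRecord) -> str:
        return r.bare_sequence if policy.strip_modifications else str(r.peptide)

    samples_per_seq: Dict[str, set] = {}
    for r in records:
        samples_per_seq.setdefault(seq_key(r), set()).add(r.sample_id)

    kept = []
    for r in records:
        if r.flavour == "db":
            if r.neg10lgP < policy.min_neg10lgP:
                continue
        else:
            if r.alc_percent < policy.min_alc:
                continue
        if r.z < policy.min_charge:
            continue
        if len(samples_per_seq[seq_key(r)]) < policy.min_samples:
            continue
        kept.append(r)
    return kept


# -- protein roll-up --------------------------------------------------------

def _sum_scores(scores: Sequence[float]) -> float:
    return float(sum(scores))


def rollup_proteins(
    records: Sequence[PeptideRecord],
    protein_lengths: Optional[Mapping[str, int]] = None,
    peptide_positions: Optional[Mapping[Tuple[str, str], Tuple[int, int]]] = None,
    score_aggregator: Callable[[Sequence[float]], float] = _sum_scores,
) -> List[ProteinRollup]:
    """Roll peptide records up to their proteins.

    ``total_area`` sums supporting areas with not-detected areas as zero.
    Coverage is computed only when both a protein length and 0-based
    half-open peptide positions ``(accession, bare_sequence) -> (start, end)``
    are supplied; otherwise it is absent.  The protein score defaults to the
    plain sum of supporting-peptide scores; pass ``score_aggregator`` to
    plug in a weighting scheme.
    """
    by_accession: Dict[str, List[PeptideRecord]] = {}
    for r in records:
        if not r.accessions:
            raise ValueError(f"record {r.peptide} lists no accession")
        for acc in r.accessions:
            by_accession.setdefault(acc, []).append(r)

    rollups = []
    for acc in sorted(by_accession):
        supp = by_accession[acc]
        total_area = sum(r.area or 0.0 for r in supp)
        scores = [r.neg10lgP if r.neg10lgP is not None else r.alc_percent for r in supp]
        coverage = None
        if protein_lengths is not None and acc in protein_lengths and peptide_positions:
            covered: set = set()
            have_positions = False
            for r in supp:
                pos = peptide_positions.get((acc, r.bare_sequence))
                if pos is not None:
                    have_positions = True
                    covered.update(range(pos[0], pos[1]))
            if have_positions:
                coverage = 100.0 * len(covered) / protein_lengths[acc]
        elif protein_lengths is not None and acc not in protein_lengths:
            logger.warning("accession %s not in protein_lengths; coverage absent", acc)
        rollups.append(
            ProteinRollup(
                accession=acc,
                protein_neg10lgP=score_aggregator(scores),
                n_supporting=len(supp),
                total_area=total_area,
                coverage_percent=coverage,
                supporting=tuple(supp),
            )
        )
    return rollups


def rollups_to_json(rollups: Sequence[ProteinRollup], path=None) -> str:
    """Serialise roll-ups to JSON (supporting peptides by sequence)."""
    payload = [
        {
            "accession": r.accession,
            "protein_neg10lgP": r.protein_neg10lgP,
            "n_supporting": r.n_supporting,
            "total_area": r.total_area,
            "coverage_percent": r.coverage_percent,
            "supporting": [str(s.peptide) for s in r.supporting],
        }
        for r in rollups
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
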