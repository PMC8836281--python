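"""Bioactive-fragment dictionary and substring scanning.

Short peptide fragments (1–10 residues) with experimentally reported
activities — ACE inhibition, DPP-III/IV inhibition, antioxidant capacity,
renin inhibition, opioid activity — are matched as contiguous substrings of a
query peptide.  The bundled default library is a small curated set in which
every fragment and every EC50 is traceable to published in-vitro data for
olive-oil peptide fragments (e.g. VY 7.1 µM, SVY 8.1 µM, KA 31.5 µM, FL
15.8 µM for ACE); users screening against a full reference dictionary load
their own export with :func:`load_library`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import pandas as pd

from .peptide import Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVITY_CLASSES",
    "MotifRecord",
    "MotifLibrary",
    "MotifHit",
    "load_library",
    "default_library",
    "scan",
]

#: Enumerated activity classes; anything else is carried as ``other:<label>``.
ACTIVITY_CLASSES = (
    "ACE_inhibitor",
    "DPP_IV_inhibitor",
    "DPP_III_inhibitor",
    "antioxidant",
    "renin_inhibitor",
    "opioid",
)


@dataclass(frozen=True)
class MotifRecord:
    """A short bioactive fragment with its activity class and optional EC50."""

    fragment: str
    activity: str
    ec50_uM: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.fragment) < 1:
            raise ValueError("fragment must have >= 1 residue")
        if self.ec50_uM is not None and self.ec50_uM <= 0:
            raise ValueError(f"EC50 must be positive, got {self.ec50_uM}")
        if self.activity not in ACTIVITY_CLASSES and not self.activity.startswith("other:"):
            raise ValueError(f"unknown activity class {self.activity!r}")


@dataclass(frozen=True)
class MotifLibrary:
    """A validated set of motif records indexed by fragment."""

    records: Tuple[MotifRecord, ...]
    index: Dict[str, Tuple[MotifRecord, ...]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        idx: Dict[str, List[MotifRecord]] = {}
        seen: Dict[Tuple[str, str], MotifRecord] = {}
        for rec in self.records:
            key = (rec.fragment, rec.activity)
            if key in seen:
                logger.warning("duplicate motif %s/%s: last record wins", *key)
            seen[key] = rec
        deduped = tuple(seen.values())
        for rec in deduped:
            idx.setdefault(rec.fragment, []).append(rec)
        object.__setattr__(self, "records", deduped)
        object.__setattr__(self, "index", {f: tuple(rs) for f, rs in idx.items()})

    def __len__(self) -> int:
        return len(self.records)

    @property
    def max_fragment_length(self) -> int:
        return max((len(f) for f in self.index), default=0)

    def union(self, other: "MotifLibrary") -> "MotifLibrary":
        return MotifLibrary(self.records + other.records)


def load_library(path) -> MotifLibrary:
    """Load a library from delimited text (fragment, activity, ec50_uM, source).

    Duplicate (fragment, activity) rows: the last one wins, with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    records = []
    for i, row in df.iterrows():
        ec50_raw = str(row.get("ec50_um", "")).strip()
        try:
            ec50 = float(ec50_raw) if ec50_raw else None
        except ValueError as exc:
            raise ValueError(f"row {i}: malformed EC50 {ec50_raw!r}") from exc
        records.append(
            MotifRecord(
                fragment=row["fragment"].strip(),
                activity=row["activity"].strip(),
                ec50_uM=ec50,
                source=str(row.get("source", "")).strip(),
            )
        )
    return MotifLibrary(tuple(records))


def default_library() -> MotifLibrary:
    """The bundled curated library (see module docstring)."""
    with resources.as_file(
        resources.files("oleopep.data").joinpath("bioactive_motifs.tsv")
    ) as p:
        return load_library(p)


class MotifHit(NamedTuple):
    """One motif occurrence: fragment, 0-based start position, record."""

    fragment: str
    position: int
    record: MotifRecord


def scan(p: Peptide, lib: MotifLibrary, activity: Optional[str] = None) -> List[MotifHit]:
    """Find every occurrence of every library fragment in the bare sequence.

    Hits are ordered by position, then fragment.  ``activity`` restricts the
    scan to one class; by default all classes are reported.
    """
    seq = p.sequence
    hits: List[MotifHit] = []
    for start in range(len(seq)):
        for length in range(1, min(lib.max_fragment_length, len(seq) - start) + 1):
            frag = seq[start:start + length]
            for rec in lib.index.get(frag, ()):
                if activity is None or rec.activity == activity:
                    hits.append(MotifHit(frag, start, rec))
    hits.sort(key=lambda h: (h.position, h.fragment, h.record.activity))
    return hits
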