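"""Multi-criterion screen for synthesis-candidate peptides.

The screen mirrors the criteria used to pick peptides for wet-lab synthesis:
water solubility (hydrophobic fraction not too high), predicted ACE-inhibitory
and antioxidant activity, survival of an active fragment through simulated
digestion, relative abundance, hydrophobic/basic residues near the C-terminus,
and cysteine content.  Each criterion yields an independent pass/fail/absent
flag; the overall verdict requires every *required* criterion to pass, with
missing data recorded as absent rather than failure (expert judgement on such
rows is left to the user, which is why flags are exposed rather than a single
boolean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .digestion import DigestResult
from .peptide import DEFAULT_CLASSES, Peptide, ResidueClassConfig, cterm_rule, hydrophobic_fraction
from .reports import PeptideRecord
from .scoring import ActivityProfile

__all__ = ["SelectionCriteria", "CandidateReport", "evaluate", "rank", "reports_to_frame"]

PASS, FAIL, ABSENT = "pass", "fail", "absent"


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds and switches of the candidate screen."""

    max_hydrophobic_fraction: float = 0.85
    require_predicted_activity: frozenset = frozenset({"ACE_inhibitor", "antioxidant"})
    require_digestion_survival: bool = True
    min_area: Optional[float] = None
    require_cterm_rule: bool = True
    require_cysteine: bool = False  # scored, not required, by default
    residue_classes: ResidueClassConfig = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if not 0 <= self.max_hydrophobic_fraction <= 1:
            raise ValueError("max_hydrophobic_fraction must be in [0, 1]")
        object.__setattr__(
            self, "require_predicted_activity", frozenset(self.require_predicted_activity)
        )

    @classmethod
    def from_yaml(cls, path) -> "SelectionCriteria":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class CandidateReport:
    peptide: Peptide
    criterion_flags: Mapping[str, str]
    area: Optional[float] = None

    @property
    def n_passed(self) -> int:
        return sum(1 for v in self.criterion_flags.values() if v == PASS)

    @property
    def overall_pass(self) -> bool:
        """No required criterion failed (absent data does not block)."""
        return FAIL not in self.criterion_flags.values()


def evaluate(
    p: Peptide,
    activity_profile: ActivityProfile,
    digests: Mapping[str, DigestResult],
    record: Optional[PeptideRecord] = None,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> CandidateReport:
    """Evaluate one peptide against the screen.

    ``digests`` should carry annotations (see
    :func:`oleopep.digestion.annotate_fragments`); digestion survival means at
    least one fragment with a required activity class survives some enzyme.
    All inputs must describe the same peptide.
    """
    if activity_profile.peptide.sequence != p.sequence:
        raise ValueError("activity profile is for a different peptide")
    for d in digests.values():
        if d.parent.sequence != p.sequence:
            raise ValueError("digest is for a different peptide")
    if record is not None and record.bare_sequence != p.sequence:
        raise ValueError("record is for a different peptide")

    flags: Dict[str, str] = {}

    frac = hydrophobic_fraction(p, criteria.residue_classes)
    flags["solubility"] = PASS if frac <= criteria.max_hydrophobic_fraction else FAIL

    predicted = set(activity_profile.per_activity) & criteria.require_predicted_activity
    flags["predicted_activity"] = PASS if predicted else FAIL

    if criteria.require_digestion_survival:
        survived = any(
            any(act in criteria.require_predicted_activity for act, _ in anns)
            for d in digests.values()
            for anns in d.annotations.values()
        ) if digests else False
        flags["digestion_survival"] = PASS if survived else FAIL

    if criteria.min_area is not None:
        if record is None or record.area is None:
            flags["abundance"] = ABSENT
        else:
            flags["abundance"] = PASS if record.area >= criteria.min_area else FAIL

    if criteria.require_cterm_rule:
        flags["cterm"] = PASS if cterm_rule(p, criteria.residue_classes) else FAIL

    flags["cysteine"] = (
        (PASS if "C" in p.sequence else FAIL)
        if criteria.require_cysteine
        else (PASS if "C" in p.sequence else ABSENT)
    )

    return CandidateReport(
        peptide=p,
        criterion_flags=flags,
        area=record.area if record is not None else None,
    )


def rank(reports: Sequence[CandidateReport]) -> List[CandidateReport]:
    """Order candidates: most criteria passed, then higher area, then sequence.

    The order is total and deterministic; ties on pass count break on relative
    abundance (absent area ranks below any observed area) and finally on the
    sequence string.
    """
    if not reports:
        raise ValueError("rank requires at least one report")
    return sorted(
        reports,
        key=lambda r: (-r.n_passed, -(r.area or 0.0), r.peptide.sequence),
    )


def reports_to_frame(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """Tabular (TSV-ready) export of the screen."""
    keys = sorted({k for r in reports for k in r.criterion_flags})
    rows = []
    for r in reports:
        row = {"peptide": str(r.peptide), "n_passed": r.n_passed,
               "overall_pass": r.overall_pass, "area": r.area}
        row.update({k: r.criterion_flags.get(k, ABSENT) for k in keys})
        rows.append(row)
    return pd.DataFrame(rows)
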