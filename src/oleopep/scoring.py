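"""Activity-profile scoring of peptides against a bioactive-fragment library.

Two standard metrics per activity class:

* **Parameter A** — the frequency of bioactive fragments: the number ``a`` of
  library fragments with the activity found in the sequence, divided by the
  residue count ``N``.
* **Parameter B** — the potential biological activity (µM⁻¹):
  ``Σᵢ 1/EC50ᵢ / N`` over the quantified fragments; fragments without a
  reported EC50 contribute to A but not to B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .motifs import MotifHit, MotifLibrary, scan
from .peptide import Peptide

__all__ = ["ActivityScore", "ActivityProfile", "parameter_A", "parameter_B", "profile"]


def parameter_A(a: int, n_residues: int) -> float:
    """Bioactive-fragment frequency a/N (compare printed tables at 4 d.p.)."""
    if n_residues < 1:
        raise ValueError("residue count must be >= 1")
    if a < 0:
        raise ValueError("fragment count must be >= 0")
    return a / n_residues


def parameter_B(ec50_list: Sequence[float], n_residues: int) -> float:
    """Potency density Σ(1/EC50)/N in µM⁻¹ over quantified fragments."""
    if n_residues < 1:
        raise ValueError("residue count must be >= 1")
    if any(e <= 0 for e in ec50_list):
        raise ValueError("EC50 values must be positive")
    return sum(1.0 / e for e in ec50_list) / n_residues


@dataclass(frozen=True)
class ActivityScore:
    """Per-class score: fragment count a, frequency A, optional potency B."""

    a: int
    A: float
    B: Optional[float]
    hits: Tuple[MotifHit, ...] = ()


@dataclass(frozen=True)
class ActivityProfile:
    peptide: Peptide
    per_activity: Dict[str, ActivityScore]

    def activities(self) -> List[str]:
        return sorted(self.per_activity)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (activity, count, A, B) in the reference layout."""
        rows = [
            {"activity": act, "count": s.a, "A": round(s.A, 4), "B": s.B}
            for act, s in sorted(self.per_activity.items())
        ]
        return pd.DataFrame(rows, columns=["activity", "count", "A", "B"])


def profile(
    p: Peptide, lib: MotifLibrary, counting: str = "distinct"
) -> ActivityProfile:
    """Scan the peptide and score every activity class found.

    ``counting`` sets what ``a`` counts: ``"distinct"`` (default) counts each
    (fragment, activity) pair once regardless of how often the fragment
    recurs; ``"occurrences"`` counts every positional occurrence.  EC50-bearing
    fragments enter B once per counted unit, consistently with the mode.
    """
    if counting not in ("distinct", "occurrences"):
        raise ValueError(f"unknown counting mode {counting!r}")
    hits = scan(p, lib)
    by_activity: Dict[str, List[MotifHit]] = {}
    for h in hits:
        by_activity.setdefault(h.record.activity, []).append(h)

    per_activity: Dict[str, ActivityScore] = {}
    n = len(p)
    for act, act_hits in by_activity.items():
        if counting == "distinct":
            units = {h.fragment: h.record for h in act_hits}
            a = len(units)
            ec50s = [r.ec50_uM for r in units.values() if r.ec50_uM is not None]
        else:
            a = len(act_hits)
            ec50s = [h.record.ec50_uM for h in act_hits if h.record.ec50_uM is not None]
        per_activity[act] = ActivityScore(
            a=a,
            A=parameter_A(a, n),
            B=parameter_B(ec50s, n) if ec50s else None,
            hits=tuple(act_hits),
        )
    return ActivityProfile(peptide=p, per_activity=per_activity)
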