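"""Peptide sequence model, modification notation and mass/charge arithmetic.

Sequences are the 20 canonical one-letter amino-acid codes.  Residue
modifications are written inline in the identification-report dialect, as a
signed mass delta in parentheses immediately after the modified residue, e.g.
``LLLGAGCM(+15.99)`` for a C-terminal oxidised methionine.  Masses are
monoisotopic throughout: the mass of a peptide is the sum of its residue masses
plus one water, plus any modification deltas.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "CANONICAL_RESIDUES",
    "RESIDUE_MONO_MASS",
    "WATER_MONO_MASS",
    "PROTON_MASS",
    "CANONICAL_DELTAS",
    "Peptide",
    "ResidueClassConfig",
    "PeptideParseError",
    "parse_sequence",
    "monoisotopic_mass",
    "theoretical_mz",
    "ppm_error",
    "hydrophobic_fraction",
    "cterm_rule",
    "residue_census",
    "read_fasta",
    "write_fasta",
]

#: Monoisotopic residue masses (Da) of the 20 canonical amino acids.
RESIDUE_MONO_MASS: Dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MONO_MASS)

WATER_MONO_MASS = 18.010565
PROTON_MASS = 1.007276

#: Nominal printed deltas -> exact monoisotopic deltas.  Reports print
#: two-decimal nominal values; mass computation substitutes the exact delta
#: by default (Met oxidation is the only modification seen in these data).
CANONICAL_DELTAS: Dict[float, float] = {15.99: 15.9949}

_MOD_RE = re.compile(r"\(([+−-]\d+(?:\.\d+)?)\)")


class PeptideParseError(ValueError):
    """Raised when a modification-annotated sequence string is malformed."""


@dataclass(frozen=True)
class Peptide:
    """An amino-acid sequence with optional per-residue mass deltas.

    ``modifications`` maps 0-based residue index to the nominal delta (Da) as
    printed in the report.
    """

    sequence: str
    modifications: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("peptide must contain at least one residue")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue(s): {sorted(bad)}")
        for idx in self.modifications:
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"modification index {idx} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        out = []
        for i, res in enumerate(self.sequence):
            out.append(res)
            if i in self.modifications:
                out.append(f"({self.modifications[i]:+.2f})")
        return "".join(out)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def parse_sequence(text: str) -> Peptide:
    """Parse a modification-annotated sequence string into a :class:`Peptide`.

    Parenthesised deltas of the form ``(+15.99)`` / ``(-0.98)`` attach to the
    immediately preceding residue.  Formatting the result with ``str()``
    round-trips the input.

    Raises
    ------
    PeptideParseError
        On an unknown residue letter (the error names its position) or a
        dangling modification with no preceding residue.
    """
    if not text:
        raise PeptideParseError("empty sequence string")
    residues: list[str] = []
    mods: Dict[int, float] = {}
    pos = 0
    prev_was_mod = False
    while pos < len(text):
        m = _MOD_RE.match(text, pos)
        if m:
            if not residues or prev_was_mod:
                raise PeptideParseError(
                    f"modification at position {pos} has no preceding residue"
                )
            mods[len(residues) - 1] = float(m.group(1).replace("−", "-"))
            prev_was_mod = True
            pos = m.end()
            continue
        ch = text[pos]
        if ch not in CANONICAL_RESIDUES:
            raise PeptideParseError(
                f"unknown residue {ch!r} at position {pos}"
            )
        residues.append(ch)
        prev_was_mod = False
        pos += 1
    return Peptide("".join(residues), mods)


def monoisotopic_mass(p: Peptide, canonical_modifications: bool = True) -> float:
    """Monoisotopic peptide mass in Da.

    Sum of residue masses + one water + modification deltas.  With
    ``canonical_modifications`` (default) nominal printed deltas listed in
    :data:`CANONICAL_DELTAS` are replaced by their exact values, e.g. the
    printed ``+15.99`` of oxidised Met by +15.9949.
    """
    mass = WATER_MONO_MASS + sum(RESIDUE_MONO_MASS[r] for r in p.sequence)
    for delta in p.modifications.values():
        if canonical_modifications:
            delta = CANONICAL_DELTAS.get(round(abs(delta), 2), abs(delta)) * (
                1 if delta >= 0 else -1
            )
        mass += delta
    return mass


def theoretical_mz(p: Peptide, z: int, **mass_kwargs) -> float:
    """Theoretical m/z (Th) at charge state ``z`` (protonated species)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (monoisotopic_mass(p, **mass_kwargs) + z * PROTON_MASS) / z


def ppm_error(observed_mz: float, p: Peptide, z: int, **mass_kwargs) -> float:
    """Signed precursor mass error in ppm on the m/z scale."""
    if observed_mz <= 0:
        raise ValueError("observed m/z must be positive")
    theo = theoretical_mz(p, z, **mass_kwargs)
    return (observed_mz - theo) / theo * 1e6


@dataclass(frozen=True)
class ResidueClassConfig:
    """Residue classes used by the physicochemical descriptors.

    Defaults: hydrophobic {A,V,L,I,P,F,M,W}; basic {K,R,H}; the
    antioxidant-prone set collects residues commonly implicated in radical
    scavenging and metal chelation (Cys thiol, Met thioether, His imidazole,
    aromatic Trp/Tyr, Lys).
    """

    hydrophobic_set: frozenset = frozenset("AVLIPFMW")
    basic_set: frozenset = frozenset("KRH")
    antioxidant_prone_set: frozenset = frozenset("CMHWYK")

    def __post_init__(self) -> None:
        for name in ("hydrophobic_set", "basic_set", "antioxidant_prone_set"):
            s = getattr(self, name)
            object.__setattr__(self, name, frozenset(s))
            bad = frozenset(s) - CANONICAL_RESIDUES
            if bad:
                raise ValueError(f"{name} has non-canonical residues {sorted(bad)}")
        if self.hydrophobic_set & self.basic_set:
            raise ValueError("hydrophobic_set and basic_set must be disjoint")


DEFAULT_CLASSES = ResidueClassConfig()


def hydrophobic_fraction(p: Peptide, cfg: ResidueClassConfig = DEFAULT_CLASSES) -> float:
    """Fraction of residues in the hydrophobic set (water-solubility proxy)."""
    return sum(r in cfg.hydrophobic_set for r in p.sequence) / len(p)


def cterm_rule(
    p: Peptide, cfg: ResidueClassConfig = DEFAULT_CLASSES, window: int = 3
) -> bool:
    """True iff a hydrophobic or basic residue lies within the C-terminal window.

    ACE-inhibitory peptides typically carry hydrophobic and/or basic residues
    among their last three positions; ``window`` defaults to 3.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tail = p.sequence[-min(window, len(p)):]
    allowed = cfg.hydrophobic_set | cfg.basic_set
    return any(r in allowed for r in tail)


def residue_census(p: Peptide) -> Dict[str, int]:
    """Per-residue counts (sums to N)."""
    return dict(Counter(p.sequence))


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> Dict[str, Peptide]:
    """Read plain peptide sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: Peptide(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(peptides: Iterable[Tuple[str, Peptide]], path) -> None:
    """Write peptides to FASTA, flattened to bare sequences.

    Modified peptides carry their inline notation in the description so no
    information is silently lost.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for name, p in peptides:
        desc = f"modified={p}" if p.modifications else ""
        records.append(SeqRecord(Seq(p.sequence), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")
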