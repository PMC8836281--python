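"""Declarative protease-specificity engine for simulated gastrointestinal digestion.

A cleavage rule names the residues after which the backbone is cut (the P1
set) and the residues that block cleavage when they immediately follow the
site (P1′ exclusions, classically proline).  The bundled profiles model the
main digestive enzymes as applied to short endogenous peptides:

* ``pepsin`` (pH 1.3-like specificity): cuts after F or L, no P1′ block;
* ``trypsin``: cuts after K or R, blocked before P;
* ``chymotrypsin``: cuts after F, L, M, N, W or Y, blocked before P
  (a broad, low-specificity profile that includes Asn).

Fragments that exactly match a bioactive-library fragment can be annotated,
answering whether a peptide's activity would survive digestion in the gut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .motifs import MotifLibrary, MotifRecord
from .peptide import CANONICAL_RESIDUES, Peptide

__all__ = [
    "EnzymeRule",
    "DigestResult",
    "PEPSIN",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "DEFAULT_RULES",
    "cleave",
    "digest_multi",
    "annotate_fragments",
    "rules_from_yaml",
    "rules_to_yaml",
]


@dataclass(frozen=True)
class EnzymeRule:
    """A cleavage specificity: cut after any P1 residue unless P1′ blocks."""

    name: str
    p1_set: frozenset
    p1prime_block: frozenset = frozenset("P")

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1_set", frozenset(self.p1_set))
        object.__setattr__(self, "p1prime_block", frozenset(self.p1prime_block))
        if not self.p1_set:
            raise ValueError("p1_set must be non-empty")
        bad = (self.p1_set | self.p1prime_block) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residues in rule: {sorted(bad)}")

    def cuts_after(self, seq: str, i: int) -> bool:
        """Whether the bond after 0-based residue ``i`` is cleaved."""
        return (
            i + 1 < len(seq)
            and seq[i] in self.p1_set
            and seq[i + 1] not in self.p1prime_block
        )


PEPSIN = EnzymeRule("pepsin", frozenset("FL"), frozenset())
TRYPSIN = EnzymeRule("trypsin", frozenset("KR"))
CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("FLMNWY"))

DEFAULT_RULES: Tuple[EnzymeRule, ...] = (PEPSIN, TRYPSIN, CHYMOTRYPSIN)


@dataclass(frozen=True)
class DigestResult:
    """Ordered fragments of a parent peptide under one (or more) rules.

    ``cut_sites`` are 0-based inter-residue indices: a cut at ``i`` separates
    residues ``i`` and ``i+1``.  Fragments always concatenate back to the
    parent's bare sequence.
    """

    parent: Peptide
    enzyme: str
    fragments: Tuple[str, ...]
    cut_sites: Tuple[int, ...]
    annotations: Mapping[str, Tuple[Tuple[str, MotifRecord], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if "".join(self.fragments) != self.parent.sequence:
            raise ValueError("fragments do not reassemble the parent sequence")
        if len(self.fragments) != len(self.cut_sites) + 1:
            raise ValueError("fragment/cut-site count mismatch")

    def __str__(self) -> str:
        """Hyphen-joined fragment notation, e.g. ``CPAN-GF-Y``."""
        return "-".join(self.fragments)

    @property
    def active_fragments(self) -> Tuple[str, ...]:
        return tuple(f for f in self.fragments if self.annotations.get(f))


def cleave(p: Peptide, rule: EnzymeRule) -> DigestResult:
    """Digest a peptide with a single rule (complete, deterministic digestion)."""
    seq = p.sequence
    cut_sites = tuple(i for i in range(len(seq)) if rule.cuts_after(seq, i))
    fragments: List[str] = []
    start = 0
    for site in cut_sites:
        fragments.append(seq[start:site + 1])
        start = site + 1
    fragments.append(seq[start:])
    return DigestResult(parent=p, enzyme=rule.name, fragments=tuple(fragments),
                        cut_sites=cut_sites)


def digest_multi(
    p: Peptide,
    rules: Sequence[EnzymeRule] = DEFAULT_RULES,
    mode: str = "independent",
) -> Dict[str, DigestResult]:
    """Digest with several enzymes.

    ``independent`` (default) digests the intact parent with each rule, one
    result per enzyme — the per-enzyme presentation of a digestion table.
    ``sequential`` feeds the fragments of each rule into the next, returning
    a single entry keyed by the joined rule names.
    """
    if not rules:
        raise ValueError("at least one rule required")
    if mode == "independent":
        return {rule.name: cleave(p, rule) for rule in rules}
    if mode != "sequential":
        raise ValueError(f"unknown mode {mode!r}")
    fragments = [p.sequence]
    all_sites: List[int] = []
    for rule in rules:
        nxt: List[str] = []
        for frag in fragments:
            nxt.extend(cleave(Peptide(frag), rule).fragments)
        fragments = nxt
    # recover cut sites from fragment boundaries
    pos = 0
    for frag in fragments[:-1]:
        pos += len(frag)
        all_sites.append(pos - 1)
    name = "+".join(r.name for r in rules)
    return {
        name: DigestResult(
            parent=p, enzyme=name, fragments=tuple(fragments),
            cut_sites=tuple(all_sites),
        )
    }


def annotate_fragments(d: DigestResult, lib: MotifLibrary) -> DigestResult:
    """Attach activity annotations to fragments that are themselves library entries.

    Whole-fragment matching only: a fragment is annotated iff it equals a
    library fragment, not when it merely contains one.
    """
    annotations: Dict[str, Tuple[Tuple[str, MotifRecord], ...]] = {}
    for frag in set(d.fragments):
        recs = lib.index.get(frag, ())
        if recs:
            annotations[frag] = tuple((r.activity, r) for r in recs)
    return replace(d, annotations=annotations)


# -- editable enzyme profiles ----------------------------------------------

def rules_from_yaml(path) -> List[EnzymeRule]:
    """Load enzyme profiles from YAML: list of {name, p1_set, p1prime_block}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        EnzymeRule(
            name=entry["name"],
            p1_set=frozenset(entry["p1_set"]),
            p1prime_block=frozenset(entry.get("p1prime_block", "P")),
        )
        for entry in raw
    ]


def rules_to_yaml(rules: Sequence[EnzymeRule], path) -> None:
    payload = [
        {
            "name": r.name,
            "p1_set": sorted(r.p1_set),
            "p1prime_block": sorted(r.p1prime_block),
        }
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)
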