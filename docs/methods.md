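# Methods

`oleopep` implements the desk half of an endogenous-peptidomics screen for
bioactive food peptides: from mass-spectrometry identification reports of a
virgin-olive-oil (VOO) water-soluble extract to a ranked shortlist of
candidates for synthesis, plus the calculators used to quantify activity at
the bench.  This note records the models, parameter choices and numerical
conventions, and what the bundled synthetic data can and cannot show.

## Sequence model and mass arithmetic

Peptides are sequences of the 20 canonical one-letter codes with optional
per-residue mass deltas written inline, e.g. `LLLGAGCM(+15.99)` for a
C-terminal oxidised methionine.  The monoisotopic mass is the sum of the
standard monoisotopic residue masses (G 57.02146 … W 186.07931 Da), one
water (18.010565 Da) and the modification deltas.  Report dialects print
deltas to two decimals; by default the nominal `+15.99` is replaced by the
exact Met-oxidation delta `+15.9949` when computing mass (`+15.99` verbatim
is available via `canonical_modifications=False`).  The exact delta is
required to reproduce the reported mass of the oxidised peptide to < 2 mDa;
with it, all 27 bundled reference masses agree with the printed values
within 0.002 Da.  m/z at charge z is `(M + z·1.007276)/z`; ppm error is
signed and defined on the m/z scale.  Printed ppm columns of the reference
report are *not* reproducible from the printed m/z and mass columns (the
engine's internal reference point is unknown); the package implements the
standard definition and makes no attempt to match that column.

## Report filtering

Database-search rows carry a −10·log10(p) match score; the acceptance
threshold of 30 corresponds to p = 0.001 (20 ↔ 0.01).  De novo rows carry
per-residue local-confidence percentages whose mean is the ALC; the
threshold is 90 %.  Further rules: charge ≥ +2 (singly charged precursors
are instrument-rejected) and presence in ≥ 2 distinct samples.  Sample
replication is keyed on the modification-stripped sequence, so oxidised and
unmodified forms pool their evidence (configurable).

ALC rounding: the integer ALC printed by report software is not consistently
reproducible from the printed per-residue scores — truncation matches 7 of
the 8 bundled rows, nearest-integer only 5, and no rule matches all 8,
implying the per-residue scores are themselves display-rounded.
`compute_alc` therefore returns the unrounded mean plus an integer rendering,
defaulting to truncation with `half_up` available.

Protein roll-up: protein abundance is the plain sum of supporting-peptide
areas with "ND" (not detected) counted as zero — the only convention under
which the bundled per-protein areas reproduce.  The protein score defaults
to the plain sum of supporting-peptide scores behind a pluggable aggregator;
published protein scores hint at an undocumented weighting and are not
matched.  Coverage needs peptide→protein positions, which the unannotated
source database does not provide; it is computed only when the caller
supplies them.

## Motif scanning and activity scoring

The motif library maps short fragments (1–10 residues) to activity classes
(ACE/DPP-III/DPP-IV/renin inhibition, antioxidant, opioid, free-form
`other:` labels) with optional EC50 in µM.  Scanning enumerates every
contiguous-substring occurrence; an independent brute-force oracle checks
equivalence in the tests.  The bundled default library holds 22 records,
every one traceable to published in-vitro values for these fragments
(e.g. VY 7.1, SVY 8.1, KA 31.5, FL 15.8, IPP 5, VPP 9 µM for ACE; FY is
stored at the midpoint of its published 1.65–42.6 µM range).  It is a
deliberately small, fully sourced subset: screening against a complete
reference dictionary (thousands of records) requires loading that export
with `load_library`.

Parameter A is a/N — known-active fragments per residue; parameter B is
Σ(1/EC50)/N in µM⁻¹ over quantified fragments.  The counting mode for `a`
defaults to distinct (fragment, activity) pairs, with per-occurrence
counting exposed, since published tables report only final counts.
Published A values can only be reproduced from the published counts, not
re-derived from the bundled subset; the bundled activity table carries a
`consistent` flag because a handful of printed A values contradict their own
(count, N) pair (swapped or misaligned columns) — those rows are kept
verbatim but excluded from exact-reproduction checks.

## Simulated gastrointestinal digestion

Cleavage rules are declarative: a P1 set (cut after these residues) and a
P1′ block set (no cut when the next residue is in it).  Bundled profiles,
chosen as the minimal rule sets consistent with the published per-enzyme
fragments of these peptides:

| profile        | P1              | P1′ block |
|----------------|-----------------|-----------|
| `pepsin`       | F, L            | —         |
| `trypsin`      | K, R            | P         |
| `chymotrypsin` | F, L, M, N, W, Y | P        |

The pepsin profile reflects the strong pH-1.3 preference for Phe/Leu; the
chymotrypsin-like profile is broad (including Asn) because that is the only
set reproducing the published fragments; W is included by analogy and is
untested by the reference data.  Profiles are data (YAML-editable), not
code.  Digestion is complete and deterministic — every eligible bond is cut;
no missed-cleavage enumeration or kinetics.  Multi-enzyme digestion defaults
to independent per-enzyme digestion (matching per-enzyme report columns);
sequential mode pipes fragments through the rules in order.  Fragment
annotation is whole-fragment matching only: a fragment keeps an activity iff
it *is* a library fragment, because survival of the intact active unit is
what matters after digestion.

## Candidate selection

Criteria, each an independent pass/fail/absent flag: hydrophobic fraction
≤ 0.85 as a solubility proxy (sequences above ~85 % hydrophobic residues
proved insoluble at the bench; the cut is configurable because the published
choice was qualitative); predicted ACE-inhibitory or antioxidant activity;
survival of ≥ 1 annotated active fragment under some enzyme; relative
abundance (disabled by default — no published threshold exists); a
hydrophobic or basic residue within the last three positions (the classical
C-terminal signature of ACE-inhibitory peptides); and cysteine content
(scored but not required by default — thiol-bearing peptides are
antioxidant-prone, but cysteine-free actives exist).  Missing data yields
`absent`, which does not block the overall verdict.  Ranking is by criteria
passed, then area, then sequence — total and deterministic.  The screen
deliberately exposes flags rather than a single hard verdict: the original
shortlist involved expert judgement that a rule set cannot (and should not
pretend to) reproduce.

## Assay calculators

ACE inhibition from fluorescence readings:
`%inh = ((FC−FB) − (FS−FBs)) / (FC−FB) × 100`, with FC the no-inhibitor
control, FB the substrate blank, FS the sample and FBs the sample blank.
Values outside [0, 100] are reported as-is with a flag, never clipped.
Replicates are averaged per concentration before curve analysis.  IC50
defaults to linear interpolation of % inhibition against log10
concentration between the bracketing pair — assumption-free and exactly
reproducible; a four-parameter logistic least-squares fit
(`bottom + (top−bottom)/(1+(IC50/c)^h)`, bounded curve_fit, geometric-mean
initialisation) is available as `method="4pl"`.  When no pair brackets
50 %, estimation fails loudly with the observed range.

TEAC is the slope ratio: least-squares response-vs-concentration slopes of
sample and Trolox calibration (0–1 mM).  Sample responses mapping outside
the calibration range trigger an extrapolation warning; a single-point mode
exists for one-concentration data.  TEAC is invariant to rescaling both
response axes by a common factor.

## Synthetic data: what it emulates, and what it does not

The report generator emulates the *statistical shape* of the reference
tables: observed mass = theoretical × (1 + ε) with ε ~ N(0, 5 ppm) (printed
|ppm| spans 0.5–9.6); z ∈ {2, 3}; per-residue confidences from
100·Beta(60, 4) (ALC ≈ 90–97); areas log-normal(µ=13, σ=1.5) (~1e4–1e7);
retention times uniform over the observed window.  True rows are
constructed to pass every default filter (scores drawn above threshold;
rare sub-threshold ALC draws are deterministically redrawn from the seeded
stream), and each decoy violates exactly one rule — sub-threshold score,
charge +1, or single-sample presence — so filter recall and decoy rejection
are exactly 100 %/100 % by construction and any deviation is a bug, not
noise.  Plates are generated from a 4PL curve with known IC50 and Hill
slope, converted to fluorescence consistent with the inhibition formula,
with multiplicative noise (default CV 2 %, 3 replicates, 7 concentrations
spanning ±1 decade around the true IC50).  ABTS runs use a Trolox slope of
0.7 response/mM and a known slope ratio (default 3.20).

What passing these tests does *not* show: the generators contain no
co-elution, no charge-state misassignment, no correlated per-residue
confidence errors, no plate drift or edge effects, and no real biological
variation in abundance.  Recovery of IC50 within 10 % over 100 seeds at 2 %
noise demonstrates the estimator's correctness at realistic assay noise, not
the wet-lab values themselves — measured IC50/TEAC of the synthesised
peptides are instrument results the desk pipeline can only carry as
reference fixtures.  Likewise the 19 + 8 identification counts are a
property of the instrument runs, not recomputable.

All generators take an explicit integer seed (NumPy `default_rng`); there is
no global random state, and fixed seeds give byte-identical report files.

## Problem sizes

Property suites run digestion reassembly/idempotence on 1,000 random
peptides (lengths 1–29), motif-scan oracle equivalence on 200, IC50 recovery
over 100 seeded plates and ppm calibration on ~1,000 simulated rows — sizes
at which every invariant is exercised across the rule and length space while
the whole suite stays interactive.

## Known limitations

* Digestion is all-or-nothing: no partial cleavage, missed-cleavage
  enumeration or pH-dependent switching beyond the named profiles.
* The bundled motif library is a sourced subset; absolute fragment counts
  (and hence A) against a full reference dictionary will be higher.
* Isotope envelopes, average masses and terminal (non-residue) chemical
  modifications are out of scope.
* Protein scores use an unweighted sum; published weighted scores are not
  reproducible without the (undocumented) weights.
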