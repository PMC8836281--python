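"""Scan a peptide against the bioactive-fragment library and score it.

Parameter A is the count of known bioactive fragments divided by the residue
count N; parameter B sums the reciprocal EC50s (µM^-1) of the quantified
fragments, again per residue.  Higher values mean a denser packing of known
active motifs.
"""

from oleopep import default_library, parse_sequence, profile

lib = default_library()
for seq in ("CCYSVY", "CPANGFY", "DCHYFL"):
    p = parse_sequence(seq)
    prof = profile(p, lib)
    print(f"{seq} (N={len(p)}):")
    for activity, score in sorted(prof.per_activity.items()):
        frags = ",".join(sorted({h.fragment for h in score.hits}))
        b = f"{score.B:.4g} uM^-1" if score.B is not None else "n/a"
        print(f"  {activity:18s} a={score.a}  A={score.A:.4f}  B={b}  [{frags}]")
    print()
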