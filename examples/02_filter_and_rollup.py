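"""Filter a simulated identification report and roll peptides up to proteins.

Generates a ground-truthed synthetic report (true rows built to pass the
screen, decoys each violating exactly one rule), applies the default policy
(score threshold, charge >= +2, >= 2 samples) and aggregates label-free areas
per protein.
"""

from oleopep import FilterPolicy, apply_filters, rollup_proteins
from oleopep.simulate import ReportSimConfig, simulate_report

cfg = ReportSimConfig(
    true_peptides=("CCYSVY", "CPANGFY", "VCGEAFGKA", "NALLCSNS", "DCHYFL"),
    n_samples=2,
    decoy_fraction=0.4,
    seed=42,
)
records, manifest = simulate_report(cfg)
kept = apply_filters(records, FilterPolicy())

n_true = len(manifest["must_survive"])
n_decoy = len(manifest["decoy_rows"])
print(f"simulated rows: {len(records)} ({n_true} true, {n_decoy} decoy)")
print(f"retained after filtering: {len(kept)} "
      f"(recall {sum(r in kept for r in (records[i] for i in manifest['must_survive'])) / n_true:.0%}, "
      f"decoys retained: {sum(records[int(i)] in kept for i in manifest['decoy_rows'])})")

print("\nprotein roll-up (areas are sums over supporting peptides):")
for rollup in rollup_proteins(kept):
    print(f"  {rollup.accession}: {rollup.n_supporting} peptides, "
          f"total area {rollup.total_area:.3g}, score {rollup.protein_neg10lgP:.1f}")
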