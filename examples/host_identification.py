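"""In-silico host identification from cytochrome-b amplicons.

Builds the synthetic reference panel (12 host species carrying both
published primer pairs' binding sites), extracts the ~244 bp and ~358 bp
amplicons, mutates queries at a 2 % substitution rate and runs the
two-tier best-identity assignment.
"""

from bloodmeal.hostid import KITANO_PAIR, KOCHER_PAIR, ReferencePanel, extract_amplicon, two_tier_identify
from bloodmeal.synth import generate_amplicons, synthetic_reference_panel

refs = synthetic_reference_panel()
tier1 = ReferencePanel(tuple((n, extract_amplicon(s, KITANO_PAIR)) for n, s in refs.entries))
tier2 = ReferencePanel(tuple((n, extract_amplicon(s, KOCHER_PAIR)) for n, s in refs.entries))
print(f"panel: {len(refs)} species; amplicons "
      f"{len(tier1.entries[0][1])} bp (tier 1) / {len(tier2.entries[0][1])} bp (tier 2)")

queries = generate_amplicons(tier1, per_taxon=5, substitution_rate=0.02, seed=11)
calls = two_tier_identify(
    [(q, s) for q, s, _ in queries], [("tier1", tier1), ("tier2", tier2)]
)

correct = sum(c.best_taxon == truth for c, (_, _, truth) in zip(calls, queries))
assigned = sum(c.status == "assigned" for c in calls)
print(f"{assigned}/{len(calls)} assigned, {correct}/{len(calls)} to the true species")
for c in calls[:3]:
    print(f"  {c.query_id}: {c.best_taxon}  identity={c.identity:.3f} "
          f"margin={c.margin:.3f} [{c.status}, {c.tier}]")

# At 2 % divergence from its reference, a query keeps ~98 % identity to the
# true species but only ~30 % to the others, so assignments are essentially
# always correct and resolved at tier 1.
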