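"""Host-feeding-based transmission-risk ranking.

Combines each taxon's blood-meal fractions (Fa avian, Fh human, Fm
non-human mammal) with its relative abundance Ap into the two risk
products Ap*Fa*Fh (birds -> humans) and Ap*Fm*Fh (mammals -> humans).
Here Ap is taken from the survey's own specimen shares, with the pooled
Culex pipiens-complex share assigned to both of its members.
"""

from bloodmeal import feeding_fractions, rank_species, transmission_risk
from bloodmeal import tables
from bloodmeal.records import tabulate_species_summary

survey = tables.reconstruct_survey()
shares = tabulate_species_summary(survey).set_index("mosquito_taxon")["pct_all_specimens"] / 100

pooled_culex = float(
    shares["Culex pipiens pipiens form pipiens"]
    + shares["Culex pipiens (s.l.)/torrentium"]
    + shares["Culex torrentium"]
)
abundance = {t: float(shares[t]) for t in tables.named_species()}
abundance["Culex pipiens pipiens form pipiens"] = pooled_culex
abundance["Culex torrentium"] = pooled_culex

estimates = [
    transmission_risk(feeding_fractions(survey, t), ap) for t, ap in abundance.items()
]
birds, mammals = rank_species(estimates)

print("Birds -> humans channel (top 3):")
for e in birds[:3]:
    print(f"  {e.taxon:38s} Ap*Fa*Fh = {e.risk_bird_to_human:.5f}")
print("Non-human mammals -> humans channel (top 3):")
for e in mammals[:3]:
    print(f"  {e.taxon:38s} Ap*Fm*Fh = {e.risk_mammal_to_human:.5f}")

# The Culex pipiens-complex members dominate the bird-to-human channel
# (they feed on both birds and people); the abundant floodwater mosquito
# Aedes vexans dominates the mammal-to-human channel.
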