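"""Host-feeding-group clustering.

Reduces every mosquito taxon to a binary bird/mammal/human feeding profile,
clusters the profiles with Jaccard dissimilarity under UPGMA, and lists the
zero-height groups: sets of taxa feeding on exactly the same combination of
host groups.
"""

from bloodmeal.clustering import extract_feeding_groups, group_profiles, upgma
from bloodmeal import tables

survey = tables.reconstruct_survey()
profiles = group_profiles(survey)
tree = upgma(profiles)
groups = extract_feeding_groups(tree, profiles)

print(f"{len(profiles)} taxa fall into {len(groups)} feeding groups:\n")
for label, taxa in sorted(groups.items(), key=lambda kv: -len(kv[1])):
    print(f"  {label} ({len(taxa)} taxa)")
    for t in taxa:
        print(f"    - {t}")

print("\nDendrogram (Newick):")
print(tree.to_newick())

# Taxa merging at height zero share an identical host-group combination.
# The two large groups -- "non-human mammals and humans" and "birds,
# non-human mammals and humans" -- separate plain mammal-feeders from
# potential bridge vectors that also bite birds.
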