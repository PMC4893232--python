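"""Host-feeding-group identification.

Each mosquito taxon is reduced to a binary profile over the three host
groups (bird, non-human mammal, human): a bit is set iff at least one blood
meal from that group was recorded. Taxa are clustered by Jaccard
dissimilarity under average-linkage (UPGMA) agglomeration; taxa merging at
height zero share an identical host-group combination and form one
*feeding group* (e.g. "non-human mammals and humans").

Ties between equally close cluster pairs are broken by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest leaf
name), which makes the dendrogram fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyDatasetError
from .records import HOST_GROUPS, SurveyDataset

#: display names for host-group combinations, in canonical group order
_GROUP_WORDS = {"bird": "birds", "non-human mammal": "non-human mammals", "human": "humans"}


@dataclass(frozen=True)
class GroupProfile:
    """Binary host-group presence triple for one mosquito taxon."""

    taxon: str
    bits: tuple[int, int, int]  # (bird, non-human mammal, human)
    aggregate: bool = False

    def __post_init__(self) -> None:
        if len(self.bits) != 3 or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be a binary triple")

    def combination_label(self) -> str:
        present = [
            _GROUP_WORDS[g] for g, b in zip(HOST_GROUPS, self.bits) if b
        ]
        if not present:
            return "none"
        if len(present) == 1:
            return present[0]
        return ", ".join(present[:-1]) + " and " + present[-1]


@dataclass(frozen=True)
class DendrogramNode:
    """A node of the merge tree: a leaf (taxon) or a merge of two children."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    def leaves(self) -> tuple[str, ...]:
        if self.children is None:
            return (self.label,)
        return self.children[0].leaves() + self.children[1].leaves()

    def _newick(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.children is None:
            name = self.label.replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")
            return f"{name}:{length:g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{length:g}"


@dataclass(frozen=True)
class Dendrogram:
    root: DendrogramNode

    def leaves(self) -> tuple[str, ...]:
        return self.root.leaves()

    def merge_heights(self) -> tuple[float, ...]:
        heights: list[float] = []

        def walk(node: DendrogramNode) -> None:
            if node.children is not None:
                heights.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return tuple(sorted(heights))

    def to_newick(self) -> str:
        inner = ",".join(c._newick(self.root.height) for c in self.root.children) \
            if self.root.children else self.root._newick(self.root.height)
        return f"({inner});" if self.root.children else f"{inner};"


def group_profiles(dataset: SurveyDataset, flag_aggregates: tuple[str, ...] = ()) -> list[GroupProfile]:
    """One binary host-group profile per mosquito taxon in the dataset."""
    ds = dataset.identified()
    if not ds.records:
        raise EmptyDatasetError("no identified records")
    seen: dict[str, set[str]] = {}
    for r in ds:
        seen.setdefault(r.mosquito_taxon, set()).add(r.host_group)
    return [
        GroupProfile(
            taxon=t,
            bits=tuple(int(g in groups) for g in HOST_GROUPS),
            aggregate=t in flag_aggregates,
        )
        for t, groups in sorted(seen.items())
    ]


def profiles_from_counts(counts: dict[str, tuple[int, int, int]]) -> list[GroupProfile]:
    """Profiles from per-taxon (bird, mammal, human) count triples."""
    return [
        GroupProfile(taxon=t, bits=tuple(int(c > 0) for c in triple))
        for t, triple in sorted(counts.items())
    ]


def jaccard_dissimilarity(a: GroupProfile, b: GroupProfile) -> float:
    """1 - |intersection| / |union| over the set bits of two profiles."""
    if sum(a.bits) == 0 or sum(b.bits) == 0:
        raise ValueError("profiles must have at least one host group present")
    inter = sum(x & y for x, y in zip(a.bits, b.bits))
    union = sum(x | y for x, y in zip(a.bits, b.bits))
    return 1.0 - inter / union


def upgma(profiles: list[GroupProfile]) -> Dendrogram:
    """Average-linkage agglomerative clustering of host-group profiles.

    Merge heights are the unweighted mean of all inter-cluster pairwise
    Jaccard dissimilarities; heights are non-decreasing because Jaccard on
    binary triples is a metric.
    """
    if len(profiles) < 2:
        raise ValueError("upgma needs at least 2 profiles")
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            dist[(i, j)] = jaccard_dissimilarity(profiles[i], profiles[j])
    return upgma_from_distances([p.taxon for p in profiles], dist)


def upgma_from_distances(
    labels: list[str], dist: dict[tuple[int, int], float]
) -> Dendrogram:
    """UPGMA over an explicit pairwise dissimilarity matrix.

    ``dist`` maps index pairs (i, j) with i < j into dissimilarities over
    ``labels``. Ties between equally close cluster pairs merge the pair with
    the lexicographically smallest labels.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 items")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    # cluster state: label (= smallest leaf name), member leaf indices, node
    clusters: list[tuple[str, list[int], DendrogramNode]] = [
        (lab, [i], DendrogramNode(height=0.0, label=lab))
        for i, lab in enumerate(labels)
    ]

    def d(members_a: list[int], members_b: list[int]) -> float:
        total = 0.0
        for i in members_a:
            for j in members_b:
                total += dist[(i, j)] if i < j else dist[(j, i)]
        return total / (len(members_a) * len(members_b))

    while len(clusters) > 1:
        best = None
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                la, ma, _ = clusters[ia]
                lb, mb, _ = clusters[ib]
                key = (d(ma, mb), *sorted((la, lb)))
                if best is None or key < best[0]:
                    best = (key, ia, ib)
        (height, *_), ia, ib = best
        la, ma, na = clusters[ia]
        lb, mb, nb = clusters[ib]
        merged = DendrogramNode(height=height, children=(na, nb) if la < lb else (nb, na))
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append((min(la, lb), ma + mb, merged))
    return Dendrogram(root=clusters[0][2])


def extract_feeding_groups(
    dendrogram: Dendrogram, profiles: list[GroupProfile]
) -> dict[str, tuple[str, ...]]:
    """Feeding groups: taxa sharing one identical host-group combination.

    These are exactly the dendrogram's zero-height clusters (Jaccard
    dissimilarity is zero iff the binary profiles coincide). Returned as
    {combination label: (taxa...)}; together the groups partition the taxa.
    """
    leafset = set(dendrogram.leaves())
    byprofile: dict[tuple[int, int, int], list[str]] = {}
    for p in profiles:
        if p.taxon not in leafset:
            raise ValueError(f"profile taxon {p.taxon!r} absent from dendrogram")
        byprofile.setdefault(p.bits, []).append(p.taxon)
    labels = {bits: GroupProfile("_", bits).combination_label() for bits in byprofile}
    return {labels[bits]: tuple(sorted(taxa)) for bits, taxa in byprofile.items()}
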