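"""Synthetic blood-meal surveys, co-occurrence scenarios and amplicon sets.

The survey generator emulates the sampling design the analyses assume: a
multi-site, multi-season survey in which each engorged specimen gets a
mosquito taxon (by relative abundance), a trapping site, a month, a trap
method, and a host species drawn from the elementwise product of the
taxon's host preference, the site's host availability and the trap's
host-group capture bias, renormalized. Setting preferences uniform isolates
availability-driven feeding patterns; trap bias defaults to 1 (no bias).
Every generator is a pure function of its configuration including the seed.

``generate_feeding_scenario`` builds presence-absence matrices with known
ground truth for calibrating the null model: *aggregated* (all hosts share
one universal column plus sparse noise), *segregated* (hosts occupy pairwise
disjoint column blocks) and *random* (uniform placement with fixed row
sums — exactly the null hypothesis).

``synthetic_reference_panel`` builds cytochrome-b-like references for twelve
host species (six mammals including humans, six birds) carrying both
published primer pairs' binding sites, with inter-species divergence of at
least 10 % so best-identity assignment is well separated.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .cooccurrence import PresenceAbsenceMatrix
from .errors import ConfigError
from .hostid import KITANO_PAIR, KOCHER_PAIR, ReferencePanel, reverse_complement
from .records import BloodMealRecord, SurveyDataset

SYNTHETIC_BIRDS = (
    "Turdus merula",
    "Turdus philomelos",
    "Passer domesticus",
    "Sylvia atricapilla",
    "Cyanistes caeruleus",
    "Erithacus rubecula",
)
SYNTHETIC_MAMMALS = (
    "Homo sapiens",
    "Capreolus capreolus",
    "Bos taurus",
    "Sus scrofa",
    "Ovis aries",
    "Lepus europaeus",
)
SYNTHETIC_HOSTS = SYNTHETIC_BIRDS + SYNTHETIC_MAMMALS

SYNTHETIC_HOST_GROUPS = {
    **{h: "bird" for h in SYNTHETIC_BIRDS},
    "Homo sapiens": "human",
    **{h: "non-human mammal" for h in SYNTHETIC_MAMMALS if h != "Homo sapiens"},
}


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    land_use: str
    availability: dict[str, float]  # host species -> weight
    weight: float = 1.0


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    abundance: float  # relative abundance weight
    preference: dict[str, float]  # host species -> weight


@dataclass(frozen=True)
class TrapSpec:
    name: str
    bias: dict[str, float] = field(default_factory=dict)  # host group -> factor
    weight: float = 1.0


@dataclass(frozen=True)
class SurveyConfig:
    seed: int
    n: int
    sites: tuple[SiteSpec, ...]
    taxa: tuple[TaxonSpec, ...]
    traps: tuple[TrapSpec, ...]
    seasonal: dict[int, float]  # month -> weight
    host_groups: dict[str, str]
    n_per_taxon: int | None = None  # if set, exactly this many records per taxon

    def __post_init__(self) -> None:
        if self.n < 1 and self.n_per_taxon is None:
            raise ConfigError("n must be >= 1")
        for coll, label in [
            ([s.weight for s in self.sites], "site weights"),
            ([t.abundance for t in self.taxa], "taxon abundances"),
            ([t.weight for t in self.traps], "trap weights"),
            (list(self.seasonal.values()), "seasonal weights"),
        ]:
            if not coll or min(coll) < 0 or sum(coll) <= 0:
                raise ConfigError(f"{label} must be non-negative with positive sum")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters plus realized outcomes of one survey draw."""

    expected_group_fractions: dict[str, dict[str, float]]
    realized_group_fractions: dict[str, dict[str, float]]
    preferences: dict[str, dict[str, float]]


def default_survey_config(
    seed: int,
    n: int = 2000,
    n_per_taxon: int | None = None,
    trap_bias: dict[str, dict[str, float]] | None = None,
) -> SurveyConfig:
    """A realistic default: four sites across land uses with uneven host
    availability, four taxa spanning mammal-biased to bird-biased feeders,
    two trap methods, and a summer-peaked season."""
    sites = (
        SiteSpec("u1", "urban", {**{h: 0.3 for h in SYNTHETIC_HOSTS}, "Homo sapiens": 3.0, "Passer domesticus": 1.5}),
        SiteSpec("r1", "rural", {**{h: 0.6 for h in SYNTHETIC_HOSTS}, "Bos taurus": 3.0, "Capreolus capreolus": 2.5, "Sus scrofa": 1.5}),
        SiteSpec("r2", "rural", {**{h: 0.6 for h in SYNTHETIC_HOSTS}, "Capreolus capreolus": 3.0, "Ovis aries": 1.5}),
        SiteSpec("n1", "natural", {**{h: 0.8 for h in SYNTHETIC_HOSTS}, "Capreolus capreolus": 2.0, "Turdus merula": 2.0}),
    )
    taxa = (
        TaxonSpec("Aedes vexans", 0.47, {**{h: 0.2 for h in SYNTHETIC_BIRDS}, **{h: 2.0 for h in SYNTHETIC_MAMMALS}, "Homo sapiens": 1.0}),
        TaxonSpec("Culex pipiens pipiens form pipiens", 0.13, {h: 1.0 for h in SYNTHETIC_HOSTS}),
        TaxonSpec("Culex torrentium", 0.05, {**{h: 2.0 for h in SYNTHETIC_BIRDS}, **{h: 0.3 for h in SYNTHETIC_MAMMALS}, "Homo sapiens": 1.0}),
        TaxonSpec("Ochlerotatus cantans", 0.35, {**{h: 0.0 for h in SYNTHETIC_BIRDS}, **{h: 1.5 for h in SYNTHETIC_MAMMALS}, "Homo sapiens": 1.0}),
    )
    bias = trap_bias or {}
    traps = (
        TrapSpec("EVS", bias.get("EVS", {}), weight=0.8),
        TrapSpec("gravid", bias.get("gravid", {}), weight=0.2),
    )
    seasonal = {m: w for m, w in zip(range(1, 13), (0, 0, 1, 2, 4, 6, 8, 8, 5, 2, 1, 0))}
    return SurveyConfig(
        seed=seed,
        n=n,
        sites=sites,
        taxa=taxa,
        traps=traps,
        seasonal=seasonal,
        host_groups=dict(SYNTHETIC_HOST_GROUPS),
        n_per_taxon=n_per_taxon,
    )


def _host_distribution(
    taxon: TaxonSpec, site: SiteSpec, trap: TrapSpec, host_groups: dict[str, str]
) -> tuple[tuple[str, ...], np.ndarray]:
    hosts = tuple(taxon.preference)
    w = np.array(
        [
            taxon.preference[h]
            * site.availability.get(h, 0.0)
            * trap.bias.get(host_groups[h], 1.0)
            for h in hosts
        ]
    )
    total = w.sum()
    if total <= 0:
        raise ConfigError(
            f"taxon {taxon.name!r} has an all-zero host distribution at site "
            f"{site.site_id!r} with trap {trap.name!r}"
        )
    return hosts, w / total


def generate_survey(config: SurveyConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Draw a survey dataset plus its generating/realized ground truth."""
    rng = np.random.default_rng(config.seed)
    site_p = np.array([s.weight for s in config.sites], dtype=float)
    site_p /= site_p.sum()
    trap_p = np.array([t.weight for t in config.traps], dtype=float)
    trap_p /= trap_p.sum()
    months = sorted(config.seasonal)
    month_p = np.array([config.seasonal[m] for m in months], dtype=float)
    month_p /= month_p.sum()
    taxon_p = np.array([t.abundance for t in config.taxa], dtype=float)
    taxon_p /= taxon_p.sum()

    # expected host-group fractions per taxon, marginalized over site and trap
    expected: dict[str, dict[str, float]] = {}
    for taxon in config.taxa:
        acc = {g: 0.0 for g in ("bird", "non-human mammal", "human")}
        for site, sp in zip(config.sites, site_p):
            for trap, tp in zip(config.traps, trap_p):
                hosts, w = _host_distribution(taxon, site, trap, config.host_groups)
                for h, p in zip(hosts, w):
                    acc[config.host_groups[h]] += sp * tp * p
        expected[taxon.name] = acc

    if config.n_per_taxon is not None:
        taxon_draws = np.repeat(np.arange(len(config.taxa)), config.n_per_taxon)
    else:
        taxon_draws = rng.choice(len(config.taxa), size=config.n, p=taxon_p)

    records: list[BloodMealRecord] = []
    realized: dict[str, dict[str, int]] = {
        t.name: {"bird": 0, "non-human mammal": 0, "human": 0} for t in config.taxa
    }
    for i, ti in enumerate(taxon_draws):
        taxon = config.taxa[int(ti)]
        site = config.sites[int(rng.choice(len(config.sites), p=site_p))]
        trap = config.traps[int(rng.choice(len(config.traps), p=trap_p))]
        month = months[int(rng.choice(len(months), p=month_p))]
        hosts, w = _host_distribution(taxon, site, trap, config.host_groups)
        host = hosts[int(rng.choice(len(hosts), p=w))]
        group = config.host_groups[host]
        realized[taxon.name][group] += 1
        records.append(
            BloodMealRecord(
                specimen_id=f"SYN{i:05d}",
                mosquito_taxon=taxon.name,
                host_species=host,
                host_group=group,
                site_id=site.site_id,
                collection_date=_dt.date(2014, month, int(rng.integers(1, 29))),
                trap_method=trap.name,
                land_use=site.land_use,
            )
        )
    realized_frac = {
        t: {g: (c / max(sum(d.values()), 1)) for g, c in d.items()}
        for t, d in ((t, d) for t, d in realized.items())
    }
    truth = GroundTruth(
        expected_group_fractions=expected,
        realized_group_fractions=realized_frac,
        preferences={t.name: dict(t.preference) for t in config.taxa},
    )
    sites_meta = {s.site_id: {"land_use": s.land_use} for s in config.sites}
    return SurveyDataset(records, sites_meta), truth


def generate_feeding_scenario(
    kind: str,
    n_hosts: int = 8,
    n_columns: int = 6,
    seed: int = 0,
    row_fill: int = 2,
    extra_per_row: int = 1,
) -> PresenceAbsenceMatrix:
    """A presence-absence matrix with a known co-occurrence structure.

    aggregated: column 0 is a universal host column (every row present)
    plus ``extra_per_row`` noise presences per row elsewhere; segregated:
    rows occupy pairwise disjoint column blocks (requires
    n_hosts <= n_columns, so pass explicit sizes, e.g. 4 hosts over 8
    columns); random: ``row_fill`` presences per row placed uniformly —
    the fixed-equiprobable null itself.

    Default sizes mirror a per-species host-by-site analysis at desk scale:
    a handful of sites, most hosts present at only a couple of them. Sparse
    rows keep the C-score lattice coarse, which (with tie-inclusive tails)
    keeps the null-model verdict conservative on random matrices while a
    universal shared host remains easily detected.
    """
    if n_hosts < 2 or n_columns < 2:
        raise ConfigError("n_hosts and n_columns must each be >= 2")
    rng = np.random.default_rng(seed)
    data = np.zeros((n_hosts, n_columns), dtype=np.uint8)
    if kind == "aggregated":
        data[:, 0] = 1
        for i in range(n_hosts):
            k = min(extra_per_row, n_columns - 1)
            data[i, 1 + rng.choice(n_columns - 1, size=k, replace=False)] = 1
    elif kind == "segregated":
        if n_hosts > n_columns:
            raise ConfigError(
                f"segregated scenario infeasible: {n_hosts} hosts > {n_columns} columns"
            )
        bounds = np.linspace(0, n_columns, n_hosts + 1).astype(int)
        for i in range(n_hosts):
            data[i, bounds[i] : bounds[i + 1]] = 1
    elif kind == "random":
        for i in range(n_hosts):
            data[i, rng.choice(n_columns, size=min(row_fill, n_columns), replace=False)] = 1
    else:
        raise ConfigError(f"unknown scenario kind {kind!r}")
    return PresenceAbsenceMatrix(
        data,
        tuple(f"host-{i:02d}" for i in range(n_hosts)),
        tuple(f"col-{j:02d}" for j in range(n_columns)),
    )


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def synthetic_reference_panel(
    seed: int = 7, min_divergence: float = 0.10
) -> ReferencePanel:
    """Cytochrome-b-like references for the twelve synthetic host species.

    Each reference carries the binding sites of both primer pairs with
    species-specific inserts sized so the products are ~244 bp and ~358 bp.
    Inserts are drawn independently per species and checked for pairwise
    divergence >= ``min_divergence``; the construction is deterministic in
    the seed.
    """
    rng = np.random.default_rng(seed)
    p1f = KITANO_PAIR.forward_sequence
    p1r = reverse_complement(KITANO_PAIR.reverse_sequence)
    p2f = KOCHER_PAIR.forward_sequence
    p2r = reverse_complement(KOCHER_PAIR.reverse_sequence)
    insert1_len = KITANO_PAIR.expected_length - len(p1f) - len(p1r)
    insert2_len = KOCHER_PAIR.expected_length - len(p2f) - len(p2r)

    entries = []
    inserts1: list[str] = []
    for name in SYNTHETIC_HOSTS:
        for _ in range(100):  # rejection loop; virtually always exits at once
            ins1 = _random_seq(rng, insert1_len)
            div_ok = all(
                np.mean([a != b for a, b in zip(ins1, prev)]) >= min_divergence
                for prev in inserts1
            )
            if div_ok:
                break
        else:
            raise ConfigError("could not achieve required panel divergence")
        inserts1.append(ins1)
        ins2 = _random_seq(rng, insert2_len)
        seq = (
            _random_seq(rng, 20)
            + p1f + ins1 + p1r
            + _random_seq(rng, 30)
            + p2f + ins2 + p2r
            + _random_seq(rng, 20)
        )
        entries.append((name, seq))
    return ReferencePanel(tuple(entries))


def generate_amplicons(
    panel: ReferencePanel,
    per_taxon: int | dict[str, int],
    substitution_rate: float,
    seed: int,
) -> list[tuple[str, str, str]]:
    """Mutated copies of panel sequences as (query_id, sequence, true_taxon).

    Each query is a panel member with i.i.d. substitutions at the given
    rate (a substitution always changes the base).
    """
    if not 0.0 <= substitution_rate <= 0.2:
        raise ConfigError("substitution_rate must lie in [0, 0.2]")
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(seed)
    counts = (
        {name: per_taxon for name, _ in panel.entries}
        if isinstance(per_taxon, int)
        else dict(per_taxon)
    )
    out: list[tuple[str, str, str]] = []
    k = 0
    for name, seq in panel.entries:
        for _ in range(counts.get(name, 0)):
            chars = np.array(list(seq))
            hit = rng.random(len(chars)) < substitution_rate
            for pos in np.flatnonzero(hit):
                choices = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = choices[int(rng.integers(3))]
            out.append((f"q{k:05d}", "".join(chars), name))
            k += 1
    return out
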