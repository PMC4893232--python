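"""Core data model for blood-meal survey records.

One row of a survey is a single engorged mosquito: the mosquito taxon it was
identified as, the vertebrate host species its gut content was typed to, and
the sampling context (site, date, trap method, land use around the site).
Host species are collapsed into three host groups — birds, non-human mammals
and humans — through an explicit taxonomy; all downstream analyses
(period comparisons, co-occurrence null models, feeding-group clustering,
transmission-risk indices) operate on these records.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import (
    EmptyDatasetError,
    FormatError,
    LandUseTieError,
    TaxonomyError,
    UnclassifiedLandCoverError,
)

logger = logging.getLogger(__name__)

HOST_GROUPS: tuple[str, ...] = ("bird", "non-human mammal", "human")
TRAP_METHODS: tuple[str, ...] = (
    "EVS",
    "BG-Sentinel",
    "gravid",
    "aspirator",
    "sweep-net",
    "human-bait",
)
LAND_USES: tuple[str, ...] = ("urban", "rural", "natural")
UNIDENTIFIED = "unidentified"

#: Columns a records file must provide, in canonical order.
RECORD_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "mosquito_taxon",
    "host_species",
    "site_id",
    "collection_date",
    "trap_method",
    "land_use",
)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-table style (e.g. 0.25 -> 0.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class HostTaxonomy:
    """Mapping from host species (Latin binomial) to host group.

    Unknown species raise :class:`TaxonomyError` rather than defaulting:
    a silent mis-grouping would corrupt every downstream fraction.
    """

    def __init__(self, mapping: Mapping[str, str], provenance: Mapping[str, str] | None = None):
        for species, group in mapping.items():
            if group not in HOST_GROUPS:
                raise ValueError(f"unknown host group {group!r} for {species!r}")
        if mapping.get("Homo sapiens", "human") != "human":
            raise ValueError("Homo sapiens must map to the human group")
        self._mapping = dict(mapping)
        self._provenance = dict(provenance or {})

    def group_of(self, host_species: str) -> str:
        try:
            return self._mapping[host_species]
        except KeyError:
            raise TaxonomyError(
                f"host species {host_species!r} is not in the taxonomy"
            ) from None

    def __contains__(self, host_species: str) -> bool:
        return host_species in self._mapping

    def __len__(self) -> int:
        return len(self._mapping)

    def species(self) -> tuple[str, ...]:
        return tuple(self._mapping)

    def provenance_of(self, host_species: str) -> str | None:
        return self._provenance.get(host_species)

    @classmethod
    def from_file(cls, path: str | Path) -> "HostTaxonomy":
        """Read a two-column delimited file (host_species, host_group)."""
        frame = _read_delimited(path)
        for col in ("host_species", "host_group"):
            if col not in frame.columns:
                raise FormatError(f"taxonomy file missing column {col!r}")
        return cls(
            dict(zip(frame["host_species"], frame["host_group"])),
            provenance={s: str(path) for s in frame["host_species"]},
        )

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(
            {"host_species": list(self._mapping), "host_group": list(self._mapping.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BloodMealRecord:
    """One identified blood-fed mosquito specimen."""

    specimen_id: str
    mosquito_taxon: str
    host_species: str
    host_group: str | None  # None only for unidentified hosts
    site_id: str
    collection_date: _dt.date
    trap_method: str
    land_use: str

    def __post_init__(self) -> None:
        if self.host_species != UNIDENTIFIED and self.host_group not in HOST_GROUPS:
            raise ValueError(
                f"record {self.specimen_id}: host_group {self.host_group!r} invalid"
            )
        if self.trap_method not in TRAP_METHODS:
            raise ValueError(
                f"record {self.specimen_id}: trap_method {self.trap_method!r} invalid"
            )
        if self.land_use not in LAND_USES:
            raise ValueError(
                f"record {self.specimen_id}: land_use {self.land_use!r} invalid"
            )


@dataclass
class SurveyDataset:
    """An ordered collection of records plus per-site metadata.

    ``sites`` maps site_id to its land-use class; extra keys (e.g. land-cover
    proportions) are carried through untouched.
    """

    records: list[BloodMealRecord]
    sites: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes[:5]}")
        if not self.sites:
            self.sites = {
                r.site_id: {"land_use": r.land_use} for r in self.records
            }
        missing = {r.site_id for r in self.records} - set(self.sites)
        if missing:
            raise ValueError(f"records reference unknown sites: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BloodMealRecord]:
        return iter(self.records)

    def identified(self) -> "SurveyDataset":
        """Drop records whose host could not be identified (logged, not silent)."""
        kept = [r for r in self.records if r.host_species != UNIDENTIFIED]
        n_dropped = len(self.records) - len(kept)
        if n_dropped:
            logger.info("excluding %d records with unidentified hosts", n_dropped)
        return SurveyDataset(kept, dict(self.sites))

    def filter_taxon(self, taxon: str) -> "SurveyDataset":
        return SurveyDataset(
            [r for r in self.records if r.mosquito_taxon == taxon], dict(self.sites)
        )

    def taxa(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.mosquito_taxon, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in self.records],
                "mosquito_taxon": [r.mosquito_taxon for r in self.records],
                "host_species": [r.host_species for r in self.records],
                "host_group": [r.host_group for r in self.records],
                "site_id": [r.site_id for r in self.records],
                "collection_date": [r.collection_date.isoformat() for r in self.records],
                "trap_method": [r.trap_method for r in self.records],
                "land_use": [r.land_use for r in self.records],
            }
        )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read comma- or tab-delimited UTF-8 text, auto-detecting the delimiter."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    delim = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, comment="#")


def read_records(path: str | Path, taxonomy: HostTaxonomy) -> SurveyDataset:
    """Read a survey records file into a :class:`SurveyDataset`.

    Host groups are filled from ``taxonomy``; malformed rows are reported with
    their line numbers, unknown host species with their names.
    """
    frame = _read_delimited(path)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"records file {path} missing columns: {missing}")

    unknown_hosts: set[str] = set()
    bad_rows: list[str] = []
    records: list[BloodMealRecord] = []
    for idx, row in frame.iterrows():
        lineno = int(idx) + 2  # header is line 1
        host = row["host_species"]
        if host != UNIDENTIFIED and host not in taxonomy:
            unknown_hosts.add(host)
            continue
        try:
            date = _dt.date.fromisoformat(row["collection_date"])
            records.append(
                BloodMealRecord(
                    specimen_id=row["specimen_id"],
                    mosquito_taxon=row["mosquito_taxon"],
                    host_species=host,
                    host_group=None if host == UNIDENTIFIED else taxonomy.group_of(host),
                    site_id=row["site_id"],
                    collection_date=date,
                    trap_method=row["trap_method"],
                    land_use=row["land_use"],
                )
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append(f"line {lineno}: {exc}")
    if unknown_hosts:
        raise TaxonomyError(
            f"unknown host species in {path}: {sorted(unknown_hosts)}"
        )
    if bad_rows:
        raise FormatError(f"malformed rows in {path}: " + "; ".join(bad_rows[:10]))
    return SurveyDataset(records)


def write_records(dataset: SurveyDataset, path: str | Path, sep: str = ",") -> None:
    dataset.to_frame().to_csv(path, index=False, sep=sep)


def assign_period(date: _dt.date) -> str:
    """Sampling period: months 1-6 are 'early', months 7-12 'late'."""
    return "early" if date.month <= 6 else "late"


def aggregate_corine(class_code: int) -> str:
    """Collapse a land-cover class code into urban/rural/natural.

    Codes 111-142 are artificial surfaces (urban), 211-244 agricultural
    (rural), 311-423 forest, semi-natural, wetland and water (natural).
    """
    if 111 <= class_code <= 142:
        return "urban"
    if 211 <= class_code <= 244:
        return "rural"
    if 311 <= class_code <= 423:
        return "natural"
    raise UnclassifiedLandCoverError(f"land-cover class code {class_code} is unclassified")


def classify_land_use(
    proportions: Mapping[str, float],
    tie_break: Sequence[str] | None = None,
) -> str:
    """Dominant land-use class around a site from aggregate cover proportions.

    Raises :class:`LandUseTieError` on an exact tie unless ``tie_break`` gives
    an explicit precedence order (e.g. ``("urban", "rural", "natural")``).
    """
    cleaned = {k: float(proportions.get(k, 0.0)) for k in LAND_USES}
    if any(v < 0 for v in cleaned.values()):
        raise ValueError("proportions must be non-negative")
    if sum(cleaned.values()) > 1.0 + 1e-9:
        raise ValueError("proportions sum to more than 1")
    top = max(cleaned.values())
    winners = [k for k, v in cleaned.items() if v == top]
    if len(winners) == 1:
        return winners[0]
    if tie_break is None:
        raise LandUseTieError(f"exact tie between {winners}; supply a tie_break order")
    for cls in tie_break:
        if cls in winners:
            return cls
    raise LandUseTieError(f"tie_break {tie_break} does not cover {winners}")


def _identified_records(dataset: SurveyDataset) -> list[BloodMealRecord]:
    recs = dataset.identified().records
    if not recs:
        raise EmptyDatasetError("no identified records in dataset")
    return recs


def tabulate_species_summary(dataset: SurveyDataset) -> pd.DataFrame:
    """Per-mosquito-taxon summary: n, share of all specimens, host-group counts,
    number of distinct host species.

    Percentages are kept at full precision in ``pct_all_specimens``; a
    display-rounded column ``pct_display`` (one decimal, half-up) mirrors
    printed-table style.
    """
    recs = _identified_records(dataset)
    total = len(recs)
    rows: dict[str, dict] = {}
    for r in recs:
        d = rows.setdefault(
            r.mosquito_taxon,
            {"n_specimens": 0, **{g: 0 for g in HOST_GROUPS}, "hosts": set()},
        )
        d["n_specimens"] += 1
        d[r.host_group] += 1
        d["hosts"].add(r.host_species)
    out = pd.DataFrame(
        {
            "mosquito_taxon": list(rows),
            "n_specimens": [d["n_specimens"] for d in rows.values()],
            "pct_all_specimens": [100.0 * d["n_specimens"] / total for d in rows.values()],
            "birds": [d["bird"] for d in rows.values()],
            "non_human_mammals": [d["non-human mammal"] for d in rows.values()],
            "humans": [d["human"] for d in rows.values()],
            "n_host_species": [len(d["hosts"]) for d in rows.values()],
        }
    ).sort_values("mosquito_taxon", kind="stable", ignore_index=True)
    out["pct_display"] = out["pct_all_specimens"].map(lambda v: round_half_up(v, 1))
    return out


def tabulate_host_summary(dataset: SurveyDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-host-species and per-host-group summaries.

    Returns ``(species_table, group_table)``; group totals equal the sums of
    their member species and the three groups sum to the grand total.
    """
    recs = _identified_records(dataset)
    total = len(recs)
    counts: dict[str, dict] = {}
    for r in recs:
        d = counts.setdefault(r.host_species, {"n": 0, "group": r.host_group})
        d["n"] += 1
    species = pd.DataFrame(
        {
            "host_species": list(counts),
            "host_group": [d["group"] for d in counts.values()],
            "n_specimens": [d["n"] for d in counts.values()],
            "pct_all_specimens": [100.0 * d["n"] / total for d in counts.values()],
        }
    ).sort_values(["host_group", "host_species"], kind="stable", ignore_index=True)
    species["pct_display"] = species["pct_all_specimens"].map(lambda v: round_half_up(v, 1))
    groups = (
        species.groupby("host_group", as_index=False)
        .agg(n_specimens=("n_specimens", "sum"), n_species=("host_species", "nunique"))
        .sort_values("host_group", ignore_index=True)
    )
    groups["pct_all_specimens"] = 100.0 * groups["n_specimens"] / total
    groups["pct_display"] = groups["pct_all_specimens"].map(lambda v: round_half_up(v, 1))
    return species, groups


def host_range_breadth(
    dataset: SurveyDataset, denominator_taxa: Sequence[str]
) -> pd.DataFrame:
    """Share of mosquito taxa (from an explicit denominator list) with at
    least one feed on each host species.

    The denominator is explicit because aggregate taxa (e.g. genus-level
    pools) are normally excluded from "percentage of species" statements.
    """
    if not denominator_taxa:
        raise ValueError("denominator_taxa must be non-empty")
    denom = list(dict.fromkeys(denominator_taxa))
    recs = [r for r in dataset.identified() if r.mosquito_taxon in denom]
    feeders: dict[str, set[str]] = {}
    for r in recs:
        feeders.setdefault(r.host_species, set()).add(r.mosquito_taxon)
    return pd.DataFrame(
        {
            "host_species": list(feeders),
            "n_taxa": [len(v) for v in feeders.values()],
            "pct_taxa": [100.0 * len(v) / len(denom) for v in feeders.values()],
        }
    ).sort_values("host_species", ignore_index=True)
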