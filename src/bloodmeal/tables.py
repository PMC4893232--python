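"""Packaged survey summary fixtures and a record-level reconstruction.

The package ships the published aggregate tables of a nationwide German
blood-meal survey (775 engorged mosquitoes, 2012-2015, 52 sites):

* ``load_species_summary`` — per mosquito taxon: specimen counts, host-group
  counts and number of distinct host species (20 named species plus four
  aggregate taxa such as "Culex pipiens (s.l.)/torrentium");
* ``load_host_summary`` — per host species: counts within the three host
  groups (11 birds, Homo sapiens, 20 non-human mammals);
* ``load_period_counts`` — early/late season split of host-group counts for
  the three dominant taxa.

The specimen-level pairing of mosquito taxon and host species was never
published. ``load_host_allocation`` ships one *synthetic reconstruction*: a
feasible allocation consistent with every aggregate count above and with the
published host-range breadths (65 % of the 20 named species fed on roe deer,
90 % on humans, 60 % on cattle, 50 % on wild boar). ``reconstruct_survey``
expands it deterministically into a full record-level dataset so every
analysis stage can run end-to-end.
"""

from __future__ import annotations

import datetime as _dt
from importlib import resources
from pathlib import Path

import pandas as pd

from .records import (
    BloodMealRecord,
    HostTaxonomy,
    SurveyDataset,
)

_DATA = resources.files("bloodmeal") / "data"

#: The three dominant taxa with a published early/late season split.
DOMINANT_TAXA = (
    "Aedes vexans",
    "Culex pipiens pipiens form pipiens",
    "Ochlerotatus cantans",
)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, comment="#")


def load_species_summary() -> pd.DataFrame:
    """Published per-mosquito-taxon summary (counts, shares, host groups)."""
    return _read("species_summary.csv")


def load_host_summary() -> pd.DataFrame:
    """Published per-host-species summary with host-group labels."""
    return _read("host_summary.csv")


def load_period_counts() -> pd.DataFrame:
    """Published early/late host-group counts for the three dominant taxa."""
    return _read("period_counts.csv")


def load_host_allocation() -> pd.DataFrame:
    """Synthetic per-(taxon, host species) count allocation (see module docs)."""
    return _read("host_allocation.csv")


def default_taxonomy() -> HostTaxonomy:
    """Host-group taxonomy covering all 32 host species of the survey."""
    hosts = load_host_summary()
    return HostTaxonomy(
        dict(zip(hosts["host_species"], hosts["host_group"])),
        provenance={s: "packaged host summary" for s in hosts["host_species"]},
    )


def named_species() -> tuple[str, ...]:
    """The 20 named mosquito species (aggregate taxa excluded)."""
    t1 = load_species_summary()
    return tuple(t1.loc[t1["is_aggregate"] == 0, "mosquito_taxon"])


#: Deterministic site roster used by the reconstruction.
_SITES = (
    ("site-01", "urban"),
    ("site-02", "urban"),
    ("site-03", "rural"),
    ("site-04", "rural"),
    ("site-05", "rural"),
    ("site-06", "natural"),
)
_EARLY_MONTHS = (4, 5, 6)
_LATE_MONTHS = (7, 8, 9)
_YEARS = (2012, 2013, 2014, 2015)


def _record_date(period: str, k: int) -> _dt.date:
    months = _EARLY_MONTHS if period == "early" else _LATE_MONTHS
    return _dt.date(_YEARS[k % len(_YEARS)], months[k % len(months)], 1 + (k % 28))


def reconstruct_survey() -> SurveyDataset:
    """Expand the packaged allocation into a deterministic record-level dataset.

    Group-level early/late splits follow the published period table for the
    three dominant taxa (other taxa default to the late period, when most
    by-catch accrues). Sites cycle through a fixed roster; bird-fed Culex
    specimens are attributed to gravid traps and every tenth record to a
    sweep net, echoing the survey's trap mix, with EVS traps elsewhere.
    Dates, sites and traps are synthetic plumbing: only the taxon, host,
    group and period structure is data-constrained.
    """
    taxonomy = default_taxonomy()
    alloc = load_host_allocation()
    period_counts = load_period_counts()

    early_quota: dict[tuple[str, str], int] = {}
    for _, row in period_counts.iterrows():
        if row["period"] == "early":
            early_quota[(row["mosquito_taxon"], row["host_group"])] = int(
                row["n_specimens"]
            )

    records: list[BloodMealRecord] = []
    counter = 0
    for taxon, taxon_rows in alloc.groupby("mosquito_taxon", sort=True):
        group_seen: dict[str, int] = {}
        k = 0
        for _, row in taxon_rows.sort_values("host_species").iterrows():
            host = row["host_species"]
            group = taxonomy.group_of(host)
            for _ in range(int(row["count"])):
                quota = early_quota.get((taxon, group))
                used = group_seen.get(group, 0)
                if quota is not None:
                    period = "early" if used < quota else "late"
                else:
                    period = "late"
                group_seen[group] = used + 1
                site_id, land_use = _SITES[k % len(_SITES)]
                if group == "bird" and taxon.startswith("Culex"):
                    trap = "gravid"
                elif counter % 10 == 9:
                    trap = "sweep-net"
                else:
                    trap = "EVS"
                counter += 1
                records.append(
                    BloodMealRecord(
                        specimen_id=f"RM{counter:04d}",
                        mosquito_taxon=taxon,
                        host_species=host,
                        host_group=group,
                        site_id=site_id,
                        collection_date=_record_date(period, k),
                        trap_method=trap,
                        land_use=land_use,
                    )
                )
                k += 1
    sites = {sid: {"land_use": lu} for sid, lu in _SITES}
    return SurveyDataset(records, sites)


def write_fixture_files(out_dir: str | Path) -> list[Path]:
    """Copy the packaged fixture tables into ``out_dir`` as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, loader in [
        ("species_summary.csv", load_species_summary),
        ("host_summary.csv", load_host_summary),
        ("period_counts.csv", load_period_counts),
        ("host_allocation.csv", load_host_allocation),
    ]:
        path = out / name
        loader().to_csv(path, index=False)
        written.append(path)
    return written
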