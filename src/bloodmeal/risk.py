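"""Host-feeding-based transmission-risk index per mosquito species.

For a taxon with relative abundance Ap (fraction of all surveyed mosquitoes)
and blood-meal fractions Fa (avian), Fh (human) and Fm (non-human mammal),
the two risk channels are plain products:

    risk from birds to humans            = Ap * Fa * Fh
    risk from non-human mammals to humans = Ap * Fm * Fh

A high bird-to-human value marks a potential bridge vector between avian
reservoirs and people; a high mammal-to-human value marks a vector between
mammalian reservoirs and people. Vector competence is deliberately not a
factor: the index captures ecological contact, not physiological ability.

Abundance tables often pool sibling taxa that field keys cannot separate
(e.g. the Culex pipiens complex); ``share_aggregate_abundance`` propagates a
pooled Ap unchanged to each member taxon, and the sharing is recorded in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import EmptyDatasetError
from .records import SurveyDataset, _read_delimited


@dataclass(frozen=True)
class FeedingFractions:
    taxon: str
    n_blood_meals: int
    fraction_avian: float
    fraction_human: float
    fraction_mammal: float

    def __post_init__(self) -> None:
        for f in (self.fraction_avian, self.fraction_human, self.fraction_mammal):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1]; got {f}")
        if self.n_blood_meals > 0:
            total = self.fraction_avian + self.fraction_human + self.fraction_mammal
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions must sum to 1; got {total}")


@dataclass(frozen=True)
class RiskEstimate:
    taxon: str
    abundance: float  # Ap, fraction of all surveyed specimens
    risk_bird_to_human: float
    risk_mammal_to_human: float
    abundance_shared_from: str | None = None  # aggregate taxon Ap was pooled under

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "abundance_fraction": self.abundance,
            "abundance_pct": 100.0 * self.abundance,
            "risk_bird_to_human": self.risk_bird_to_human,
            "risk_mammal_to_human": self.risk_mammal_to_human,
            "abundance_shared_from": self.abundance_shared_from,
        }


def feeding_fractions(dataset: SurveyDataset, taxon: str) -> FeedingFractions:
    """Host-group blood-meal fractions for one taxon (counts / taxon n)."""
    ds = dataset.identified().filter_taxon(taxon)
    n = len(ds.records)
    if n == 0:
        raise EmptyDatasetError(f"taxon {taxon!r} has no identified records")
    counts = {"bird": 0, "human": 0, "non-human mammal": 0}
    for r in ds:
        counts[r.host_group] += 1
    return FeedingFractions(
        taxon=taxon,
        n_blood_meals=n,
        fraction_avian=counts["bird"] / n,
        fraction_human=counts["human"] / n,
        fraction_mammal=counts["non-human mammal"] / n,
    )


def transmission_risk(fractions: FeedingFractions, abundance: float) -> RiskEstimate:
    """The two risk products for one taxon; ``abundance`` is Ap in [0, 1]."""
    if not 0.0 <= abundance <= 1.0:
        raise ValueError(f"abundance must be a fraction in [0, 1]; got {abundance}")
    return RiskEstimate(
        taxon=fractions.taxon,
        abundance=abundance,
        risk_bird_to_human=abundance * fractions.fraction_avian * fractions.fraction_human,
        risk_mammal_to_human=abundance * fractions.fraction_mammal * fractions.fraction_human,
    )


def rank_species(
    estimates: list[RiskEstimate],
) -> tuple[list[RiskEstimate], list[RiskEstimate]]:
    """Descending rankings on the bird-to-human and mammal-to-human channels.

    Ties are broken alphabetically by taxon name.
    """
    if not estimates:
        raise ValueError("rank_species needs at least one estimate")
    birds = sorted(estimates, key=lambda e: (-e.risk_bird_to_human, e.taxon))
    mammals = sorted(estimates, key=lambda e: (-e.risk_mammal_to_human, e.taxon))
    return birds, mammals


def read_abundance_table(path: str | Path, percentage: bool | None = None) -> dict[str, float]:
    """Read a two-column (taxon, abundance) delimited file into Ap fractions.

    If the value column is named ``abundance_pct`` (or ``percentage=True``),
    values are divided by 100; a column named ``abundance_fraction`` (or
    ``percentage=False``) is taken as-is.
    """
    frame = _read_delimited(path)
    cols = [c for c in frame.columns if c != "taxon"]
    if "taxon" not in frame.columns or len(cols) != 1:
        raise ValueError("abundance table needs columns: taxon, abundance_{pct,fraction}")
    col = cols[0]
    if percentage is None:
        if col == "abundance_pct":
            percentage = True
        elif col == "abundance_fraction":
            percentage = False
        else:
            raise ValueError(f"cannot infer scale from column name {col!r}")
    values = frame[col].astype(float)
    if percentage:
        values = values / 100.0
    return dict(zip(frame["taxon"], values))


def share_aggregate_abundance(
    abundance: dict[str, float], members: dict[str, str]
) -> dict[str, tuple[float, str | None]]:
    """Assign pooled abundances to member taxa.

    ``members`` maps a member taxon to the aggregate taxon whose pooled Ap it
    should inherit unchanged (e.g. both members of a sibling-species complex
    inherit the complex's Ap). Returns {taxon: (Ap, shared_from or None)}.
    """
    out: dict[str, tuple[float, str | None]] = {
        t: (v, None) for t, v in abundance.items()
    }
    for member, aggregate in members.items():
        if aggregate not in abundance:
            raise KeyError(f"aggregate taxon {aggregate!r} missing from abundance table")
        out[member] = (abundance[aggregate], aggregate)
    return out


def risk_table(estimates: list[RiskEstimate]) -> pd.DataFrame:
    birds, mammals = rank_species(estimates)
    frame = pd.DataFrame([e.to_dict() for e in estimates])
    frame["rank_bird_to_human"] = frame["taxon"].map(
        {e.taxon: i + 1 for i, e in enumerate(birds)}
    )
    frame["rank_mammal_to_human"] = frame["taxon"].map(
        {e.taxon: i + 1 for i, e in enumerate(mammals)}
    )
    return frame.sort_values("taxon", ignore_index=True)
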