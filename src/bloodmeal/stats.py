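"""Frequency comparisons of host-feeding patterns.

Chi-square tests compare host-group counts between the two sampling periods
(first vs second half of the year) for a taxon; Kruskal-Wallis compares
per-site host-group percentages across land-use classes; pairwise chi-square
tests contrast the bird:mammal detection ratio between trapping methods,
with multiple-comparison adjustment over the family of trap pairs.

Conventions forced by the reference results: Pearson's statistic without
continuity correction for tables larger than 2x2; Yates' continuity
correction automatically on 2x2 tables; rows/columns with a zero marginal
total are dropped before testing (the degrees of freedom reflect the reduced
table). Expected counts below 5 raise a warning flag, never an error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, EmptyDatasetError
from .records import HOST_GROUPS, SurveyDataset, assign_period

logger = logging.getLogger(__name__)

#: statsmodels method names for the supported adjustment procedures
ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    degrees_of_freedom: int
    p_value: float
    correction: str = "none"  # "none" or "continuity"
    warnings: tuple[str, ...] = ()
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.degrees_of_freedom,
            "p_value": self.p_value,
            "correction": self.correction,
            "p_adjusted": self.p_adjusted,
            "warnings": list(self.warnings),
        }


def _as_counts(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if arr.sum() < 1:
        raise DegenerateTableError("contingency table is empty")
    return arr


def chi_square(
    table, name: str = "chi-square", continuity: bool | None = None
) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    Zero-marginal rows/columns are dropped first; Yates' continuity
    correction is applied iff the reduced table is 2x2 (override with
    ``continuity=True/False``; it never applies beyond 2x2). A table that
    reduces below 2x2 raises :class:`DegenerateTableError`.
    """
    arr = _as_counts(table)
    # drop zero margins (rows then columns)
    arr = arr[arr.sum(axis=1) > 0]
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTableError(
            f"table reduces to shape {arr.shape} after dropping zero margins"
        )
    is_2x2 = arr.shape == (2, 2) if continuity is None else (continuity and arr.shape == (2, 2))
    stat, p, df, expected = _sps.chi2_contingency(arr, correction=is_2x2)
    warns = []
    if (expected < 5).any():
        warns.append(f"{int((expected < 5).sum())} expected cell(s) below 5")
    return TestResult(
        name=name,
        statistic=float(stat),
        degrees_of_freedom=int(df),
        p_value=float(p),
        correction="continuity" if is_2x2 else "none",
        warnings=tuple(warns),
    )


def kruskal_wallis(groups: list, name: str = "kruskal-wallis") -> TestResult:
    """Kruskal-Wallis rank test with tie correction (chi-square approximation).

    When every observation is identical the tie-correction denominator
    vanishes; the statistic is reported as 0 with a ties warning instead of
    an error. Groups smaller than 5 get a small-sample warning because the
    chi-square approximation is rough there.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    samples = [np.asarray(g, dtype=float) for g in groups]
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    warns = []
    if any(s.size < 5 for s in samples):
        warns.append("group(s) smaller than 5; chi-square approximation is rough")
    pooled = np.concatenate(samples)
    df = len(samples) - 1
    if np.ptp(pooled) == 0:
        return TestResult(
            name=name,
            statistic=0.0,
            degrees_of_freedom=df,
            p_value=1.0,
            warnings=tuple(warns + ["all observations identical"]),
        )
    stat, p = _sps.kruskal(*samples)
    return TestResult(
        name=name,
        statistic=float(stat),
        degrees_of_freedom=df,
        p_value=float(p),
        warnings=tuple(warns),
    )


def period_comparison(
    dataset: SurveyDataset, taxon: str
) -> tuple[pd.DataFrame, TestResult]:
    """Early/late period versus host-group contingency table for one taxon,
    with its chi-square test.

    Returns the full period x host-group count table (so period percentages
    can be reproduced) alongside the test on the zero-margin-reduced table.
    """
    ds = dataset.identified().filter_taxon(taxon)
    if not ds.records:
        raise EmptyDatasetError(f"taxon {taxon!r} not present in dataset")
    counts = pd.DataFrame(0, index=["early", "late"], columns=list(HOST_GROUPS))
    for r in ds:
        counts.loc[assign_period(r.collection_date), r.host_group] += 1
    result = chi_square(counts.to_numpy(), name=f"period comparison: {taxon}")
    return counts, result


def pairwise_trap_tests(
    dataset: SurveyDataset, adjust: str = "bh"
) -> pd.DataFrame:
    """Bird-versus-mammal detection compared between every pair of trapping
    methods, with adjusted p-values over the family of pairs.

    Traps without any bird-or-mammal record are excluded (logged). Pairs
    whose 2x2 table degenerates (e.g. no birds in either trap) are reported
    with NaN statistics and a note rather than silently dropped.
    """
    if adjust not in ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(ADJUST_METHODS)}")
    counts: dict[str, dict[str, int]] = {}
    for r in dataset.identified():
        if r.host_group in ("bird", "non-human mammal"):
            d = counts.setdefault(r.trap_method, {"bird": 0, "non-human mammal": 0})
            d[r.host_group] += 1
    traps = sorted(t for t, d in counts.items() if d["bird"] + d["non-human mammal"] > 0)
    excluded = sorted(set(counts) - set(traps))
    if excluded:
        logger.info("excluding traps without relevant records: %s", excluded)
    if len(traps) < 2:
        raise EmptyDatasetError("fewer than 2 trap methods with bird/mammal records")

    rows = []
    for a, b in itertools.combinations(traps, 2):
        table = np.array(
            [
                [counts[a]["bird"], counts[a]["non-human mammal"]],
                [counts[b]["bird"], counts[b]["non-human mammal"]],
            ]
        )
        try:
            res = chi_square(table, name=f"{a} vs {b}")
            rows.append(
                {
                    "trap_a": a,
                    "trap_b": b,
                    "statistic": res.statistic,
                    "df": res.degrees_of_freedom,
                    "p_raw": res.p_value,
                    "warnings": "; ".join(res.warnings),
                }
            )
        except DegenerateTableError as exc:
            rows.append(
                {
                    "trap_a": a,
                    "trap_b": b,
                    "statistic": np.nan,
                    "df": 0,
                    "p_raw": np.nan,
                    "warnings": f"degenerate table: {exc}",
                }
            )
    out = pd.DataFrame(rows)
    mask = out["p_raw"].notna()
    adjusted = np.full(len(out), np.nan)
    if mask.any():
        adjusted[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_raw"].to_numpy(), method=ADJUST_METHODS[adjust]
        )[1]
    out["p_adjusted"] = adjusted
    out["adjust_method"] = adjust
    return out
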