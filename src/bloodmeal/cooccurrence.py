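"""C-score null-model analysis of host-feeding patterns.

The observed host-by-column presence-absence matrix (columns are mosquito
taxa for the survey-wide analysis, or trapping sites for per-taxon analyses)
is summarized by the C-score: the mean number of checkerboard units over all
unordered row pairs,

    C = mean_{i<j} (r_i - S_ij)(r_j - S_ij),

where r_i is row i's total and S_ij the number of columns shared by rows i
and j. Low C-scores mean hosts co-occur on the same columns (an *aggregated*
feeding pattern — many taxa share at least one host); high C-scores mean
mutual exclusion (*segregated*).

Significance comes from a fixed-equiprobable randomization null: each row's
total is kept fixed and its presences are re-placed uniformly at random over
all columns, rows independent. Tail probabilities use the add-one
(observed-included) convention, so with n iterations the smallest reportable
p is 1/(n+1); ties between a null value and the observed score count toward
both tails. The verdict is aggregated if P(null <= observed) < alpha,
segregated if P(null >= observed) < alpha, random otherwise.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateMatrixError, EmptyDatasetError
from .records import HOST_GROUPS, SurveyDataset

logger = logging.getLogger(__name__)

#: float comparisons between rational C-scores
_EPS = 1e-9


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary host-occurrence matrix with row and column labels."""

    data: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise ValueError("label lengths must match matrix shape")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("row labels must be unique")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("column labels must be unique")
        object.__setattr__(self, "data", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.row_labels), columns=list(self.col_labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceAbsenceMatrix":
        return cls(frame.to_numpy(), tuple(map(str, frame.index)), tuple(map(str, frame.columns)))


@dataclass(frozen=True)
class NullModelConfig:
    """Randomization settings; the seed is mandatory (no wall-clock seeding)."""

    seed: int
    n_iterations: int = 5000
    algorithm: str = "fixed-equiprobable"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.algorithm != "fixed-equiprobable":
            raise ValueError(f"unsupported algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class NullModelResult:
    observed_c_score: float
    null_mean: float
    null_variance: float
    p_low: float
    p_high: float
    n_iterations: int
    seed: int
    pattern: str
    alpha: float = 0.05

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed_c_score": self.observed_c_score,
                "null_mean": self.null_mean,
                "null_variance": self.null_variance,
                "p_low": self.p_low,
                "p_high": self.p_high,
                "n_iterations": self.n_iterations,
                "seed": self.seed,
                "alpha": self.alpha,
                "pattern": self.pattern,
            },
            indent=2,
        )

    def summary_line(self, label: str = "matrix") -> str:
        """One-line report in the style of a published null-model table row."""
        return (
            f"{label}\tC-score {self.observed_c_score:.3f}\t"
            f"Mean ± Variance {self.null_mean:.3f} ± {self.null_variance:.3f}\t"
            f"P<exp {self.p_low:.4g}\tP>exp {self.p_high:.4g}\t{self.pattern.capitalize()}"
        )


def build_matrix(
    dataset: SurveyDataset,
    rows: str = "host_species",
    columns: str = "mosquito_taxon",
    taxon: str | None = None,
    column_subset: tuple[str, ...] | None = None,
) -> PresenceAbsenceMatrix:
    """Build a presence-absence matrix from survey records.

    ``rows`` is ``host_species`` or ``host_group``; ``columns`` is
    ``mosquito_taxon`` (survey-wide analysis) or ``site_id`` (per-taxon
    analysis, with ``taxon`` set). A cell is 1 iff at least one record links
    the row host to the column entity. All-zero rows/columns are dropped and
    logged; a result smaller than 2x2 raises :class:`DegenerateMatrixError`.
    """
    if rows not in ("host_species", "host_group"):
        raise ValueError(f"invalid rows axis {rows!r}")
    if columns not in ("mosquito_taxon", "site_id"):
        raise ValueError(f"invalid columns axis {columns!r}")
    ds = dataset.identified()
    if taxon is not None:
        ds = ds.filter_taxon(taxon)
    if not ds.records:
        raise EmptyDatasetError(f"no records for taxon {taxon!r}" if taxon else "empty dataset")

    row_vals: dict[str, int] = {}
    col_vals: dict[str, int] = {}
    cells: set[tuple[int, int]] = set()
    for r in ds:
        rv = r.host_species if rows == "host_species" else r.host_group
        cv = r.mosquito_taxon if columns == "mosquito_taxon" else r.site_id
        if column_subset is not None and cv not in column_subset:
            continue
        i = row_vals.setdefault(rv, len(row_vals))
        j = col_vals.setdefault(cv, len(col_vals))
        cells.add((i, j))
    data = np.zeros((len(row_vals), len(col_vals)), dtype=np.uint8)
    for i, j in cells:
        data[i, j] = 1

    keep_r = data.sum(axis=1) > 0
    keep_c = data.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.info(
            "dropping %d all-zero rows and %d all-zero columns",
            int((~keep_r).sum()),
            int((~keep_c).sum()),
        )
    data = data[keep_r][:, keep_c]
    row_labels = tuple(l for l, k in zip(row_vals, keep_r) if k)
    col_labels = tuple(l for l, k in zip(col_vals, keep_c) if k)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise DegenerateMatrixError(
            f"matrix degenerate after drops: shape {data.shape}"
        )
    order_r = np.argsort(row_labels, kind="stable")
    order_c = np.argsort(col_labels, kind="stable")
    return PresenceAbsenceMatrix(
        data[order_r][:, order_c],
        tuple(np.asarray(row_labels)[order_r]),
        tuple(np.asarray(col_labels)[order_c]),
    )


def c_score(matrix: PresenceAbsenceMatrix | np.ndarray) -> float:
    """Mean checkerboard units over all unordered row pairs."""
    data = matrix.data if isinstance(matrix, PresenceAbsenceMatrix) else np.asarray(matrix)
    n_rows = data.shape[0]
    if n_rows < 2:
        raise ValueError("C-score requires at least 2 rows")
    r = data.sum(axis=1).astype(np.int64)
    s = (data.astype(np.int64) @ data.T.astype(np.int64))
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(n_rows, k=1)
    return float(cu[iu].mean())


def fixed_equiprobable_randomize(
    matrix: PresenceAbsenceMatrix, rng: np.random.Generator
) -> PresenceAbsenceMatrix:
    """One fixed-equiprobable randomization: row totals preserved, each row's
    presences re-placed uniformly over distinct columns, rows independent."""
    data = matrix.data
    out = np.zeros_like(data)
    n_cols = data.shape[1]
    for i, row in enumerate(data):
        k = int(row.sum())
        if k:
            out[i, rng.choice(n_cols, size=k, replace=False)] = 1
    return PresenceAbsenceMatrix(out, matrix.row_labels, matrix.col_labels)


def _null_c_scores(
    data: np.ndarray, n_iterations: int, rng: np.random.Generator, batch: int = 2000
) -> np.ndarray:
    """Vectorized null ensemble of C-scores under fixed-equiprobable."""
    n_rows, n_cols = data.shape
    row_sums = data.sum(axis=1).astype(np.int64)
    iu = np.triu_indices(n_rows, k=1)
    out = np.empty(n_iterations)
    done = 0
    while done < n_iterations:
        n = min(batch, n_iterations - done)
        # uniform subset per row via the order statistics of iid uniforms
        keys = rng.random((n, n_rows, n_cols))
        order = np.argsort(keys, axis=2)
        b = np.zeros((n, n_rows, n_cols), dtype=np.float64)
        idx = np.arange(n)[:, None]
        for i, k in enumerate(row_sums):
            if k:
                b[idx, i, order[:, i, :k]] = 1.0
        s = np.einsum("nik,njk->nij", b, b)
        cu = (row_sums[None, :, None] - s) * (row_sums[None, None, :] - s)
        out[done : done + n] = cu[:, iu[0], iu[1]].mean(axis=1)
        done += n
    return out


def run_null_model(
    matrix: PresenceAbsenceMatrix, config: NullModelConfig
) -> NullModelResult:
    """Observed C-score versus its fixed-equiprobable null distribution.

    Fully reproducible from ``config.seed``; identical config gives an
    identical result.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DegenerateMatrixError(f"matrix too small for testing: {matrix.shape}")
    observed = c_score(matrix)
    rng = np.random.default_rng(config.seed)
    null = _null_c_scores(matrix.data, config.n_iterations, rng)
    n = config.n_iterations
    p_low = (int((null <= observed + _EPS).sum()) + 1) / (n + 1)
    p_high = (int((null >= observed - _EPS).sum()) + 1) / (n + 1)
    if p_low < config.alpha:
        pattern = "aggregated"
    elif p_high < config.alpha:
        pattern = "segregated"
    else:
        pattern = "random"
    return NullModelResult(
        observed_c_score=observed,
        null_mean=float(null.mean()),
        null_variance=float(null.var()),
        p_low=p_low,
        p_high=p_high,
        n_iterations=n,
        seed=config.seed,
        pattern=pattern,
        alpha=config.alpha,
    )


def exact_null_tails(
    matrix: PresenceAbsenceMatrix | np.ndarray, max_outcomes: int = 2_000_000
) -> tuple[float, float]:
    """Exact tail probabilities P(C <= observed), P(C >= observed) by full
    enumeration of the fixed-equiprobable outcome space.

    Feasible only for small matrices: the outcome space is the product over
    rows of C(n_cols, r_i) equally likely placements.
    """
    data = matrix.data if isinstance(matrix, PresenceAbsenceMatrix) else np.asarray(matrix)
    n_rows, n_cols = data.shape
    row_sums = data.sum(axis=1).astype(int)
    total = math.prod(math.comb(n_cols, int(k)) for k in row_sums)
    if total > max_outcomes:
        raise ValueError(f"outcome space too large to enumerate ({total})")
    placements = [
        [np.array(c, dtype=int) for c in itertools.combinations(range(n_cols), int(k))]
        for k in row_sums
    ]
    observed = c_score(data)
    n_le = n_ge = 0
    for combo in itertools.product(*placements):
        m = np.zeros((n_rows, n_cols), dtype=np.uint8)
        for i, cols in enumerate(combo):
            m[i, cols] = 1
        c = c_score(m)
        if c <= observed + _EPS:
            n_le += 1
        if c >= observed - _EPS:
            n_ge += 1
    return n_le / total, n_ge / total
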