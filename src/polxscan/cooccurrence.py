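"""Contingency tables over genome summaries and the Pearson chi-square test.

The analytic test is implemented directly (statistic from observed/expected
counts, upper-tail probability via the regularized upper incomplete gamma
function) and is cross-checked in the test suite both against
``scipy.stats.chi2_contingency`` and against the seeded permutation test
provided here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc

from .errors import DegenerateTableError
from .genomes import GenomeSummary, NHEJ_STATUSES, POLX_STATUSES

logger = logging.getLogger(__name__)

BOTH_POLICIES = ("exclude", "as_altered", "as_canonical", "own_row")


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label/count shape mismatch")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def _resolve_status(summary: GenomeSummary, var: str, both_policy: str) -> str | None:
    if var == "polx":
        status = summary.polx_status
        if status == "both":
            if both_policy == "exclude":
                return None
            if both_policy == "as_altered":
                return "altered"
            if both_policy == "as_canonical":
                return "canonical"
            return "both"
        return status
    if var == "nhej":
        return summary.nhej_status
    raise ValueError(f"unknown variable {var!r}; expected 'polx' or 'nhej'")


def build_contingency(
    summaries: list[GenomeSummary],
    row_var: str = "polx",
    col_var: str = "nhej",
    both_policy: str = "exclude",
    drop_empty: bool = True,
) -> ContingencyTable:
    """Cross-classify genomes by two status variables.

    Each genome contributes exactly one count; genomes with polx_status
    'both' are handled per ``both_policy`` (excluded by default).  Category
    levels with zero marginal are dropped when ``drop_empty`` and recorded
    on the returned table.
    """
    if not summaries:
        raise ValueError("no genome summaries given")
    if both_policy not in BOTH_POLICIES:
        raise ValueError(f"both_policy must be one of {BOTH_POLICIES}")

    def levels(var):
        base = list(POLX_STATUSES) if var == "polx" else list(NHEJ_STATUSES)
        if var == "polx" and both_policy != "own_row":
            base.remove("both")
        return base

    rows, cols = levels(row_var), levels(col_var)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for s in summaries:
        r = _resolve_status(s, row_var, both_policy)
        c = _resolve_status(s, col_var, both_policy)
        if r is None or c is None:
            continue
        counts[rows.index(r), cols.index(c)] += 1

    dropped_rows = dropped_cols = ()
    if drop_empty:
        keep_r = counts.sum(axis=1) > 0
        keep_c = counts.sum(axis=0) > 0
        dropped_rows = tuple(l for l, k in zip(rows, keep_r) if not k)
        dropped_cols = tuple(l for l, k in zip(cols, keep_c) if not k)
        if dropped_rows or dropped_cols:
            logger.info("dropping empty categories: rows=%s cols=%s", dropped_rows, dropped_cols)
        counts = counts[np.ix_(keep_r, keep_c)]
        rows = [l for l, k in zip(rows, keep_r) if k]
        cols = [l for l, k in zip(cols, keep_c) if k]

    return ContingencyTable(
        row_labels=tuple(rows),
        col_labels=tuple(cols),
        counts=counts,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


def _check_testable(counts: np.ndarray) -> None:
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            f"need at least a 2x2 table for testing, got shape {counts.shape}"
        )
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero marginal in contingency table")


def chi_square_statistic(counts: np.ndarray) -> tuple[float, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, expected


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    The upper-tail p-value is ``Q(df/2, statistic/2)``, the regularized
    upper incomplete gamma function.  A warning flag is set when any
    expected cell is below 5 (the test is still performed).
    """
    _check_testable(table.counts)
    stat, expected = chi_square_statistic(table.counts)
    df = (table.counts.shape[0] - 1) * (table.counts.shape[1] - 1)
    p = float(gammaincc(df / 2.0, stat / 2.0))
    return ChiSquareResult(
        statistic=stat,
        df=df,
        p_value=p,
        expected=expected,
        low_expected_warning=bool((expected < 5).any()),
    )


def permutation_p(table: ContingencyTable, n_perm: int = 20000, seed: int = 0) -> float:
    """Monte-Carlo permutation p-value for independence.

    Reconstructs the paired row/column label lists from the counts, shuffles
    the column labels ``n_perm`` times with a seeded generator and applies
    the add-one estimator ``(1 + #{stat_perm >= stat_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    _check_testable(table.counts)
    counts = table.counts
    n_rows, n_cols = counts.shape
    stat_obs, _ = chi_square_statistic(counts)

    row_labels = np.repeat(
        np.arange(n_rows), counts.sum(axis=1)
    )  # fixed margin
    col_labels = np.concatenate(
        [np.repeat(np.arange(n_cols), counts[i]) for i in range(n_rows)]
    )
    rng = np.random.default_rng(seed)
    n_ge = 0
    # tolerance guards against ties lost to float round-off
    eps = 1e-9 * max(stat_obs, 1.0)
    for _ in range(n_perm):
        perm = rng.permutation(col_labels)
        perm_counts = np.bincount(
            row_labels * n_cols + perm, minlength=n_rows * n_cols
        ).reshape(n_rows, n_cols)
        stat, _ = chi_square_statistic(perm_counts)
        if stat >= stat_obs - eps:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


def enrichment_report(
    summaries: list[GenomeSummary],
    group_by: str | None = "taxon_class",
    min_group_size: int = 1,
    both_policy: str = "exclude",
) -> list[dict]:
    """Per-group NHEJ-status proportions within each PolX-status group.

    Rows are produced for the pooled dataset (group 'all') and, when
    ``group_by`` names a taxon attribute, for each taxon group; groups with
    fewer than ``min_group_size`` genomes are suppressed.
    """
    groups: dict[str, list[GenomeSummary]] = {"all": list(summaries)}
    if group_by:
        for s in summaries:
            key = getattr(s, group_by)
            if key:
                groups.setdefault(key, []).append(s)

    rows = []
    for group in sorted(groups, key=lambda g: (g != "all", g)):
        members = groups[group]
        if len(members) < min_group_size:
            continue
        by_polx: dict[str, list[GenomeSummary]] = {}
        for s in members:
            status = _resolve_status(s, "polx", both_policy)
            if status is None:
                continue
            by_polx.setdefault(status, []).append(s)
        for polx_status in sorted(by_polx):
            cell = by_polx[polx_status]
            n = len(cell)
            for nhej_status in NHEJ_STATUSES:
                k = sum(1 for s in cell if s.nhej_status == nhej_status)
                rows.append(
                    {
                        "group": group,
                        "polx_status": polx_status,
                        "nhej_status": nhej_status,
                        "n_genomes": n,
                        "n_with_status": k,
                        "percent": 100.0 * k / n,
                    }
                )
    return rows


def genome_length_comparison(summaries: list[GenomeSummary]) -> list[dict]:
    """n / mean / median genome length per (nhej_status, PolX presence) cell.

    Summaries without a genome_length are excluded (count logged).
    """
    with_length = [s for s in summaries if s.genome_length is not None]
    n_missing = len(summaries) - len(with_length)
    if n_missing:
        logger.warning("%d genomes lack genome_length and were excluded", n_missing)
    rows = []
    for nhej_status in NHEJ_STATUSES:
        for polx_presence in ("polx_absent", "polx_present"):
            want_polx = polx_presence == "polx_present"
            cell = [
                s.genome_length
                for s in with_length
                if s.nhej_status == nhej_status and (s.polx_status != "none") == want_polx
            ]
            if not cell:
                continue
            arr = np.asarray(cell, dtype=float)
            rows.append(
                {
                    "nhej_status": nhej_status,
                    "polx": polx_presence,
                    "n": len(cell),
                    "mean_length": float(arr.mean()),
                    "median_length": float(np.median(arr)),
                }
            )
    return rows
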