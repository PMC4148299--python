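"""Nonparametric pipeline comparisons: Friedman omnibus and Nemenyi post-hoc.

Pipelines are repeated measures within each block (voxels for t/ICC
comparisons, subjects for violation-proportion comparisons), so treatments
are compared by within-block ranks. The Friedman chi-square uses average
ranks for ties with the standard tie-correction factor; the all-pairs Nemenyi
test compares mean ranks against the studentized-range distribution, which
controls the family-wise error over the pairwise comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchedStatMatrix",
    "FriedmanResult",
    "ComparisonSummary",
    "friedman",
    "nemenyi",
    "compare_pipelines",
]


@dataclass
class MatchedStatMatrix:
    """Blocks x treatments matrix of one matched statistic."""

    values: np.ndarray
    treatments: list
    block_kind: str = "voxel"       # "voxel" | "subject"
    stat_kind: str = "t_value"      # "t_value" | "icc" | "violation_proportion"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expected a blocks x treatments matrix")
        n, k = self.values.shape
        if k < 2:
            raise ValueError("need at least two treatments")
        if n < 2:
            raise ValueError("need at least two blocks")
        if len(self.treatments) != k:
            raise ValueError("treatment labels must match the column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed")


@dataclass
class FriedmanResult:
    chi_square: float
    df: int
    p_value: float
    mean_ranks: pd.Series


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, MatchedStatMatrix):
        return matrix.values, list(matrix.treatments)
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2 or values.shape[0] < 2:
        raise ValueError("expected a blocks x treatments matrix with k >= 2, n >= 2")
    return values, [f"treatment_{j + 1}" for j in range(values.shape[1])]


def friedman(matrix) -> FriedmanResult:
    """Tie-corrected Friedman rank test over matched treatments.

    chi^2 = 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2 / C with the
    standard tie-correction C = 1 - sum(t^3 - t) / (n k (k^2 - 1)); df = k-1.
    Identical columns give chi^2 = 0, p = 1.
    """
    values, treatments = _as_matrix(matrix)
    n, k = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    mean_ranks = ranks.mean(axis=0)
    s = n * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    tie_sum = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k ** 2 - 1.0))
    if correction <= 0:  # every block fully tied
        chi2, p = 0.0, 1.0
    else:
        chi2 = 12.0 * s / (k * (k + 1.0)) / correction
        p = float(stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(
        chi_square=float(chi2),
        df=k - 1,
        p_value=p,
        mean_ranks=pd.Series(mean_ranks, index=treatments, name="mean_rank"),
    )


def nemenyi(matrix) -> pd.DataFrame:
    """All-pairs Nemenyi test on Friedman mean ranks.

    The pairwise statistic is the mean-rank difference divided by
    sqrt(k (k+1) / (6 n)), referred to the studentized range distribution
    (times sqrt 2) with k groups and infinite df. Returns a symmetric k x k
    p-value table with a unit diagonal.
    """
    values, treatments = _as_matrix(matrix)
    n, k = values.shape
    if k < 3:
        raise ValueError("Nemenyi post-hoc requires at least three treatments")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1.0) / (6.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    q = diff / se * np.sqrt(2.0)
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=treatments, columns=treatments)


@dataclass
class ComparisonSummary:
    """Ordered result of one pipeline comparison."""

    stat_kind: str
    block_kind: str
    n_blocks: int
    friedman: FriedmanResult
    nemenyi_p: pd.DataFrame | None
    note: str = ""
    alpha: float = 0.05
    pairwise_decisions: dict = field(default_factory=dict)

    @property
    def ranking(self) -> list:
        """Treatments from lowest to highest mean rank."""
        return list(self.friedman.mean_ranks.sort_values().index)

    def to_json(self) -> str:
        payload = {
            "stat_kind": self.stat_kind,
            "block_kind": self.block_kind,
            "n_blocks": self.n_blocks,
            "chi_square": self.friedman.chi_square,
            "df": self.friedman.df,
            "p_value": self.friedman.p_value,
            "mean_ranks": self.friedman.mean_ranks.to_dict(),
            "nemenyi_p": (
                None if self.nemenyi_p is None
                else {f"{a}|{b}": float(self.nemenyi_p.loc[a, b])
                      for a in self.nemenyi_p.index for b in self.nemenyi_p.columns
                      if a < b}
            ),
            "pairwise_decisions": self.pairwise_decisions,
            "note": self.note,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def __str__(self) -> str:
        f = self.friedman
        lines = [
            f"Friedman test on {self.stat_kind} "
            f"({self.n_blocks} {self.block_kind} blocks): "
            f"chi2({f.df}) = {f.chi_square:.2f}, p = {f.p_value:.3g}",
            "mean ranks: "
            + ", ".join(f"{t}={r:.2f}" for t, r in f.mean_ranks.items()),
        ]
        if self.note:
            lines.append(self.note)
        return "\n".join(lines)


def compare_pipelines(
    stats_by_pipeline: dict,
    stat_kind: str,
    block_kind: str = "voxel",
    alpha: float = 0.05,
) -> ComparisonSummary:
    """Friedman + Nemenyi comparison of per-pipeline matched statistics.

    ``stats_by_pipeline`` maps pipeline name to a 1D array of per-block values
    (per-voxel t or ICC within a shared ROI, or per-subject violation
    proportions); all arrays must be matched element-for-element.
    """
    names = list(stats_by_pipeline)
    if len(names) < 2:
        raise ValueError("need at least two pipelines to compare")
    arrays = [np.asarray(stats_by_pipeline[n], dtype=float).ravel() for n in names]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(
            "pipelines were not computed on identical geometry: block counts "
            f"{dict(zip(names, (a.shape[0] for a in arrays)))}"
        )
    matrix = MatchedStatMatrix(
        values=np.column_stack(arrays),
        treatments=names,
        block_kind=block_kind,
        stat_kind=stat_kind,
    )
    omnibus = friedman(matrix)
    if len(names) >= 3:
        pairwise = nemenyi(matrix)
        note = ""
        decisions = {
            f"{a}|{b}": bool(pairwise.loc[a, b] < alpha)
            for i, a in enumerate(names) for b in names[i + 1:]
        }
    else:
        pairwise = None
        note = "Nemenyi post-hoc skipped: fewer than three pipelines"
        decisions = {}
    return ComparisonSummary(
        stat_kind=stat_kind,
        block_kind=block_kind,
        n_blocks=matrix.values.shape[0],
        friedman=omnibus,
        nemenyi_p=pairwise,
        note=note,
        alpha=alpha,
        pairwise_decisions=decisions,
    )
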