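"""Somitogenesis-period estimation from boundary-formation times.

Somites form rhythmically; the time at which each boundary appears is
linear in somite index, and the slope of that line is the somitogenesis
period of the embryo.  Periods are estimated per embryo by ordinary
least squares, normalized within each experimental batch to the mean of
the control (wildtype) population, pooled, and compared between
genotypes with a two-tailed Mann-Whitney U test; group means carry
normal-approximation 95% confidence intervals.

Input is a TSV with columns embryo_id, batch, genotype, somite_index,
time_min; the genotype column may be withheld until after fitting to
support analysis blind to genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeriodEstimate",
    "fit_period",
    "fit_all_periods",
    "normalize_periods",
    "compare_groups",
    "GroupComparison",
    "read_boundary_tsv",
]

REQUIRED_COLUMNS = ("embryo_id", "batch", "somite_index", "time_min")


@dataclass(frozen=True)
class PeriodEstimate:
    """Per-embryo somitogenesis period (minutes per somite) and, after
    normalization, the dimensionless period relative to the batch
    control mean."""

    embryo_id: str
    genotype: str
    batch: str
    period_min: float
    normalized_period: float = float("nan")


def fit_period(somite_index, time_min, embryo_id: str = "?") -> float:
    """OLS slope of boundary-formation time (minutes) on somite index.

    Requires at least three boundaries and strictly increasing times in
    index order (a non-monotone series indicates an annotation error and
    is rejected with the embryo id).
    """
    idx = np.asarray(somite_index, dtype=float)
    t = np.asarray(time_min, dtype=float)
    if idx.size < 3:
        raise ValueError(f"embryo {embryo_id}: need >= 3 boundaries, got {idx.size}")
    order = np.argsort(idx)
    idx, t = idx[order], t[order]
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            f"embryo {embryo_id}: formation times not strictly increasing in "
            "somite index"
        )
    res = stats.linregress(idx, t)
    return float(res.slope)


def fit_all_periods(table: pd.DataFrame) -> list[PeriodEstimate]:
    """Fit one period per embryo of a boundary table.

    The genotype column is optional at this stage (blind analysis):
    estimates then carry an empty genotype that can be merged in later.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"boundary table lacks column(s) {sorted(missing)}")
    blind = "genotype" not in table.columns
    out = []
    for (embryo, batch), sub in table.groupby(["embryo_id", "batch"], sort=False):
        genotype = "" if blind else str(sub["genotype"].iloc[0])
        out.append(
            PeriodEstimate(
                embryo_id=str(embryo),
                genotype=genotype,
                batch=str(batch),
                period_min=fit_period(
                    sub["somite_index"], sub["time_min"], embryo_id=str(embryo)
                ),
            )
        )
    return out


def normalize_periods(
    estimates: list[PeriodEstimate], control_group: str = "wildtype"
) -> list[PeriodEstimate]:
    """Divide each period by the mean control period of its batch.

    Normalization is per experimental batch, so day-to-day temperature
    or staging differences cancel before pooling.  Every batch must
    contain at least one control embryo.
    """
    control_mean: dict[str, float] = {}
    for batch in {e.batch for e in estimates}:
        ctrl = [
            e.period_min
            for e in estimates
            if e.batch == batch and e.genotype == control_group
        ]
        if not ctrl:
            raise ValueError(
                f"batch {batch!r} has no {control_group!r} control embryos; "
                "cannot normalize"
            )
        control_mean[batch] = float(np.mean(ctrl))
    return [
        replace(e, normalized_period=e.period_min / control_mean[e.batch])
        for e in estimates
    ]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: Mann-Whitney p-value plus each group's mean
    and normal-approximation 95% confidence interval."""

    p_value: float
    mean_a: float
    ci_a: tuple[float, float]
    mean_b: float
    ci_b: tuple[float, float]
    n_a: int
    n_b: int
    method: str


def _ci95(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    half = 1.96 * float(np.std(x, ddof=1)) / np.sqrt(x.size) if x.size > 1 else 0.0
    return (m - half, m + half)


def compare_groups(a, b, value: str = "normalized_period") -> GroupComparison:
    """Two-tailed Mann-Whitney U test between two groups of estimates
    (or raw number sequences).

    The exact null distribution is enumerated when the smaller group has
    at most 8 observations and the data are tie-free; otherwise the
    normal approximation with tie correction is used.  Each group needs
    at least 3 observations.
    """
    def _values(group):
        seq = list(group)
        if seq and hasattr(seq[0], value):
            return np.array([getattr(e, value) for e in seq], dtype=float)
        return np.asarray(seq, dtype=float)

    xa = _values(a)
    xb = _values(b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs n >= 3")
    has_ties = np.unique(np.concatenate([xa, xb])).size < xa.size + xb.size
    if min(xa.size, xb.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return GroupComparison(
        p_value=float(res.pvalue),
        mean_a=float(np.mean(xa)),
        ci_a=_ci95(xa),
        mean_b=float(np.mean(xb)),
        ci_b=_ci95(xb),
        n_a=int(xa.size),
        n_b=int(xb.size),
        method=method,
    )


def read_boundary_tsv(path) -> pd.DataFrame:
    """Read a boundary table (TSV: embryo_id, batch, genotype,
    somite_index, time_min)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: boundary TSV lacks column(s) {sorted(missing)}")
    return df
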