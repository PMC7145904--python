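"""Compartment-level expression statistics.

qPCR relative expression via the delta-delta-Ct scheme (target Ct
internally normalised to an endogenous 18S-style reference, then expressed
as fold change over the control-group mean), group summaries as mean ± SEM,
and two-tailed Mann-Whitney U tests.  For small samples the Mann-Whitney p
is exact: the U distribution is enumerated over all C(n1+n2, n1) labelings
of the observed (possibly tied) pooled values with midranks, and the
two-sided p is twice the smaller tail probability, capped at 1.  Larger
samples fall back to the usual normal approximation with tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

GROUPS = ("CTRL", "LPS", "LPS_ADA")

#: exact enumeration is used when n1 + n2 does not exceed this
DEFAULT_EXACT_LIMIT = 12

_TOL = 1e-9


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: target and reference-gene Ct for a sample."""

    sample_id: str
    group: str
    target_gene: str
    ct_target: float
    ct_ref: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_ref"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise DomainError(f"sample {self.sample_id}: missing {name}")
            if not 0.0 < v < 45.0:
                raise DomainError(
                    f"sample {self.sample_id}: {name}={v} outside (0, 45)")


@dataclass(frozen=True)
class FoldChangeRecord:
    """Reference-normalised expression and its fold over the control mean."""

    sample_id: str
    group: str
    target_gene: str
    rel_expr: float        # 2^-(ct_target - ct_ref)
    fold_over_control: float


def relative_expression(
    records: Sequence[CtRecord],
    calibrator_group: str = "CTRL",
) -> list[FoldChangeRecord]:
    """Delta-delta-Ct fold changes per target gene.

    rel = 2^-(ct_target - ct_ref); fold = rel / mean(rel over the calibrator
    group), computed per gene, so the calibrator-group mean fold is exactly 1.
    Amplification efficiency is fixed at 2 (no efficiency correction).
    """
    by_gene: dict[str, list[CtRecord]] = {}
    for r in records:
        by_gene.setdefault(r.target_gene, []).append(r)
    out: list[FoldChangeRecord] = []
    for gene, recs in by_gene.items():
        rel = {id(r): 2.0 ** (-(r.ct_target - r.ct_ref)) for r in recs}
        cal = [rel[id(r)] for r in recs if r.group == calibrator_group]
        if not cal:
            raise DomainError(f"gene {gene}: calibrator group "
                              f"{calibrator_group!r} is empty")
        cal_mean = sum(cal) / len(cal)
        out.extend(
            FoldChangeRecord(r.sample_id, r.group, r.target_gene,
                             rel[id(r)], rel[id(r)] / cal_mean)
            for r in recs
        )
    return out


def ct_records_from_frame(df: pd.DataFrame) -> list[CtRecord]:
    """Build CtRecords from the Ct TSV dialect (one row per well)."""
    required = {"sample_id", "group", "target_gene", "ct_target", "ct_ref"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"Ct table missing columns {sorted(missing)}")
    return [CtRecord(str(r.sample_id), str(r.group), str(r.target_gene),
                     float(r.ct_target), float(r.ct_ref))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """A two-group comparison: U statistic, two-sided p, group summaries."""

    group1: str
    group2: str
    n1: int
    n2: int
    u_statistic: float
    p_value: float
    mean1: float
    sem1: float | None
    mean2: float
    sem2: float | None
    method: str  # 'exact' or 'asymptotic'
    significant: bool
    low_n: bool


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    labels: tuple[str, str] = ("x", "y"),
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test, exact for small samples.

    With n1 + n2 <= ``exact_limit`` the p value is computed by enumerating
    the U distribution over every C(n1+n2, n1) assignment of the pooled
    observed values (midranks for ties):
    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).
    Beyond the limit, scipy's tie-corrected normal approximation is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DomainError("both groups must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_from_ranks(float(ranks[:n1].sum()), n1)

    n = n1 + n2
    if n <= exact_limit:
        method = "exact"
        total = math.comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            u = _u_from_ranks(float(ranks[list(idx)].sum()), n1)
            if u <= u_obs + _TOL:
                le += 1
            if u >= u_obs - _TOL:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        p = float(res.pvalue)

    # smallest attainable two-sided p given the group sizes
    min_p = 2.0 / math.comb(n, n1)
    sem = lambda v: (float(np.std(v, ddof=1) / math.sqrt(len(v)))
                     if len(v) > 1 else None)
    return GroupComparison(
        group1=labels[0], group2=labels[1], n1=n1, n2=n2,
        u_statistic=float(u_obs), p_value=p,
        mean1=float(x.mean()), sem1=sem(x),
        mean2=float(y.mean()), sem2=sem(y),
        method=method, significant=p <= alpha,
        low_n=min_p > alpha,
    )


def unpaired_ttest(
    x: Sequence[float], y: Sequence[float],
    *, labels: tuple[str, str] = ("x", "y"), alpha: float = 0.05,
) -> GroupComparison:
    """Unpaired two-sided t test in the same result shape (optional route)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("t test needs >= 2 values per group")
    res = sps.ttest_ind(x, y)
    sem = lambda v: float(np.std(v, ddof=1) / math.sqrt(len(v)))
    return GroupComparison(labels[0], labels[1], len(x), len(y),
                           float(res.statistic), float(res.pvalue),
                           float(x.mean()), sem(x), float(y.mean()), sem(y),
                           "ttest", float(res.pvalue) <= alpha, False)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def group_summary(
    values: Mapping[str, Sequence[float]],
    *,
    alpha: float = 0.05,
    test: str = "mannwhitney",
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Mean ± SEM per group plus all pairwise comparisons.

    SEM is sd/sqrt(n) (None for n = 1).  Comparisons use the exact
    Mann-Whitney test by default (``test='ttest'`` switches, where group
    sizes allow); pairs are flagged significant at p <= ``alpha`` and low-n
    when the sizes cannot reach ``alpha`` at all.
    """
    if test not in ("mannwhitney", "ttest"):
        raise DomainError("test must be 'mannwhitney' or 'ttest'")
    rows = []
    for group, vals in values.items():
        v = np.asarray(list(vals), dtype=float)
        if len(v) == 0:
            raise DomainError(f"group {group!r} is empty")
        sem = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else None
        rows.append((group, len(v), float(v.mean()), sem))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])

    comparisons: list[GroupComparison] = []
    names = list(values)
    for g1, g2 in combinations(names, 2):
        if test == "ttest":
            comparisons.append(unpaired_ttest(values[g1], values[g2],
                                              labels=(g1, g2), alpha=alpha))
        else:
            comparisons.append(mann_whitney_exact(values[g1], values[g2],
                                                  labels=(g1, g2),
                                                  alpha=alpha))
    return summary, comparisons


def fold_change_summary(
    folds: Sequence[FoldChangeRecord],
    *,
    alpha: float = 0.05,
    test: str = "mannwhitney",
) -> dict[str, tuple[pd.DataFrame, list[GroupComparison]]]:
    """Per-gene group summary of delta-delta-Ct fold changes."""
    by_gene: dict[str, dict[str, list[float]]] = {}
    for r in folds:
        by_gene.setdefault(r.target_gene, {}).setdefault(r.group, []).append(
            r.fold_over_control)
    return {gene: group_summary(groups, alpha=alpha, test=test)
            for gene, groups in by_gene.items()}
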