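"""Negative-binomial differential expression and the TNF-dependence partition.

The differential-expression stage is a transparent desk-scale NB Wald test:
median-of-ratios size factors, method-of-moments dispersion, and a Wald
statistic on the log2 fold change of normalised group means with a
delta-method standard error.  It deliberately omits dispersion shrinkage,
GLM covariates and LFC shrinkage — it is a substitution for, not a
re-implementation of, a full DE engine.

Downstream, LPS-induced genes (baseMean > 10, fold change >= 4, adjusted
p < 0.05) are partitioned by their Adalimumab-vs-LPS fold change into
TNF-dependent (attenuated >= 1.5-fold), TNF-independent (within the open
(1/1.5, 1.5) band) and further-upregulated classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EstimationError

LN2 = math.log(2.0)

CLASSES = ("induced_dependent", "induced_independent",
           "induced_upregulated", "not_induced")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDERecord:
    """Per-gene inputs of the trichotomy: baseMean, LPS contrast, ADA ratio."""

    gene_id: str
    base_mean: float
    log2fc_lps_ctrl: float
    padj_lps_ctrl: float
    fc_ada_lps: float  # linear fold change Adalimumab vs LPS (> 0)


@dataclass(frozen=True)
class TrichotomyThresholds:
    """Gene-partition thresholds.

    induced: baseMean > ``base_mean_min`` (strict), LPS fold >=
    ``induce_fc_min`` (inclusive), adjusted p < ``padj_max`` (strict; set
    ``padj_max=None`` to drop the significance requirement).  Among induced:
    dependent when the ADA/LPS ratio falls to 1/``suppress_fold`` or below
    (inclusive), upregulated at ``suppress_fold`` or above (inclusive),
    independent in the open band between.
    """

    base_mean_min: float = 10.0
    induce_fc_min: float = 4.0
    suppress_fold: float = 1.5
    padj_max: float | None = 0.05

    def __post_init__(self) -> None:
        if self.base_mean_min <= 0 or self.induce_fc_min <= 0:
            raise DomainError("thresholds must be positive")
        if self.suppress_fold <= 1.0:
            raise DomainError("suppress_fold must exceed 1")
        if self.padj_max is not None and not 0.0 < self.padj_max <= 1.0:
            raise DomainError("padj_max must lie in (0, 1]")


@dataclass(frozen=True)
class TNFClassification:
    gene_id: str
    gene_class: str

    def __post_init__(self) -> None:
        if self.gene_class not in CLASSES:
            raise DomainError(f"unknown class {self.gene_class!r}")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median, over genes with nonzero counts in
    every sample, of the ratio of the sample's count to the gene's
    geometric mean across samples.
    """
    if counts.shape[1] < 2:
        raise DomainError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise EstimationError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined — filter samples or provide factors explicitly")
    logs = np.log(mat[all_positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean exactly 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _group_columns(conditions: pd.Series, counts: pd.DataFrame,
                   level: str) -> list[str]:
    cols = [c for c in counts.columns if conditions.get(c) == level]
    if len(cols) < 2:
        raise DomainError(f"condition {level!r} needs >= 2 samples, "
                          f"found {len(cols)}")
    return cols


def pooled_moment_dispersion(norm: np.ndarray,
                             groups: Sequence[np.ndarray]) -> float:
    """Across-gene method-of-moments NB dispersion.

    Within-group sample variances satisfy E[s^2] = mu + alpha * mu^2; pooling
    the excess variance over genes and groups,
    alpha = sum_g (s^2 - m) / sum_g m^2, clipped at zero.
    """
    num = 0.0
    den = 0.0
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += float(np.sum(s2 - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _per_gene_moment_dispersion(norm: np.ndarray,
                                groups: Sequence[np.ndarray]) -> np.ndarray:
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += s2 - m
        den += m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, 0.0)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def nb_differential_test(
    counts: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    contrast: tuple[str, str],
    *,
    size_factors: pd.Series | None = None,
    dispersion: str = "pooled",
    dispersion_floor: float = 1e-8,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB Wald differential expression for one contrast (A vs B).

    Counts are normalised by median-of-ratios size factors (estimated over
    all samples unless provided); the log2 fold change is computed on group
    means of normalised counts with ``pseudocount`` added to both means.
    The Wald SE comes from the NB variance mu + alpha*mu^2 via the delta
    method; dispersion is method-of-moments, either pooled across genes
    (default — precise at small n) or per gene (``dispersion='per-gene'``),
    floored at ``dispersion_floor``.  P values are two-sided normal, with
    Benjamini-Hochberg adjustment across genes.

    Returns a DataFrame indexed by gene with columns baseMean, mean_a,
    mean_b, log2fc, lfc_se, stat, pvalue, padj.
    """
    conditions = pd.Series(dict(conditions))
    a, b = contrast
    for level in (a, b):
        if level not in set(conditions.values):
            raise DomainError(f"contrast condition {level!r} absent from the "
                              "condition map")
    cols_a = _group_columns(conditions, counts, a)
    cols_b = _group_columns(conditions, counts, b)

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm_df = counts / size_factors
    norm = norm_df.to_numpy(dtype=float)
    base_mean = norm.mean(axis=1)

    ia = [counts.columns.get_loc(c) for c in cols_a]
    ib = [counts.columns.get_loc(c) for c in cols_b]
    group_idx = [np.array(ia), np.array(ib)]

    if dispersion == "pooled":
        alpha = np.full(norm.shape[0],
                        max(pooled_moment_dispersion(norm, group_idx),
                            dispersion_floor))
    elif dispersion == "per-gene":
        alpha = np.maximum(_per_gene_moment_dispersion(norm, group_idx),
                           dispersion_floor)
    else:
        raise DomainError("dispersion must be 'pooled' or 'per-gene'")

    m_a = norm[:, ia].mean(axis=1)
    m_b = norm[:, ib].mean(axis=1)
    n_a, n_b = len(ia), len(ib)
    ma_p = m_a + pseudocount
    mb_p = m_b + pseudocount
    log2fc = np.log2(ma_p) - np.log2(mb_p)

    # Var(log2 mean) ~= (mu + alpha mu^2) / (n mu^2 ln2^2) per group
    var_log2 = ((ma_p + alpha * ma_p**2) / (n_a * ma_p**2)
                + (mb_p + alpha * mb_p**2) / (n_b * mb_p**2)) / LN2**2
    se = np.sqrt(var_log2)
    stat = np.where(log2fc == 0.0, 0.0, log2fc / se)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.minimum(pvalue, 1.0)
    padj = stats.false_discovery_control(pvalue, method="bh")

    return pd.DataFrame(
        {"baseMean": base_mean, "mean_a": m_a, "mean_b": m_b,
         "log2fc": log2fc, "lfc_se": se, "stat": stat,
         "pvalue": pvalue, "padj": padj},
        index=counts.index,
    )


def build_de_records(
    counts: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    *,
    dispersion: str = "pooled",
    pseudocount: float = 0.5,
) -> list[GeneDERecord]:
    """Run the two study contrasts and assemble trichotomy inputs per gene.

    Contrast 1: LPS vs CTRL (log2 fold change and adjusted p); contrast 2:
    LPS_ADA vs LPS (linear fold change).  baseMean is the mean of
    normalised counts over all samples of all groups.
    """
    conditions = pd.Series(dict(conditions))
    sf = estimate_size_factors(counts)
    lps = nb_differential_test(counts, conditions, ("LPS", "CTRL"),
                               size_factors=sf, dispersion=dispersion,
                               pseudocount=pseudocount)
    ada = nb_differential_test(counts, conditions, ("LPS_ADA", "LPS"),
                               size_factors=sf, dispersion=dispersion,
                               pseudocount=pseudocount)
    return [
        GeneDERecord(
            gene_id=str(g),
            base_mean=float(lps.at[g, "baseMean"]),
            log2fc_lps_ctrl=float(lps.at[g, "log2fc"]),
            padj_lps_ctrl=float(lps.at[g, "padj"]),
            fc_ada_lps=float(2.0 ** ada.at[g, "log2fc"]),
        )
        for g in counts.index
    ]


# ---------------------------------------------------------------------------
# TNF-dependence trichotomy
# ---------------------------------------------------------------------------

def classify_tnf_dependence(
    records: Sequence[GeneDERecord],
    thresholds: TrichotomyThresholds = TrichotomyThresholds(),
) -> list[TNFClassification]:
    """Partition genes into the four TNF-dependence classes.

    A gene is LPS-induced when baseMean > base_mean_min, its linear LPS/CTRL
    fold change reaches induce_fc_min (inclusive) and — unless disabled —
    padj < padj_max.  Induced genes are TNF-dependent when the ADA/LPS fold
    change is at most 1/suppress_fold (boundary inclusive toward
    dependence), upregulated at suppress_fold or above, independent in the
    open band between.  Every gene receives exactly one class.
    """
    t = thresholds
    out: list[TNFClassification] = []
    for r in records:
        for name in ("base_mean", "log2fc_lps_ctrl", "padj_lps_ctrl",
                     "fc_ada_lps"):
            v = getattr(r, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise DomainError(f"gene {r.gene_id}: missing field {name}")
        if r.fc_ada_lps <= 0:
            raise DomainError(f"gene {r.gene_id}: fc_ada_lps must be > 0")
        induced = (
            r.base_mean > t.base_mean_min
            and 2.0 ** r.log2fc_lps_ctrl >= t.induce_fc_min
            and (t.padj_max is None or r.padj_lps_ctrl < t.padj_max)
        )
        if not induced:
            cls = "not_induced"
        elif r.fc_ada_lps <= 1.0 / t.suppress_fold:
            cls = "induced_dependent"
        elif r.fc_ada_lps >= t.suppress_fold:
            cls = "induced_upregulated"
        else:
            cls = "induced_independent"
        out.append(TNFClassification(r.gene_id, cls))
    return out


@dataclass(frozen=True)
class PartitionSummary:
    """Class counts and the fraction of induced genes that are TNF-dependent."""

    counts: dict[str, int]
    total: int
    induced_total: int
    dependent_fraction: float | None


def summarize_partition(
    classifications: Sequence[TNFClassification],
) -> PartitionSummary:
    """Counts per class; dependent fraction among induced (None if none)."""
    if not classifications:
        raise DomainError("no classifications to summarise")
    counts = {c: 0 for c in CLASSES}
    for c in classifications:
        counts[c.gene_class] += 1
    induced = (counts["induced_dependent"] + counts["induced_independent"]
               + counts["induced_upregulated"])
    frac = counts["induced_dependent"] / induced if induced else None
    return PartitionSummary(counts, len(classifications), induced, frac)
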