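"""Maternal/fetal origin inference from informative SNPs in RNA-seq pileups.

The procedure mirrors the genotype-divergence analysis used to establish the
origin of chorio-decidua neutrophils: genotypes are called per site from the
maternal reference sample (blood neutrophils) and the fetal reference sample
(fetal lung), sites where the two calls diverge in highly expressed genes
are retained as informative SNPs, and a query sample's per-SNP nucleotide
frequencies are summarised into a maximum-likelihood estimate of its
maternal read fraction f under a binomial mixture model:

    alt reads at a SNP  ~  Binomial(depth, p'(f)),
    p(f)  = f * g_m + (1 - f) * g_f,
    p'(f) = p(f) * (1 - e) + (1 - p(f)) * e / 3,

with g_m, g_f the maternal and fetal alt-allele dosages and e the per-read
substitution error rate.  The likelihood is maximised on a grid over [0, 1];
the 95% CI is the profile-likelihood interval (drop of 1.92 log units).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import rankdata

from .errors import DomainError, EstimationError
from .synthetic import BASES, SitePileup

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int]


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """A per-site genotype call from read counts.

    ``call_type`` is 'hom' (one allele), 'het' (two), or 'ambiguous' (low
    depth or no clean diploid pattern).  ``major_freq`` is the frequency of
    the most frequent base (0 when depth is 0).
    """

    site: SiteKey
    call_type: str
    alleles: tuple[str, ...]
    major_freq: float
    depth: int


def call_genotype(pileup: SitePileup, min_depth: int = 20,
                  hom_threshold: float = 0.9,
                  het_band: float = 0.2) -> GenotypeCall:
    """Call hom/het/ambiguous from a site pileup.

    hom if the major base reaches ``hom_threshold`` (inclusive); het if the
    two most frequent bases each reach ``het_band`` and jointly reach
    ``hom_threshold``; otherwise — or below ``min_depth`` — ambiguous.
    """
    if not het_band < 0.5 < hom_threshold <= 1.0:
        raise DomainError("thresholds must satisfy het_band < 0.5 < "
                          "hom_threshold <= 1")
    counts = np.asarray(pileup.counts, dtype=float)
    depth = int(counts.sum())
    key = pileup.key
    if depth == 0:
        return GenotypeCall(key, "ambiguous", (), 0.0, 0)
    order = np.argsort(-counts, kind="stable")
    freqs = counts / depth
    major_freq = float(freqs[order[0]])
    if depth < min_depth:
        return GenotypeCall(key, "ambiguous", (), major_freq, depth)
    if major_freq >= hom_threshold:
        return GenotypeCall(key, "hom", (BASES[order[0]],), major_freq, depth)
    top2 = freqs[order[0]] + freqs[order[1]]
    if freqs[order[0]] >= het_band and freqs[order[1]] >= het_band \
            and top2 >= hom_threshold:
        alleles = tuple(sorted((BASES[order[0]], BASES[order[1]])))
        return GenotypeCall(key, "het", alleles, major_freq, depth)
    return GenotypeCall(key, "ambiguous", (), major_freq, depth)


# ---------------------------------------------------------------------------
# informative-SNP discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InformativeSNP:
    """A site where the maternal and fetal genotype calls diverge."""

    chrom: str
    pos: int
    gene_id: str
    ref: str
    alt: str
    maternal_call: GenotypeCall
    fetal_call: GenotypeCall
    g_m: float
    g_f: float
    expression_rank: float

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class DiscoveryParams:
    """Tunable thresholds of the informative-SNP scan.

    Defaults: genotype calls require depth >= 20 with hom frequency >= 0.9
    and het minor-allele frequency >= 0.2; 'high expression' is the top
    quartile of per-gene mean depth; fewer than ``min_informative`` surviving
    SNPs triggers a warning (the study observed at least 5 per pair).
    """

    min_depth: int = 20
    hom_threshold: float = 0.9
    het_band: float = 0.2
    high_expression_quantile: float = 0.75
    min_informative: int = 5
    error_rate: float = 0.005


def _by_site(pileups: Sequence[SitePileup]) -> dict[SiteKey, SitePileup]:
    return {p.key: p for p in pileups}


def _dosage(call: GenotypeCall, ref: str, alt: str) -> float:
    """Alt-allele dosage implied by a non-ambiguous call."""
    if call.call_type == "hom":
        return 1.0 if call.alleles[0] == alt else 0.0
    return 0.5


def _third_allele_excess(pileup: SitePileup, ref: str, alt: str,
                         error_rate: float) -> bool:
    """True when a base other than ref/alt exceeds 2x the expected error."""
    limit = 2.0 * pileup.depth * error_rate / 3.0
    return any(
        pileup.count(b) > limit for b in BASES if b not in (ref, alt)
    )


def discover_informative_snps(
    maternal: Sequence[SitePileup],
    fetal: Sequence[SitePileup],
    params: DiscoveryParams = DiscoveryParams(),
) -> list[InformativeSNP]:
    """Scan paired pileups for sites divergent between mother and fetus.

    A site is informative when both genotype calls are non-ambiguous, the
    implied dosages differ, both depths reach ``params.min_depth``, and the
    gene's mean depth sits at or above ``params.high_expression_quantile``.
    Sites private to one sample are dropped (logged); bi-allelic violations
    (a third base above twice the expected error count) are dropped too.
    """
    m_by, f_by = _by_site(maternal), _by_site(fetal)
    shared = sorted(set(m_by) & set(f_by))
    dropped = len(set(m_by) ^ set(f_by))
    if dropped:
        logger.info("dropped %d sites private to one sample", dropped)
    if not shared:
        raise DomainError("maternal and fetal pileups share no sites")

    # per-gene mean depth over both samples -> expression percentile
    gene_depths: dict[str, list[int]] = {}
    for key in shared:
        gene = m_by[key].gene_id
        gene_depths.setdefault(gene, []).extend(
            (m_by[key].depth, f_by[key].depth))
    genes = sorted(gene_depths)
    mean_depth = np.array([np.mean(gene_depths[g]) for g in genes])
    ranks = rankdata(mean_depth, method="average") / len(genes)
    gene_rank = dict(zip(genes, ranks))

    out: list[InformativeSNP] = []
    for key in shared:
        mp, fp = m_by[key], f_by[key]
        m_call = call_genotype(mp, params.min_depth, params.hom_threshold,
                               params.het_band)
        f_call = call_genotype(fp, params.min_depth, params.hom_threshold,
                               params.het_band)
        if m_call.call_type == "ambiguous" or f_call.call_type == "ambiguous":
            continue
        alleles = set(m_call.alleles) | set(f_call.alleles)
        alts = alleles - {mp.ref}
        if len(alts) > 1:
            logger.info("dropped multi-allelic site %s:%d", *key)
            continue
        if not alts:  # both hom-ref: no divergence possible
            continue
        alt = alts.pop()
        if _third_allele_excess(mp, mp.ref, alt, params.error_rate) or \
                _third_allele_excess(fp, fp.ref, alt, params.error_rate):
            logger.info("dropped site %s:%d with third-allele excess", *key)
            continue
        g_m = _dosage(m_call, mp.ref, alt)
        g_f = _dosage(f_call, fp.ref, alt)
        if g_m == g_f:
            continue
        rank = float(gene_rank[mp.gene_id])
        if rank < params.high_expression_quantile:
            continue
        out.append(InformativeSNP(mp.chrom, mp.pos, mp.gene_id, mp.ref, alt,
                                  m_call, f_call, g_m, g_f, rank))
    if len(out) < params.min_informative:
        warnings.warn(
            f"only {len(out)} informative SNPs found "
            f"(< {params.min_informative})", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# nucleotide frequencies (the per-SNP profile the origin figure plots)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleotideFrequencyRecord:
    """Per-site base frequencies of one sample at an informative SNP."""

    chrom: str
    pos: int
    sample_label: str
    freqs: tuple[float, float, float, float]  # A, C, G, T
    depth: int


def compute_nucleotide_frequencies(
    query: Sequence[SitePileup],
    snps: Sequence[InformativeSNP],
    label: str,
) -> list[NucleotideFrequencyRecord]:
    """Base count / depth at each informative SNP in the query sample.

    SNP sites missing from the query (or with zero depth) are emitted with
    depth 0 and all-zero frequencies, and reported via a warning.
    """
    q_by = _by_site(query)
    out: list[NucleotideFrequencyRecord] = []
    uncovered = 0
    for snp in snps:
        p = q_by.get(snp.key)
        if p is None or p.depth == 0:
            uncovered += 1
            out.append(NucleotideFrequencyRecord(snp.chrom, snp.pos, label,
                                                 (0.0, 0.0, 0.0, 0.0), 0))
            continue
        freqs = tuple(c / p.depth for c in p.counts)
        out.append(NucleotideFrequencyRecord(snp.chrom, snp.pos, label,
                                             freqs, p.depth))
    if uncovered:
        warnings.warn(f"{uncovered} SNP sites uncovered in sample {label!r}",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# maternal-fraction estimation
# ---------------------------------------------------------------------------

@dataclass
class OriginEstimate:
    """Maximum-likelihood maternal fraction with its profile support."""

    f_hat: float
    grid: np.ndarray = field(repr=False)
    loglik: np.ndarray = field(repr=False)
    ci95: tuple[float, float]
    n_snps: int
    origin_call: str

    @property
    def loglik_profile(self) -> list[tuple[float, float]]:
        return list(zip(self.grid.tolist(), self.loglik.tolist()))


def _origin_label(f_hat: float, maternal_cut: float) -> str:
    # small tolerance so that e.g. f_hat=0.1 at cut 0.9 hits the boundary
    # despite 1 - 0.9 != 0.1 in floating point
    if f_hat >= maternal_cut - 1e-12:
        return "maternal"
    if f_hat <= (1.0 - maternal_cut) + 1e-12:
        return "fetal"
    return "mixed"


def mixture_loglik(grid: np.ndarray, alt: np.ndarray, depth: np.ndarray,
                   g_m: np.ndarray, g_f: np.ndarray,
                   error_rate: float) -> np.ndarray:
    """Summed binomial log-likelihood of the mixture over a grid of f."""
    f = grid[:, None]
    p = f * g_m[None, :] + (1.0 - f) * g_f[None, :]
    p_err = p * (1.0 - error_rate) + (1.0 - p) * error_rate / 3.0
    ll = xlogy(alt[None, :], p_err) + xlogy((depth - alt)[None, :], 1.0 - p_err)
    return ll.sum(axis=1)


def estimate_maternal_fraction(
    query: Sequence[SitePileup],
    snps: Sequence[InformativeSNP],
    error_rate: float = 0.005,
    grid_step: float = 0.001,
    maternal_cut: float = 0.9,
) -> OriginEstimate:
    """Grid maximum-likelihood estimate of the maternal read fraction.

    The 95% CI is the profile-likelihood set {f : logL(f) >= max - 1.92}
    (its extremes); ties at the maximum resolve to the smallest grid f.
    """
    if not snps:
        raise DomainError("need at least one informative SNP")
    if not 0.0 <= error_rate < 0.5:
        raise DomainError("error_rate must lie in [0, 0.5)")
    if not 0.0 < grid_step <= 0.5:
        raise DomainError("grid_step must lie in (0, 0.5]")

    q_by = _by_site(query)
    alt, depth, g_m, g_f = [], [], [], []
    for snp in snps:
        p = q_by.get(snp.key)
        if p is None or p.depth == 0:
            continue
        alt.append(p.count(snp.alt))
        depth.append(p.depth)
        g_m.append(snp.g_m)
        g_f.append(snp.g_f)
    if not alt:
        raise EstimationError("no informative SNP has usable depth in the "
                              "query sample")
    alt_a, depth_a = np.array(alt, float), np.array(depth, float)
    g_m_a, g_f_a = np.array(g_m), np.array(g_f)

    grid = np.arange(0.0, 1.0 + grid_step / 2.0, grid_step)
    grid[-1] = 1.0
    ll = mixture_loglik(grid, alt_a, depth_a, g_m_a, g_f_a, error_rate)
    i_max = int(np.argmax(ll))
    f_hat = float(grid[i_max])
    inside = grid[ll >= ll[i_max] - 1.92]
    ci95 = (float(inside.min()), float(inside.max()))
    return OriginEstimate(f_hat, grid, ll, ci95, len(alt),
                          _origin_label(f_hat, maternal_cut))


def classify_origin(estimate: OriginEstimate,
                    maternal_cut: float = 0.9) -> str:
    """Categorical origin call: maternal / fetal / mixed (idempotent)."""
    if not 0.5 < maternal_cut <= 1.0:
        raise DomainError("maternal_cut must lie in (0.5, 1]")
    return _origin_label(estimate.f_hat, maternal_cut)
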