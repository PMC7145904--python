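"""Synthetic genotypes, pileups and count matrices for the study design.

The generators emulate the data layout of an intrauterine-inflammation
experiment: a mother/father/fetus genotype trio at human-like
heterozygosity, mixed-origin RNA-seq pileups whose allele frequencies
follow a binomial mixture of the maternal and fetal genomes, and
three-condition (Control / LPS / LPS + anti-TNF) negative-binomial count
matrices with planted LPS induction and planted TNF-dependent attenuation.

Every generator is a pure function of its parameters and an integer seed.
Random streams are split per (seed, stream constant, unit index) with
:class:`numpy.random.SeedSequence`, so e.g. adding genes never perturbs the
draws of earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CONDITIONS = ("CTRL", "LPS", "LPS_ADA")

#: planted-set names used throughout the package
PLANTED_SETS = ("induced_dependent", "induced_independent", "induced_upregulated")

# stream constants for seed splitting
_STREAM_PARENTS = 1
_STREAM_FETUS = 2
_STREAM_PILEUP = 3
_STREAM_COUNTS = 4
_STREAM_EXPR = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Generator for an independent substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """A bi-allelic genomic site (1-based position) assigned to one gene."""

    chrom: str
    pos: int
    gene_id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DomainError(f"site {self.chrom}:{self.pos}: ref == alt ({self.ref})")
        for b in (self.ref, self.alt):
            if b not in BASE_INDEX:
                raise DomainError(f"site {self.chrom}:{self.pos}: invalid base {b!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class SitePileup:
    """Per-site A/C/G/T read counts — the atomic input of origin inference."""

    chrom: str
    pos: int
    ref: str
    gene_id: str
    counts: tuple[int, int, int, int]  # A, C, G, T

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise DomainError(
                f"pileup {self.chrom}:{self.pos}: negative count {self.counts}"
            )

    @property
    def depth(self) -> int:
        return int(sum(self.counts))

    def count(self, base: str) -> int:
        return int(self.counts[BASE_INDEX[base]])

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _check_dosages(d: np.ndarray, label: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if not np.isin(d, (0.0, 0.5, 1.0)).all():
        raise DomainError(f"{label}: dosages must be in {{0, 0.5, 1}}")
    return d


def _check_sites(sites: Sequence[Site]) -> None:
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            raise DomainError(
                f"site positions must strictly increase within {s.chrom} "
                f"(pos {s.pos} after {last[s.chrom]})"
            )
        last[s.chrom] = s.pos


@dataclass
class ParentalGenotypes:
    """Mother and father alt-allele dosages over a shared site list."""

    sites: list[Site]
    mother_dosage: np.ndarray
    father_dosage: np.ndarray

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        self.mother_dosage = _check_dosages(self.mother_dosage, "mother_dosage")
        self.father_dosage = _check_dosages(self.father_dosage, "father_dosage")
        n = len(self.sites)
        if len(self.mother_dosage) != n or len(self.father_dosage) != n:
            raise DomainError("dosage arrays must match the site list in length")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class FetalGenotype:
    """Fetal alt-allele dosages, Mendelian-consistent with the parents."""

    sites: list[Site]
    fetus_dosage: np.ndarray

    def __post_init__(self) -> None:
        _check_sites(self.sites)
        self.fetus_dosage = _check_dosages(self.fetus_dosage, "fetus_dosage")
        if len(self.fetus_dosage) != len(self.sites):
            raise DomainError("dosage array must match the site list in length")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated experiment.

    ``maternal_fraction`` is the mixture weight f of the maternal genome in a
    query sample; ``seq_error`` the per-read substitution probability;
    ``expression_levels`` a per-gene relative abundance (mean 1 across genes)
    that scales both pileup depth and count-matrix baselines.
    """

    maternal_fraction: float = 1.0
    seq_error: float = 0.005
    mean_depth: float = 50.0
    expression_levels: dict[str, float] = field(default_factory=dict)
    planted_gene_sets: dict[str, set[str]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maternal_fraction <= 1.0:
            raise DomainError("maternal_fraction must lie in [0, 1]")
        if not 0.0 <= self.seq_error <= 0.05:
            raise DomainError("seq_error must lie in [0, 0.05]")
        if self.mean_depth <= 0:
            raise DomainError("mean_depth must be positive")
        if self.nb_dispersion <= 0:
            raise DomainError("nb_dispersion must be positive")
        if any(v <= 0 for v in self.expression_levels.values()):
            raise DomainError("expression levels must be positive")
        if any(v <= 0 for v in self.effect_sizes.values()):
            raise DomainError("effect sizes must be positive")
        sets = [self.planted_gene_sets.get(k, set()) for k in PLANTED_SETS]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise DomainError("planted gene sets must be disjoint")


# default fold-change parameters for the planted sets: LPS vs CTRL induction
# and the Adalimumab-vs-LPS ratio applied on top of it
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "lps_fold": 6.0,            # induction of every planted-induced gene
    "ada_fold_dependent": 1 / 3.0,   # TNF-dependent: attenuated below LPS
    "ada_fold_independent": 1.0,     # TNF-independent: unchanged vs LPS
    "ada_fold_upregulated": 2.0,     # further up under anti-TNF
}


def make_truth(
    gene_ids: Sequence[str],
    seed: int,
    *,
    maternal_fraction: float = 1.0,
    seq_error: float = 0.005,
    mean_depth: float = 50.0,
    nb_dispersion: float = 0.05,
    expression_sigma: float = 1.0,
    planted_gene_sets: Mapping[str, set[str]] | None = None,
    effect_sizes: Mapping[str, float] | None = None,
) -> SimTruth:
    """Build a :class:`SimTruth` with log-normal expression levels.

    Relative abundances are log-normal with log-scale sd ``expression_sigma``
    (a typical spread for bulk RNA-seq), normalised to mean 1 so that
    ``mean_depth`` is the across-gene average pileup depth.
    """
    rng = _rng(seed, _STREAM_EXPR)
    levels = rng.lognormal(mean=-expression_sigma**2 / 2, sigma=expression_sigma,
                           size=len(gene_ids))
    levels = levels / levels.mean()
    planted = {k: set(v) for k, v in (planted_gene_sets or {}).items()}
    known = set(gene_ids)
    for name, members in planted.items():
        unknown = members - known
        if unknown:
            raise DomainError(f"planted set {name!r} references unknown genes: "
                              f"{sorted(unknown)[:5]}")
    return SimTruth(
        maternal_fraction=maternal_fraction,
        seq_error=seq_error,
        mean_depth=mean_depth,
        expression_levels=dict(zip(gene_ids, levels.tolist())),
        planted_gene_sets=planted,
        effect_sizes=dict(effect_sizes or DEFAULT_EFFECT_SIZES),
        nb_dispersion=nb_dispersion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def simulate_parental_genotypes(
    n_genes: int,
    gene_length: int,
    het_rate: float,
    seed: int,
    *,
    alt_freq: float = 0.3,
) -> ParentalGenotypes:
    """Simulate mother and father genotypes over polymorphic sites.

    Each gene is a ``gene_length``-bp window on one chromosome; the number of
    polymorphic sites per gene is Binomial(gene_length, het_rate), and each
    parent's alt-allele dosage at a site is drawn independently under
    Hardy-Weinberg equilibrium at population alt frequency ``alt_freq``.
    """
    if n_genes < 1:
        raise DomainError("n_genes must be >= 1")
    if gene_length < 1:
        raise DomainError("gene_length must be >= 1")
    if not 0.0 <= het_rate < 0.1:
        raise DomainError("het_rate must lie in [0, 0.1)")
    if not 0.0 < alt_freq < 1.0:
        raise DomainError("alt_freq must lie in (0, 1)")

    q = alt_freq
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    dosage_values = np.array([0.0, 0.5, 1.0])

    sites: list[Site] = []
    mother: list[float] = []
    father: list[float] = []
    width = max(4, len(str(n_genes)))
    for g in range(n_genes):
        rng = _rng(seed, _STREAM_PARENTS, g)
        n_sites = int(rng.binomial(gene_length, het_rate))
        if n_sites == 0:
            continue
        gene_id = f"G{g + 1:0{width}d}"
        start = g * gene_length
        positions = np.sort(
            rng.choice(gene_length, size=n_sites, replace=False)
        )
        for pos in positions:
            ref_i = int(rng.integers(4))
            alt_i = int((ref_i + 1 + rng.integers(3)) % 4)
            sites.append(Site("chr1", start + int(pos) + 1, gene_id,
                              BASES[ref_i], BASES[alt_i]))
            mother.append(float(rng.choice(dosage_values, p=hw)))
            father.append(float(rng.choice(dosage_values, p=hw)))

    return ParentalGenotypes(sites, np.array(mother), np.array(father))


def simulate_fetal_genotype(parents: ParentalGenotypes, seed: int) -> FetalGenotype:
    """Transmit one maternal and one paternal allele uniformly at random."""
    if len(parents) == 0:
        raise DomainError("parents must carry at least one site")
    rng = _rng(seed, _STREAM_FETUS)
    # a parent's dosage equals the probability of transmitting the alt allele
    m_allele = rng.random(len(parents)) < parents.mother_dosage
    p_allele = rng.random(len(parents)) < parents.father_dosage
    fetus = (m_allele.astype(float) + p_allele.astype(float)) / 2.0
    return FetalGenotype(list(parents.sites), fetus)


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------

def simulate_pileups(
    sites: Sequence[Site],
    dosages_or_mixture: np.ndarray | tuple[np.ndarray, np.ndarray, float],
    truth: SimTruth,
    seed: int,
) -> list[SitePileup]:
    """Simulate per-site read pileups from one genome or a two-genome mixture.

    ``dosages_or_mixture`` is either a single dosage array (a pure sample) or
    a ``(maternal_dosages, fetal_dosages, f)`` triple, in which case the
    expected alt-read fraction is the mixture p = f*g_m + (1-f)*g_f.  Reads
    carry a substitution error ``truth.seq_error`` spread uniformly over the
    three wrong bases, so the observed alt fraction is
    p' = p(1-e) + (1-p)e/3.  Depth at a site is Poisson with mean
    ``truth.mean_depth`` times the gene's relative expression level.
    """
    if isinstance(dosages_or_mixture, tuple):
        g_m, g_f, f = dosages_or_mixture
        if not 0.0 <= float(f) <= 1.0:
            raise DomainError("mixture fraction f must lie in [0, 1]")
        p = float(f) * np.asarray(g_m, float) + (1.0 - float(f)) * np.asarray(g_f, float)
    else:
        p = np.asarray(dosages_or_mixture, dtype=float)
    if len(p) != len(sites):
        raise DomainError("dosage array must match the site list in length")

    eps = truth.seq_error
    out: list[SitePileup] = []
    for i, site in enumerate(sites):
        rng = _rng(seed, _STREAM_PILEUP, i)
        weight = truth.expression_levels.get(site.gene_id, 1.0)
        depth = int(rng.poisson(truth.mean_depth * weight))
        probs = np.full(4, eps / 3.0)
        probs[BASE_INDEX[site.alt]] = p[i] * (1 - eps) + (1 - p[i]) * eps / 3.0
        probs[BASE_INDEX[site.ref]] = (1 - p[i]) * (1 - eps) + p[i] * eps / 3.0
        counts = rng.multinomial(depth, probs)
        out.append(SitePileup(site.chrom, site.pos, site.ref, site.gene_id,
                              tuple(int(c) for c in counts)))
    return out


# ---------------------------------------------------------------------------
# count-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    """A gene × sample count table plus its sample → condition map."""

    counts: pd.DataFrame
    conditions: pd.Series


def simulate_count_matrix(
    truth: SimTruth,
    n_per_group: int,
    seed: int,
    *,
    base_mean: float = 100.0,
    size_factor_sigma: float = 0.15,
) -> SimulatedCounts:
    """Simulate NB counts for Control / LPS / LPS+Adalimumab groups.

    Per-gene baselines are ``base_mean`` scaled by the gene's relative
    expression level; planted induced genes receive the configured LPS fold
    change in both LPS groups, with the Adalimumab-vs-LPS ratio applied on
    top in the LPS_ADA group.  Counts are NB with dispersion
    ``truth.nb_dispersion`` around mean = baseline × condition effect ×
    sample size factor (log-normal, geometric mean 1).
    """
    if n_per_group < 2:
        raise DomainError("n_per_group must be >= 2")
    genes = list(truth.expression_levels)
    if not genes:
        raise DomainError("truth carries no genes (empty expression_levels)")
    known = set(genes)
    for name, members in truth.planted_gene_sets.items():
        unknown = set(members) - known
        if unknown:
            raise DomainError(f"planted set {name!r} references unknown genes: "
                              f"{sorted(unknown)[:5]}")

    eff = {**DEFAULT_EFFECT_SIZES, **truth.effect_sizes}
    lps_mult = np.ones(len(genes))
    ada_mult = np.ones(len(genes))  # relative to LPS
    idx = {g: i for i, g in enumerate(genes)}
    ada_key = {"induced_dependent": "ada_fold_dependent",
               "induced_independent": "ada_fold_independent",
               "induced_upregulated": "ada_fold_upregulated"}
    for set_name in PLANTED_SETS:
        for g in truth.planted_gene_sets.get(set_name, ()):
            lps_mult[idx[g]] = eff["lps_fold"]
            ada_mult[idx[g]] = eff[ada_key[set_name]]

    cond_mult = {
        "CTRL": np.ones(len(genes)),
        "LPS": lps_mult,
        "LPS_ADA": lps_mult * ada_mult,
    }

    rng = _rng(seed, _STREAM_COUNTS)
    n_samples = 3 * n_per_group
    size_factors = rng.lognormal(mean=0.0, sigma=size_factor_sigma, size=n_samples)
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    baseline = base_mean * np.array([truth.expression_levels[g] for g in genes])
    alpha = truth.nb_dispersion
    columns: dict[str, np.ndarray] = {}
    sample_cond: dict[str, str] = {}
    j = 0
    for cond in CONDITIONS:
        for r in range(n_per_group):
            name = f"{cond}_{r + 1}"
            mu = baseline * cond_mult[cond] * size_factors[j]
            # NB(mean mu, var mu + alpha mu^2) via numpy's (n, p) parametrisation
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            columns[name] = rng.negative_binomial(n_param, p_param)
            sample_cond[name] = cond
            j += 1

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    conditions = pd.Series(sample_cond, name="condition")
    return SimulatedCounts(counts, conditions)


def make_count_truth(
    n_genes: int,
    seed: int,
    *,
    n_dependent: int = 60,
    n_independent: int = 20,
    n_upregulated: int = 5,
    nb_dispersion: float = 0.05,
    effect_sizes: Mapping[str, float] | None = None,
    expression_sigma: float = 1.0,
) -> SimTruth:
    """Truth object for a count simulation with planted gene classes.

    The first genes in id order are assigned to the dependent / independent /
    upregulated sets respectively; the remainder are null.
    """
    n_planted = n_dependent + n_independent + n_upregulated
    if n_planted > n_genes:
        raise DomainError("planted sets exceed the number of genes")
    width = max(4, len(str(n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    planted = {
        "induced_dependent": set(genes[:n_dependent]),
        "induced_independent": set(genes[n_dependent:n_dependent + n_independent]),
        "induced_upregulated": set(genes[n_dependent + n_independent:n_planted]),
    }
    return make_truth(genes, seed, nb_dispersion=nb_dispersion,
                      planted_gene_sets=planted, effect_sizes=effect_sizes,
                      expression_sigma=expression_sigma)


# ---------------------------------------------------------------------------
# qPCR Ct-table simulation
# ---------------------------------------------------------------------------

def simulate_ct_table(
    target_genes: Sequence[str],
    n_per_group: int,
    seed: int,
    *,
    lps_delta_ct: float = -4.0,
    ada_delta_ct: float = -2.0,
    noise_sd: float = 0.5,
    ref_ct: float = 12.0,
    base_ct: float = 26.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table (18S-style reference) for the three groups.

    LPS shifts target Ct by ``lps_delta_ct`` cycles (negative = induction);
    the anti-TNF group sits at ``ada_delta_ct``.  Gaussian noise ``noise_sd``
    is added per well.  Returns the Ct TSV dialect as a DataFrame.
    """
    rng = _rng(seed, 6)
    shift = {"CTRL": 0.0, "LPS": lps_delta_ct, "LPS_ADA": ada_delta_ct}
    rows = []
    for cond in CONDITIONS:
        for r in range(n_per_group):
            sample = f"{cond}_{r + 1}"
            for gene in target_genes:
                ct_t = base_ct + shift[cond] + rng.normal(0.0, noise_sd)
                ct_r = ref_ct + rng.normal(0.0, 0.1)
                rows.append((sample, cond, gene, round(ct_t, 3), round(ct_r, 3)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "target_gene",
                                       "ct_target", "ct_ref"])
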