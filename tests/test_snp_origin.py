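"""Genotype calling, informative-SNP discovery and origin estimation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decidecon import snp_origin as so, synthetic as sy
from decidecon.errors import DomainError, EstimationError
from conftest import flat_pileup


# ---------------------------------------------------------------------------
# call_genotype
# ---------------------------------------------------------------------------

class TestCallGenotype:
    @pytest.mark.parametrize("counts, expected_type, expected_alleles", [
        ((30, 0, 0, 0), "hom", ("A",)),        # clean homozygote
        ((15, 0, 15, 0), "het", ("A", "G")),   # balanced heterozygote
        ((27, 0, 3, 0), "hom", ("A",)),        # major_freq 0.9, inclusive hom
        ((10, 0, 0, 0), "ambiguous", ()),      # below min_depth
        ((20, 8, 8, 4), "ambiguous", ()),      # no clean diploid pattern
        ((0, 0, 0, 0), "ambiguous", ()),       # zero depth
    ])
    def test_call_types(self, counts, expected_type, expected_alleles):
        call = so.call_genotype(flat_pileup(counts), min_depth=20)
        assert call.call_type == expected_type
        assert call.alleles == expected_alleles

    def test_major_freq_consistent_with_counts(self):
        call = so.call_genotype(flat_pileup((30, 0, 10, 0)), min_depth=20)
        assert call.major_freq == pytest.approx(0.75)
        assert call.depth == 40

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(DomainError):
            so.call_genotype(flat_pileup((30, 0, 0, 0)), hom_threshold=0.4)

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            flat_pileup((-1, 0, 0, 0))

    @given(counts=st.tuples(*[st.integers(0, 200)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_call_is_exhaustive_and_consistent(self, counts):
        call = so.call_genotype(flat_pileup(counts), min_depth=20)
        assert call.call_type in ("hom", "het", "ambiguous")
        if call.call_type == "hom":
            assert len(call.alleles) == 1 and call.major_freq >= 0.9
        elif call.call_type == "het":
            assert len(set(call.alleles)) == 2


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

class TestDiscovery:
    def test_identical_samples_yield_no_snps(self, reference_pileups):
        maternal, _ = reference_pileups
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert so.discover_informative_snps(maternal, maternal) == []

    def test_forced_single_site(self):
        # mother hom A (ref), fetus het A/G, top-rank gene
        maternal = [flat_pileup((40, 0, 0, 0), pos=10, gene="G0001"),
                    flat_pileup((40, 0, 0, 0), pos=20, gene="G0002")]
        fetal = [flat_pileup((20, 0, 20, 0), pos=10, gene="G0001"),
                 flat_pileup((38, 0, 0, 0), pos=20, gene="G0002")]
        snps = so.discover_informative_snps(
            maternal, fetal,
            so.DiscoveryParams(high_expression_quantile=0.0,
                               min_informative=1))
        assert len(snps) == 1
        snp = snps[0]
        assert (snp.chrom, snp.pos) == ("chr1", 10)
        assert snp.g_m == 0.0 and snp.g_f == 0.5
        assert snp.ref == "A" and snp.alt == "G"

    def test_trio_pair_reaches_observed_floor(self, reference_pileups):
        # a synthetic mother-fetus pair at study-like settings recovers at
        # least the five informative SNPs seen per animal pair
        maternal, fetal = reference_pileups
        snps = so.discover_informative_snps(maternal, fetal)
        assert len(snps) >= 5

    def test_every_returned_snp_satisfies_all_predicates(
            self, reference_pileups):
        maternal, fetal = reference_pileups
        params = so.DiscoveryParams()
        snps = so.discover_informative_snps(maternal, fetal, params)
        m_by = {p.key: p for p in maternal}
        f_by = {p.key: p for p in fetal}
        for snp in snps:
            assert snp.g_m != snp.g_f
            assert snp.maternal_call.call_type != "ambiguous"
            assert snp.fetal_call.call_type != "ambiguous"
            assert m_by[snp.key].depth >= params.min_depth
            assert f_by[snp.key].depth >= params.min_depth
            assert snp.expression_rank >= params.high_expression_quantile

    def test_snps_sorted_by_position(self, reference_pileups):
        snps = so.discover_informative_snps(*reference_pileups)
        keys = [snp.key for snp in snps]
        assert keys == sorted(keys)

    def test_disjoint_sites_rejected(self):
        a = [flat_pileup((30, 0, 0, 0), pos=1)]
        b = [flat_pileup((30, 0, 0, 0), pos=2)]
        with pytest.raises(DomainError, match="share no sites"):
            so.discover_informative_snps(a, b)

    def test_shortfall_warns_not_raises(self):
        maternal = [flat_pileup((40, 0, 0, 0), pos=10)]
        fetal = [flat_pileup((20, 0, 20, 0), pos=10)]
        with pytest.warns(UserWarning, match="informative SNPs"):
            snps = so.discover_informative_snps(
                maternal, fetal,
                so.DiscoveryParams(high_expression_quantile=0.0))
        assert len(snps) == 1

    def test_third_allele_excess_dropped(self):
        # 6 reads of C on top of an A/G site: far above 2x expected error
        maternal = [flat_pileup((40, 6, 0, 0), pos=10)]
        fetal = [flat_pileup((20, 0, 26, 0), pos=10)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            snps = so.discover_informative_snps(
                maternal, fetal,
                so.DiscoveryParams(high_expression_quantile=0.0))
        assert snps == []


# ---------------------------------------------------------------------------
# nucleotide frequencies
# ---------------------------------------------------------------------------

def _one_snp(pos=10, gene="G0001", g_m=1.0, g_f=0.5, ref="A", alt="G"):
    call_m = so.GenotypeCall(("chr1", pos), "hom", (alt,), 1.0, 40)
    call_f = so.GenotypeCall(("chr1", pos), "het", (ref, alt), 0.5, 40)
    return so.InformativeSNP("chr1", pos, gene, ref, alt, call_m, call_f,
                             g_m, g_f, 1.0)


class TestNucleotideFrequencies:
    def test_frequencies_are_counts_over_depth(self):
        query = [flat_pileup((30, 0, 10, 0), pos=10)]
        rec, = so.compute_nucleotide_frequencies(query, [_one_snp()], "cd")
        assert rec.freqs == (0.75, 0.0, 0.25, 0.0)
        assert rec.depth == 40 and rec.sample_label == "cd"

    def test_frequencies_sum_to_one_when_covered(self, reference_pileups):
        maternal, fetal = reference_pileups
        snps = so.discover_informative_snps(maternal, fetal)
        for rec in so.compute_nucleotide_frequencies(maternal, snps, "mat"):
            if rec.depth > 0:
                assert math.isclose(sum(rec.freqs), 1.0, abs_tol=1e-9)

    def test_uncovered_site_emitted_with_zero_depth_and_flagged(self):
        query = [flat_pileup((0, 0, 0, 0), pos=10)]
        with pytest.warns(UserWarning, match="uncovered"):
            rec, = so.compute_nucleotide_frequencies(query, [_one_snp()], "q")
        assert rec.depth == 0 and rec.freqs == (0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# maternal-fraction estimation
# ---------------------------------------------------------------------------

def brute_force_mle(alt, depth, g_m, g_f, error_rate, step=1e-4):
    """Independent fine-grid oracle using plain-python likelihood sums."""
    best_f, best_ll = 0.0, -math.inf
    n_steps = int(round(1.0 / step))
    for i in range(n_steps + 1):
        f = i * step
        ll = 0.0
        for k, n, gm, gf in zip(alt, depth, g_m, g_f):
            p = f * gm + (1 - f) * gf
            p = p * (1 - error_rate) + (1 - p) * error_rate / 3
            if k > 0:
                if p == 0.0:
                    ll = -math.inf
                    break
                ll += k * math.log(p)
            if n - k > 0:
                if p == 1.0:
                    ll = -math.inf
                    break
                ll += (n - k) * math.log(1 - p)
        if ll > best_ll:
            best_f, best_ll = f, ll
    return best_f


def _mixture_pileups(parents, fetus, truth, f, seed):
    return sy.simulate_pileups(
        parents.sites, (parents.mother_dosage, fetus.fetus_dosage, f),
        truth, seed)


class TestEstimateMaternalFraction:
    def test_pure_maternal_error_free_limit(self):
        # with no sequencing error the pure-source likelihood peaks at f = 1
        parents = sy.simulate_parental_genotypes(100, 1500, 1e-3, seed=2)
        fetus = sy.simulate_fetal_genotype(parents, seed=2)
        genes = sorted({s.gene_id for s in parents.sites})
        truth = sy.make_truth(genes, seed=2, seq_error=0.0, mean_depth=60.0)
        maternal = sy.simulate_pileups(parents.sites, parents.mother_dosage,
                                       truth, 21)
        fetal = sy.simulate_pileups(parents.sites, fetus.fetus_dosage,
                                    truth, 22)
        snps = so.discover_informative_snps(
            maternal, fetal, so.DiscoveryParams(error_rate=0.0))
        query_m = _mixture_pileups(parents, fetus, truth, 1.0, 23)
        est = so.estimate_maternal_fraction(query_m, snps, error_rate=0.0)
        assert est.f_hat == 1.0 and est.origin_call == "maternal"
        query_f = _mixture_pileups(parents, fetus, truth, 0.0, 24)
        est = so.estimate_maternal_fraction(query_f, snps, error_rate=0.0)
        assert est.f_hat == 0.0 and est.origin_call == "fetal"

    def test_closed_form_half_fraction(self):
        # 10 sites (g_m=0.5, g_f=0), depth 100, 25 alt reads -> f = 0.50
        snps = [_one_snp(pos=i + 1, g_m=0.5, g_f=0.0) for i in range(10)]
        query = [flat_pileup((75, 0, 25, 0), pos=i + 1) for i in range(10)]
        est = so.estimate_maternal_fraction(query, snps, error_rate=0.0)
        assert abs(est.f_hat - 0.5) <= 0.001

    def test_grid_ml_matches_brute_force_oracle(self, trio, trio_truth,
                                                reference_pileups):
        parents, fetus = trio
        snps = so.discover_informative_snps(*reference_pileups)[:12]
        for f_true, seed in [(0.2, 31), (0.6, 32), (0.9, 33)]:
            query = _mixture_pileups(parents, fetus, trio_truth, f_true, seed)
            est = so.estimate_maternal_fraction(query, snps,
                                                error_rate=0.005)
            q_by = {p.key: p for p in query}
            alt = [q_by[s.key].count(s.alt) for s in snps]
            depth = [q_by[s.key].depth for s in snps]
            oracle = brute_force_mle(alt, depth, [s.g_m for s in snps],
                                     [s.g_f for s in snps], 0.005)
            assert abs(est.f_hat - oracle) <= 0.001 + 1e-9

    def test_symmetry_under_role_swap(self, trio, trio_truth,
                                      reference_pileups):
        parents, fetus = trio
        snps = so.discover_informative_snps(*reference_pileups)
        swapped = [so.InformativeSNP(s.chrom, s.pos, s.gene_id, s.ref, s.alt,
                                     s.fetal_call, s.maternal_call,
                                     s.g_f, s.g_m, s.expression_rank)
                   for s in snps]
        query = _mixture_pileups(parents, fetus, trio_truth, 0.7, 41)
        est = so.estimate_maternal_fraction(query, snps, error_rate=0.005)
        est_swap = so.estimate_maternal_fraction(query, swapped,
                                                 error_rate=0.005)
        assert est.f_hat + est_swap.f_hat == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_simulated_fraction(self, trio, trio_truth,
                                            reference_pileups):
        parents, fetus = trio
        snps = so.discover_informative_snps(*reference_pileups)
        estimates = []
        for f_true in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = [
                so.estimate_maternal_fraction(
                    _mixture_pileups(parents, fetus, trio_truth, f_true,
                                     100 + rep),
                    snps, error_rate=0.005).f_hat
                for rep in range(5)
            ]
            estimates.append(np.mean(vals))
        assert all(b >= a for a, b in zip(estimates, estimates[1:]))

    def test_ci_contains_point_estimate(self, trio, trio_truth,
                                        reference_pileups):
        parents, fetus = trio
        snps = so.discover_informative_snps(*reference_pileups)
        query = _mixture_pileups(parents, fetus, trio_truth, 0.5, 51)
        est = so.estimate_maternal_fraction(query, snps, error_rate=0.005)
        assert est.ci95[0] <= est.f_hat <= est.ci95[1]
        assert est.n_snps == len(snps)

    def test_zero_depth_everywhere_is_estimation_error(self):
        snps = [_one_snp()]
        query = [flat_pileup((0, 0, 0, 0), pos=10)]
        with pytest.raises(EstimationError):
            so.estimate_maternal_fraction(query, snps)

    def test_no_snps_rejected(self):
        with pytest.raises(DomainError):
            so.estimate_maternal_fraction([], [])


class TestClassifyOrigin:
    @pytest.mark.parametrize("f_hat, expected", [
        (1.0, "maternal"), (0.95, "maternal"), (0.9, "maternal"),
        (0.5, "mixed"), (0.11, "mixed"),
        (0.1, "fetal"), (0.0, "fetal"),
    ])
    def test_thresholds(self, f_hat, expected):
        est = so.OriginEstimate(f_hat, np.array([f_hat]), np.array([0.0]),
                                (f_hat, f_hat), 5, "mixed")
        assert so.classify_origin(est, maternal_cut=0.9) == expected

    def test_idempotent(self):
        est = so.OriginEstimate(0.97, np.array([0.97]), np.array([0.0]),
                                (0.9, 1.0), 5, "maternal")
        first = so.classify_origin(est)
        assert so.classify_origin(est) == first
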