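import numpy as np
import pytest

from decidecon import synthetic as sy


@pytest.fixture(scope="session")
def trio():
    """A simulated mother/father/fetus trio at human-like heterozygosity."""
    parents = sy.simulate_parental_genotypes(200, 1500, 1e-3, seed=1)
    fetus = sy.simulate_fetal_genotype(parents, seed=1)
    return parents, fetus


@pytest.fixture(scope="session")
def trio_truth(trio):
    parents, _ = trio
    genes = sorted({s.gene_id for s in parents.sites})
    return sy.make_truth(genes, seed=1, mean_depth=50.0, seq_error=0.005)


@pytest.fixture(scope="session")
def reference_pileups(trio, trio_truth):
    """Maternal and fetal reference pileups for the trio."""
    parents, fetus = trio
    maternal = sy.simulate_pileups(parents.sites, parents.mother_dosage,
                                   trio_truth, seed=11)
    fetal = sy.simulate_pileups(parents.sites, fetus.fetus_dosage,
                                trio_truth, seed=12)
    return maternal, fetal


def flat_pileup(counts, chrom="chr1", pos=100, ref="A", gene="G0001"):
    """Helper: a SitePileup from an (A, C, G, T) count tuple."""
    return sy.SitePileup(chrom, pos, ref, gene, tuple(int(c) for c in counts))
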