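import numpy as np
import pytest

from ssrgbas import simdata as sd
from ssrgbas.genotyping import GenotypeMatrix


@pytest.fixture(scope="session")
def small_loci():
    return sd.make_tetranucleotide_loci(3, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_loci):
    model = sd.make_pop_model(small_loci, n_pops=2, n_ind_per_pop=5,
                              fst_target=0.1, inbreeding_f=0.0, seed=1)
    freqs = sd.draw_population_allele_freqs(model, seed=2)
    return sd.simulate_genotypes(freqs, model, seed=3)


@pytest.fixture(scope="session")
def clean_reads(small_truth, small_loci):
    cfg = sd.ReadSimConfig(mean_depth=60, base_error_rate=0.0,
                           stutter_prob=0.0, seed=4)
    return sd.simulate_reads(small_truth, small_loci, cfg)


def toy_matrix(genotypes, pop_map, locus="L1"):
    """Build a one-locus GenotypeMatrix from {sample: (a, b)} shorthand."""
    entries = {(s, locus): (None if g is None else tuple(sorted(g)))
               for s, g in genotypes.items()}
    samples = sorted(genotypes)
    return GenotypeMatrix(samples, [locus], entries, pop_map, {})


@pytest.fixture
def hw_matrix():
    """Two populations, one locus, exact HWE proportions within each."""
    genotypes = {
        "a1": ("A", "A"), "a2": ("A", "B"), "a3": ("A", "B"), "a4": ("B", "B"),
        "b1": ("A", "A"), "b2": ("A", "B"), "b3": ("A", "B"), "b4": ("B", "B"),
    }
    pops = {s: ("p1" if s.startswith("a") else "p2") for s in genotypes}
    return toy_matrix(genotypes, pops)
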