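import numpy as np
import pytest

from selfdiv.genotype_io import GeneticMap, PhasedGenotypeMatrix
from selfdiv.synthetic_data import MatingSystemSpec, evolve_population, generate_map


def make_map(markers_per_chrom=(3,), length_cM=50.0) -> GeneticMap:
    ids, chroms, pos = [], [], []
    for c, k in enumerate(markers_per_chrom):
        p = np.linspace(0.0, length_cM, k) if k > 1 else np.array([0.0])
        for j in range(k):
            ids.append(f"chr{c + 1}_m{j + 1}")
            chroms.append(f"chr{c + 1}")
        pos.append(p)
    return GeneticMap(tuple(ids), tuple(chroms), np.concatenate(pos))


def matrix_from_rows(rows, phased=True, length_cM=50.0, markers_per_chrom=None):
    """Build a PhasedGenotypeMatrix from [[(a,b), ...], ...] genotype rows."""
    alleles = np.array(rows, dtype=np.int8)
    m = alleles.shape[1]
    gmap = make_map(markers_per_chrom or (m,), length_cM=length_cM)
    return PhasedGenotypeMatrix(
        individuals=[f"i{k}" for k in range(alleles.shape[0])],
        alleles=alleles,
        phased=phased,
        gmap=gmap,
    )


def random_matrix(n=16, markers_per_chrom=(25, 25), seed=0, missing_rate=0.0, phased=True):
    rng = np.random.default_rng(seed)
    gmap = make_map(markers_per_chrom)
    m = len(gmap)
    p = rng.uniform(0.1, 0.9, size=m)
    alleles = (rng.random((n, m, 2)) < p[None, :, None]).astype(np.int8)
    if missing_rate:
        mask = rng.random((n, m, 2)) < missing_rate
        alleles[mask] = -1
    return PhasedGenotypeMatrix(
        individuals=[f"i{k}" for k in range(n)], alleles=alleles, phased=phased, gmap=gmap
    )


@pytest.fixture(scope="session")
def partial_selfing_sample():
    """16 phased diploids from a population at partial-selfing equilibrium
    (s=0.5), 6 chromosomes x 20 SNPs: the androdioecious-like test sample."""
    spec = MatingSystemSpec(
        selfing_rate=0.5, population_size=500, generations=30,
        markers_per_chromosome=20, burn_in=10,
    )
    sample, truth = evolve_population(spec, seed=20260930)
    return sample, truth


@pytest.fixture(scope="session")
def outcrossing_sample():
    """16 phased diploids from a random-mating population (s=0)."""
    spec = MatingSystemSpec(
        selfing_rate=0.0, population_size=500, generations=20,
        markers_per_chromosome=20, burn_in=10,
    )
    sample, truth = evolve_population(spec, seed=915)
    return sample, truth
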