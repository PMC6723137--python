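"""Synthetic populations, maps and line-extinction records with known truth.

The generator emulates the design of the experimental system: a hybrid
population founded from a pool of distinct haplotypes (default 16, echoing
the 16 parental wild isolates), evolved forward in time under a chosen
selfing rate s — each offspring is produced by selfing with probability s and
by random outcrossing otherwise — on 6 chromosomes of 50 cM genotyped at
evenly spaced SNPs. Meiosis uses the same complete-interference model as the
line-derivation simulator. Optional viability selection (deleterious
recessive, overdominant, or recessive lethals in repulsion) supplies ground
truth for power checks of the drift-only credible intervals.

Known closed-form anchors for validation:

* at neutral mixed-mating equilibrium Fis -> s/(2-s) (0 at s=0, 1/3 at
  s=0.5, 1 at s=1);
* identity disequilibrium g2 > 0 only at intermediate s;
* a constant per-generation extinction hazard gives geometric survival,
  S(t) = (1-hazard)^t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GeneticMap, LineRecord, PhasedGenotypeMatrix
from .selfing_sim import MeiosisModel, gametes_batch

__all__ = [
    "MatingSystemSpec",
    "SelectionSpec",
    "generate_map",
    "founder_haplotype_pool",
    "evolve_population",
    "derive_lines",
    "generate_line_extinctions",
]


@dataclass(frozen=True)
class MatingSystemSpec:
    """Mating-system and genome settings for a forward simulation.

    ``selfing_rate`` is the probability that an offspring is produced by
    self-fertilization; the complement is random outcrossing between two
    distinct parents. Defaults mirror the experimental design: ~1000
    breeders, 50 generations, 6 chromosomes of 50 cM.
    """

    selfing_rate: float
    population_size: int = 1000
    generations: int = 50
    founder_haplotypes: int = 16
    chromosomes: int = 6
    markers_per_chromosome: int = 124
    chromosome_length_cM: float = 50.0
    burn_in: int = 10
    sample_size: int = 16

    def __post_init__(self) -> None:
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing rate must lie in [0, 1]")
        if self.founder_haplotypes < 2:
            raise ValueError("need >= 2 founder haplotypes for polymorphism")


@dataclass(frozen=True)
class SelectionSpec:
    """Viability selection acting on offspring genotypes.

    ``mode='recessive_deleterious'``: fitness 1, 1-h*s', 1-s' for 0/1/2
    copies of the ALT allele at each selected locus. ``mode='overdominant'``:
    heterozygote fitness 1, either homozygote 1-s'. ``mode='repulsion_lethals'``:
    loci are taken pairwise; the ALT allele of the first and the REF allele of
    the second of each pair are deleterious recessives, the repulsion-phase
    arrangement that behaves like overdominance. Fitness is multiplicative
    across loci. s' is written ``coefficient`` (the selfing rate keeps the
    symbol s).
    """

    mode: str = "neutral"
    loci: tuple[int, ...] = ()
    coefficient: float = 0.0
    dominance_h: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "recessive_deleterious", "overdominant", "repulsion_lethals"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not 0.0 <= self.coefficient <= 1.0:
            raise ValueError("selection coefficient must lie in [0, 1]")
        if not 0.0 <= self.dominance_h <= 1.0:
            raise ValueError("dominance h must lie in [0, 1]")
        if self.mode == "repulsion_lethals" and len(self.loci) % 2:
            raise ValueError("repulsion_lethals needs an even number of loci")

    def fitness(self, alleles: np.ndarray) -> np.ndarray:
        """Multiplicative viability of each diploid in (k, m, 2) ``alleles``."""
        k = alleles.shape[0]
        if self.mode == "neutral" or not self.loci:
            return np.ones(k)
        s, h = self.coefficient, self.dominance_h
        loci = np.asarray(self.loci)
        dose = alleles[:, loci, :].sum(axis=2)  # ALT dosage, (k, n_loci)
        if self.mode == "recessive_deleterious":
            w_locus = np.choose(dose, [1.0, 1.0 - h * s, 1.0 - s])
        elif self.mode == "overdominant":
            w_locus = np.where(dose == 1, 1.0, 1.0 - s)
        else:  # repulsion_lethals
            w_first = np.choose(dose[:, 0::2], [1.0, 1.0 - h * s, 1.0 - s])
            w_second = np.choose(2 - dose[:, 1::2], [1.0, 1.0 - h * s, 1.0 - s])
            w_locus = np.concatenate([w_first, w_second], axis=1)
        return w_locus.prod(axis=1)


def generate_map(spec: MatingSystemSpec) -> GeneticMap:
    """Evenly spaced markers over [0, length] cM on each chromosome."""
    ids, chroms, pos = [], [], []
    for c in range(spec.chromosomes):
        name = f"chr{c + 1}"
        k = spec.markers_per_chromosome
        p = np.linspace(0.0, spec.chromosome_length_cM, k) if k > 1 else np.array([0.0])
        for j in range(k):
            ids.append(f"{name}_m{j + 1}")
            chroms.append(name)
        pos.append(p)
    return GeneticMap(
        marker_ids=tuple(ids), chromosomes=tuple(chroms), positions_cM=np.concatenate(pos)
    )


def founder_haplotype_pool(spec: MatingSystemSpec, rng: np.random.Generator) -> np.ndarray:
    """Distinct founder haplotypes, alleles i.i.d. Bernoulli(1/2) per site."""
    n_markers = spec.chromosomes * spec.markers_per_chromosome
    return rng.integers(0, 2, size=(spec.founder_haplotypes, n_markers)).astype(np.int8)


def _offspring_batch(
    pop: np.ndarray,
    gmap: GeneticMap,
    selfing_rate: float,
    n_offspring: int,
    rng: np.random.Generator,
    model: MeiosisModel,
) -> np.ndarray:
    """Produce ``n_offspring`` zygotes from diploid array ``pop`` (N, m, 2)."""
    n = pop.shape[0]
    selfed = rng.random(n_offspring) < selfing_rate
    mothers = rng.integers(0, n, size=n_offspring)
    fathers = rng.integers(0, n, size=n_offspring)
    if n > 1:
        clash = (~selfed) & (fathers == mothers)
        while clash.any():
            fathers[clash] = rng.integers(0, n, size=int(clash.sum()))
            clash = (~selfed) & (fathers == mothers)
    fathers[selfed] = mothers[selfed]
    out = np.empty((n_offspring, pop.shape[1], 2), dtype=pop.dtype)
    for sl in gmap.chromosome_slices().values():
        pos = gmap.positions_cM[sl]
        out[:, sl, 0] = gametes_batch(pop[mothers][:, sl, :], pos, rng, model)
        out[:, sl, 1] = gametes_batch(pop[fathers][:, sl, :], pos, rng, model)
    return out


def evolve_population(
    mating: MatingSystemSpec,
    selection: SelectionSpec = SelectionSpec(),
    seed: int | None = None,
    model: MeiosisModel = MeiosisModel(),
) -> tuple[PhasedGenotypeMatrix, dict]:
    """Forward-simulate a population and return a phased sample plus truth.

    The population is initialised from the founder haplotype pool, run for
    ``mating.burn_in`` generations of random mating (recombining the founder
    haplotypes so realistic linkage structure exists), then for
    ``mating.generations`` generations at the target selfing rate with the
    given viability selection. Offspring are produced in rejection-sampled
    batches: a zygote survives with probability equal to its fitness.

    Returns ``(sample, truth)`` where ``sample`` holds
    ``mating.sample_size`` phased diploids and ``truth`` records the full
    population's allele frequencies, realized Fis and the parameters used.
    """
    rng = np.random.default_rng(seed)
    gmap = generate_map(mating)
    pool = founder_haplotype_pool(mating, rng)
    N = mating.population_size
    pop = pool[rng.integers(0, pool.shape[0], size=(N, 2))].transpose(0, 2, 1)

    neutral = SelectionSpec()
    for gen in range(mating.burn_in + mating.generations):
        in_burn_in = gen < mating.burn_in
        s_rate = 0.0 if in_burn_in else mating.selfing_rate
        sel = neutral if in_burn_in else selection
        survivors: list[np.ndarray] = []
        n_have = 0
        for attempt in range(300):
            batch = _offspring_batch(pop, gmap, s_rate, N, rng, model)
            w = sel.fitness(batch)
            alive = batch[rng.random(N) < w]
            if alive.shape[0]:
                survivors.append(alive)
                n_have += alive.shape[0]
            if n_have >= N:
                break
        else:
            raise RuntimeError(
                f"population went extinct under selection at generation {gen} "
                "(mean viability too low); use a weaker SelectionSpec"
            )
        pop = np.concatenate(survivors)[:N]

    p_truth = pop.sum(axis=(0, 2)) / (2.0 * N)
    he_t = 2.0 * p_truth * (1.0 - p_truth)
    ho_t = (pop[:, :, 0] != pop[:, :, 1]).mean(axis=0)
    informative = he_t >= 0.05
    fis_truth = (
        float(1.0 - ho_t[informative].mean() / he_t[informative].mean())
        if informative.any()
        else float("nan")
    )
    sample_idx = rng.choice(N, size=mating.sample_size, replace=False)
    sample = PhasedGenotypeMatrix(
        individuals=[f"ind{i + 1}" for i in range(mating.sample_size)],
        alleles=pop[sample_idx],
        phased=True,
        gmap=gmap,
    )
    truth = {
        "selfing_rate": mating.selfing_rate,
        "population_size": N,
        "generations": mating.generations,
        "burn_in": mating.burn_in,
        "selection_mode": selection.mode,
        "allele_frequencies": p_truth,
        "Fis": fis_truth,
        "mean_He": float(he_t.mean()),
        "mean_Ho": float(ho_t.mean()),
        "seed": seed,
    }
    return sample, truth


def derive_lines(
    pop: PhasedGenotypeMatrix,
    generations: int,
    n_lines: int,
    seed: int | None = None,
    selection: SelectionSpec = SelectionSpec(),
    brood_size: int = 5,
    max_failures: int = 2,
    population: str = "pop",
    block: str = "B1",
    model: MeiosisModel = MeiosisModel(),
) -> tuple[PhasedGenotypeMatrix, list[LineRecord]]:
    """Derive selfed lines from a sample, with optional viability selection.

    Each line starts from a founder drawn with replacement from ``pop``. Every
    generation, up to ``brood_size`` selfed zygotes are attempted and the
    first that survives viability selection (probability = fitness) continues
    the line; a generation with no survivor is a failed reproduction, and
    ``max_failures`` failures of the same transition (the paper-style "failed
    twice" rule: one backup attempt) make the line extinct at that
    generation. Returns the surviving lines as a phased matrix and the full
    extinction record for every line.
    """
    pop.require_phase("line derivation")
    rng = np.random.default_rng(seed)
    gmap = pop.gmap
    slices = list(gmap.chromosome_slices().values())
    survivors: list[np.ndarray] = []
    names: list[str] = []
    records: list[LineRecord] = []
    neutral = selection.mode == "neutral" or not selection.loci

    founder_idx = rng.integers(0, pop.n_individuals, size=n_lines)
    if neutral:
        # no viability deaths: self all lineages in lock-step, vectorised
        from .selfing_sim import self_lineages_batch

        final = self_lineages_batch(pop.alleles[founder_idx], gmap, generations, rng, model)
        survivors = list(final)
        names = [f"{population}_L{i + 1}" for i in range(n_lines)]
        records = [
            LineRecord(
                line_id=nm, population=population, block=block,
                generations_survived=generations, status="censored",
                assay_length=generations,
            )
            for nm in names
        ]
        lines = PhasedGenotypeMatrix(
            individuals=names, alleles=np.stack(survivors), phased=True, gmap=gmap
        )
        return lines, records

    for i in range(n_lines):
        current = pop.alleles[founder_idx[i]].copy()
        extinct_at: int | None = None
        for gen in range(1, generations + 1):
            ok = False
            for _failure in range(max_failures):
                # a brood of selfed zygotes; the first that survives
                # viability selection continues the line
                brood = np.empty((brood_size,) + current.shape, dtype=current.dtype)
                parents = np.repeat(current[None, :, :], brood_size, axis=0)
                for sl in slices:
                    pos = gmap.positions_cM[sl]
                    brood[:, sl, 0] = gametes_batch(parents[:, sl, :], pos, rng, model)
                    brood[:, sl, 1] = gametes_batch(parents[:, sl, :], pos, rng, model)
                alive = np.flatnonzero(rng.random(brood_size) < selection.fitness(brood))
                if alive.size:
                    current = brood[alive[0]]
                    ok = True
                    break
            if not ok:
                extinct_at = gen
                break
        name = f"{population}_L{i + 1}"
        if extinct_at is None:
            survivors.append(current)
            names.append(name)
            records.append(
                LineRecord(
                    line_id=name, population=population, block=block,
                    generations_survived=generations, status="censored",
                    assay_length=generations,
                )
            )
        else:
            records.append(
                LineRecord(
                    line_id=name, population=population, block=block,
                    generations_survived=extinct_at, status="extinct",
                    assay_length=generations,
                )
            )
    if not survivors:
        raise RuntimeError(
            "every line went extinct during derivation; weaken the SelectionSpec"
        )
    lines = PhasedGenotypeMatrix(
        individuals=names, alleles=np.stack(survivors), phased=True, gmap=gmap
    )
    return lines, records


def generate_line_extinctions(
    n_lines: int,
    hazard: float,
    assay_length: int,
    seed: int | None = None,
    population: str = "pop",
    block: str = "B1",
) -> list[LineRecord]:
    """Line records with a constant per-generation extinction hazard.

    Extinction times are geometric, truncated at ``assay_length``; lines that
    reach the end are censored there. ``hazard=0`` gives all-censored data,
    ``hazard=1`` extinction of every line at generation 1.
    """
    if not 0.0 <= hazard <= 1.0:
        raise ValueError("hazard must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_lines):
        t = None
        for gen in range(1, assay_length + 1):
            if rng.random() < hazard:
                t = gen
                break
        if t is None:
            records.append(
                LineRecord(
                    line_id=f"{population}_L{i + 1}", population=population, block=block,
                    generations_survived=assay_length, status="censored",
                    assay_length=assay_length,
                )
            )
        else:
            records.append(
                LineRecord(
                    line_id=f"{population}_L{i + 1}", population=population, block=block,
                    generations_survived=t, status="extinct", assay_length=assay_length,
                )
            )
    return records
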