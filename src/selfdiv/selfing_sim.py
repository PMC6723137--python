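"""Neutral forward simulation of inbred-line derivation by selfing.

The simulator propagates single-individual selfed lineages (N=1) from a
phased population sample, under the meiosis model used for the study's
genetic map: complete crossover interference (at most one crossover per
chromosome per meiosis), with the crossover probability equal to the
chromosome's map length in Morgans (0.5 for a 50 cM chromosome) and the
crossover placed between two consecutive SNPs with probability proportional
to the genetic distance between them.

``neutral_inbreeding_sim`` conditions on an observed sample: each replicate
re-samples founders with replacement, selfs each for the assay length, and
summarises diversity among the resulting lines after jackknife subsampling to
the population sample size. The empirical spread across replicates gives
drift-only 95% credible intervals against which observed post-inbreeding
diversity can be scored — diversity above the interval indicates balancing
(overdominant or associative-overdominant) selection during inbreeding, below
it purging of deleterious variation.

There is no selection, mutation or outcrossing in this module: departures
from its intervals are the signal the comparison is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import diversity
from .genotype_io import GeneticMap, PhasedGenotypeMatrix

__all__ = [
    "MeiosisModel",
    "NeutralSimConfig",
    "NeutralSimResult",
    "meiosis",
    "gametes_batch",
    "self_lineage",
    "self_lineages_batch",
    "summarize_lines",
    "neutral_inbreeding_sim",
]


@dataclass(frozen=True)
class MeiosisModel:
    """Meiosis under complete crossover interference.

    ``chromosome_length_cM`` sets the crossover probability (length in
    Morgans, capped at 1); if None, the span of the chromosome's marker map
    is used — identical for maps that run 0..50 cM. Crossovers are placed
    interval-weighted between consecutive SNPs.
    """

    interference: str = "complete"
    chromosome_length_cM: float | None = None
    crossover_position_rule: str = "interval-weighted"

    def __post_init__(self) -> None:
        if self.interference != "complete":
            raise ValueError("only complete crossover interference is modelled")
        if self.crossover_position_rule != "interval-weighted":
            raise ValueError("crossovers are placed interval-weighted")


def gametes_batch(
    alleles: np.ndarray,
    positions_cM: np.ndarray,
    rng: np.random.Generator,
    model: MeiosisModel = MeiosisModel(),
) -> np.ndarray:
    """One gamete per parent for a batch of parents on one chromosome.

    ``alleles`` has shape (k, m, 2); returns (k, m). Each meiosis draws at
    most one crossover: with probability equal to the chromosome length in
    Morgans a breakpoint is placed in interval (j, j+1) with probability
    proportional to the interval's cM length and the gamete switches parental
    haplotypes there; otherwise a whole parental haplotype is transmitted,
    each with probability 1/2.
    """
    alleles = np.asarray(alleles)
    k, m, _ = alleles.shape
    pos = np.asarray(positions_cM, dtype=float)
    start = rng.integers(0, 2, size=k)

    widths = np.diff(pos)
    total = float(widths.sum())
    span = (
        total if model.chromosome_length_cM is None else float(model.chromosome_length_cM)
    )
    if m < 2 or total <= 0.0:
        hapsel = start[:, None] & np.ones((1, m), dtype=int)
        return np.take_along_axis(alleles, hapsel[:, :, None], axis=2)[:, :, 0]

    p_co = min(span / 100.0, 1.0)
    co = rng.random(k) < p_co
    cum = np.cumsum(widths) / total
    interval = np.searchsorted(cum, rng.random(k), side="right")
    interval = np.minimum(interval, m - 2)
    after = np.arange(m)[None, :] > interval[:, None]
    hapsel = start[:, None] ^ (co[:, None] & after)
    return np.take_along_axis(alleles, hapsel.astype(int)[:, :, None], axis=2)[:, :, 0]


def meiosis(
    parent: np.ndarray,
    positions_cM: np.ndarray,
    rng: np.random.Generator,
    model: MeiosisModel = MeiosisModel(),
) -> np.ndarray:
    """Single gamete haplotype from one phased diploid over one chromosome."""
    return gametes_batch(np.asarray(parent)[None, :, :], positions_cM, rng, model)[0]


def self_lineages_batch(
    founders: np.ndarray,
    gmap: GeneticMap,
    generations: int,
    rng: np.random.Generator,
    model: MeiosisModel = MeiosisModel(),
) -> np.ndarray:
    """Self every founder for ``generations`` generations (vectorised).

    ``founders`` has shape (k, m, 2); each generation joins two independent
    gametes of the same individual, chromosome by chromosome. Returns the
    final (k, m, 2) diploids.
    """
    current = np.asarray(founders).copy()
    slices = list(gmap.chromosome_slices().values())
    for _ in range(generations):
        nxt = np.empty_like(current)
        for sl in slices:
            pos = gmap.positions_cM[sl]
            nxt[:, sl, 0] = gametes_batch(current[:, sl, :], pos, rng, model)
            nxt[:, sl, 1] = gametes_batch(current[:, sl, :], pos, rng, model)
        current = nxt
    return current


def self_lineage(
    founder: np.ndarray,
    gmap: GeneticMap,
    generations: int,
    rng: np.random.Generator,
    model: MeiosisModel = MeiosisModel(),
) -> np.ndarray:
    """Final diploid of one lineage selfed for ``generations`` generations."""
    return self_lineages_batch(
        np.asarray(founder)[None, :, :], gmap, generations, rng, model
    )[0]


# ---------------------------------------------------------------------------
# conditional neutral simulation


@dataclass(frozen=True)
class NeutralSimConfig:
    """Settings for the drift-only line-derivation simulation.

    ``generations`` is the inbreeding assay length (16 for the ancestral-style
    assay, 13 for evolved populations); ``n_lines_sampled`` matches the number
    of surviving lines; ``subset_size`` the genotyped population sample size.
    """

    generations: int
    n_lines_sampled: int
    n_sims: int = 1000
    subset_size: int = 16
    seed: int = 0
    per_chromosome: bool = True
    n_subsets: int = 20
    window: int = 10

    def __post_init__(self) -> None:
        if self.generations < 0 or self.n_sims < 1 or self.n_lines_sampled < 1:
            raise ValueError("invalid simulation configuration")


@dataclass
class NeutralSimResult:
    """Distribution of one diversity metric across simulation replicates."""

    metric: str
    values: np.ndarray
    expectation: float
    credible_interval_95: tuple[float, float]

    def score(self, observed: float) -> str:
        """Position of an observed value: 'below', 'inside' or 'above'."""
        lo, hi = self.credible_interval_95
        if observed < lo:
            return "below"
        if observed > hi:
            return "above"
        return "inside"


def _metric_fn(name: str, cfg: NeutralSimConfig):
    if name == "He":
        return lambda gm: diversity.expected_heterozygosity(
            gm, per_chromosome=cfg.per_chromosome
        )[1]
    if name == "Ho":
        return lambda gm: diversity.observed_heterozygosity(
            gm, per_chromosome=cfg.per_chromosome
        )[1]
    if name == "he":
        return lambda gm: diversity.effective_haplotype_number(
            gm, window=cfg.window, per_chromosome=cfg.per_chromosome
        )[1]
    raise ValueError(f"unknown metric {name!r}; choose from He, Ho, he")


def summarize_lines(
    lines: PhasedGenotypeMatrix,
    cfg: NeutralSimConfig,
    metrics: tuple[str, ...],
    seed: int | None = None,
) -> dict[str, float]:
    """Jackknife-matched metric values for one set of lines, exactly as each
    simulation replicate is summarised (use this on observed lines too)."""
    return {
        name: diversity.jackknife_match(
            _metric_fn(name, cfg),
            lines,
            subset_size=cfg.subset_size,
            max_subsets=cfg.n_subsets,
            seed=seed,
        )
        for name in metrics
    }


def neutral_inbreeding_sim(
    pop: PhasedGenotypeMatrix,
    cfg: NeutralSimConfig,
    metrics: tuple[str, ...] = ("He", "he", "Ho"),
    model: MeiosisModel = MeiosisModel(),
) -> dict[str, NeutralSimResult]:
    """Drift-only distribution of post-inbreeding diversity, conditional on an
    observed population sample.

    Each of ``cfg.n_sims`` replicates samples ``cfg.n_lines_sampled`` founders
    with replacement from ``pop``, selfs each lineage for ``cfg.generations``
    generations, subsamples the lines to ``cfg.subset_size`` by jackknife, and
    records each metric (chromosomes analysed separately and averaged).
    Returns, per metric, the replicate values with their empirical mean and
    2.5/97.5 percentile interval.
    """
    pop.require_phase("neutral inbreeding simulation")
    rng = np.random.default_rng(cfg.seed)
    n_sims, n_lines = cfg.n_sims, cfg.n_lines_sampled

    founder_idx = rng.integers(0, pop.n_individuals, size=(n_sims, n_lines))
    founders = pop.alleles[founder_idx.reshape(-1)]
    final = self_lineages_batch(founders, pop.gmap, cfg.generations, rng, model)
    final = final.reshape(n_sims, n_lines, pop.n_markers, 2)

    subset_seeds = rng.integers(0, 2**31, size=n_sims)
    values: dict[str, list[float]] = {name: [] for name in metrics}
    line_names = [f"line{j}" for j in range(n_lines)]
    for s in range(n_sims):
        lines = PhasedGenotypeMatrix(
            individuals=line_names, alleles=final[s], phased=True, gmap=pop.gmap
        )
        summary = summarize_lines(lines, cfg, metrics, seed=int(subset_seeds[s]))
        for name in metrics:
            values[name].append(summary[name])

    out: dict[str, NeutralSimResult] = {}
    for name in metrics:
        arr = np.asarray(values[name])
        lo, hi = np.percentile(arr, [2.5, 97.5])
        out[name] = NeutralSimResult(
            metric=name,
            values=arr,
            expectation=float(arr.mean()),
            credible_interval_95=(float(lo), float(hi)),
        )
    return out
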