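"""Single-locus and multilocus diversity statistics.

Implements the statistics used to track diversity through experimental
evolution under different mating systems:

* expected heterozygosity He = 2pq per SNP and its genome-wide mean,
* observed heterozygosity Ho,
* the multilocus inbreeding coefficient Fis = 1 - mean(Ho)/mean(He) over SNPs
  with He >= 0.05,
* identity disequilibrium g2 (David et al. 2007 multilocus estimator, the one
  implemented by inbreedR), with a bootstrap-over-individuals standard error,
* the effective number of haplotypes he = 1 / sum(k_i^2) in non-overlapping
  windows of 10 SNPs on phased data,
* delete-d jackknife subsampling so statistics on large line panels are
  comparable to 16-individual population samples,
* the correlation of per-SNP allele-frequency changes across two successive
  episodes (experimental evolution, then inbreeding).

Genome-wide summaries default to averaging per-chromosome means across
chromosomes (``per_chromosome=True``); flat averaging over all markers or
windows is available behind the flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GeneticMap, PhasedGenotypeMatrix

__all__ = [
    "DiversityReport",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "inbreeding_coefficient",
    "identity_disequilibrium_g2",
    "effective_haplotype_number",
    "haplotype_windows",
    "jackknife_match",
    "frequency_change_correlation",
    "diversity_report",
]


@dataclass
class DiversityReport:
    """Genome-wide diversity summary for one population sample."""

    population: str
    mean_He: float
    mean_Ho: float
    Fis: float
    g2: float
    g2_se: float
    mean_he: float
    n_markers_used: int
    filters_applied: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _chrom_codes(gmap: GeneticMap) -> np.ndarray:
    names = {c: i for i, c in enumerate(gmap.chromosome_names)}
    return np.array([names[c] for c in gmap.chromosomes])


def _genomewide_mean(values: np.ndarray, chrom_codes: np.ndarray, per_chromosome: bool) -> float:
    """Mean of per-marker/per-window values; per-chromosome means averaged by default."""
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        return float("nan")
    if not per_chromosome:
        return float(np.nanmean(values))
    means = [
        np.nanmean(values[(chrom_codes == c) & ok])
        for c in np.unique(chrom_codes)
        if ((chrom_codes == c) & ok).any()
    ]
    return float(np.mean(means))


def allele_frequencies(g: PhasedGenotypeMatrix) -> np.ndarray:
    """Per-marker ALT allele frequency over non-missing allele calls.

    Markers with every call missing get NaN (flagged with a warning).
    """
    alleles = g.alleles
    valid = alleles != MISSING
    counts = np.where(valid, alleles, 0).sum(axis=(0, 2)).astype(float)
    denom = valid.sum(axis=(0, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / denom
    if np.any(denom == 0):
        warnings.warn(
            f"{int((denom == 0).sum())} marker(s) have no non-missing calls; "
            "frequency set to NaN",
            stacklevel=2,
        )
    return p


def expected_heterozygosity(
    g: PhasedGenotypeMatrix, per_chromosome: bool = True
) -> tuple[np.ndarray, float]:
    """He = 2 p (1 - p) per marker, plus the genome-wide mean."""
    p = allele_frequencies(g)
    he = 2.0 * p * (1.0 - p)
    return he, _genomewide_mean(he, _chrom_codes(g.gmap), per_chromosome)


def _het_matrix(g: PhasedGenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(het indicator, valid indicator), each (n_individuals, n_markers)."""
    a = g.alleles
    valid = (a != MISSING).all(axis=2)
    het = (a[:, :, 0] != a[:, :, 1]) & valid
    return het, valid


def observed_heterozygosity(
    g: PhasedGenotypeMatrix, per_chromosome: bool = True
) -> tuple[np.ndarray, float]:
    """Ho = fraction of heterozygous individuals per marker, plus genome mean.

    Individuals with a missing allele at a marker are excluded at that marker.
    """
    het, valid = _het_matrix(g)
    denom = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het.sum(axis=0) / denom
    return ho, _genomewide_mean(ho, _chrom_codes(g.gmap), per_chromosome)


def inbreeding_coefficient(g: PhasedGenotypeMatrix, min_He: float = 0.05) -> float:
    """Multilocus fixation index Fis = 1 - mean(Ho) / mean(He).

    SNPs with He below ``min_He`` are removed first (guards against the noisy
    per-locus ratios of nearly fixed SNPs). The ratio-of-means (not the mean
    of per-locus ratios) is used throughout.
    """
    he, _ = expected_heterozygosity(g)
    ho, _ = observed_heterozygosity(g)
    keep = ~np.isnan(he) & ~np.isnan(ho) & (he >= min_He)
    if not keep.any():
        raise ValueError(f"no markers pass the He >= {min_He} filter; Fis undefined")
    return float(1.0 - ho[keep].mean() / he[keep].mean())


# ---------------------------------------------------------------------------
# identity disequilibrium


def _g2_point(het: np.ndarray, valid: np.ndarray) -> float:
    """David et al. (2007) multilocus g2 with pairwise-complete individuals.

    For each ordered locus pair (l, m), only individuals typed at both loci
    contribute. Writing h for the heterozygosity indicator restricted to valid
    calls, the estimator is

        g2 = sum_pairs E_hat[h_l h_m] / sum_pairs E_hat[h_l] E_hat[h_m] - 1

    with the cross-moment in the denominator taken over distinct individuals
    (i != j), which removes the finite-sample bias of plugging in the same
    individual twice. With complete data this reduces to the classical
    complete-data formula.
    """
    h = np.where(valid, het, False).astype(float)
    v = valid.astype(float)
    n_pair = v.T @ v  # individuals typed at both loci, per locus pair
    A = h.T @ h  # sum_i h_il h_im
    B = h.T @ v  # sum_i h_il [valid at m]
    C = v.T @ h  # sum_i h_im [valid at l]
    off = ~np.eye(h.shape[1], dtype=bool)
    ok = off & (n_pair >= 2)
    if not ok.any():
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.where(ok, A / n_pair, 0.0)
        den = np.where(ok, (B * C - A) / (n_pair * (n_pair - 1.0)), 0.0)
    den_sum = den.sum()
    if den_sum == 0:
        return float("nan")
    return float(num.sum() / den_sum - 1.0)


def identity_disequilibrium_g2(
    g: PhasedGenotypeMatrix, n_boot: int = 200, seed: int | None = None
) -> tuple[float, float]:
    """Identity disequilibrium g2 with a bootstrap-over-individuals SE.

    Returns ``(nan, nan)`` when g2 is undefined — in particular when no
    individual is heterozygous anywhere, the situation of an exclusively
    selfing population with Ho ~ 0.
    """
    het, valid = _het_matrix(g)
    if g.n_individuals < 2 or het.shape[1] < 2:
        raise ValueError("g2 needs at least 2 individuals and 2 markers")
    if not het.any():
        warnings.warn("no heterozygotes in the sample; g2 is undefined", stacklevel=2)
        return float("nan"), float("nan")
    point = _g2_point(het, valid)
    if np.isnan(point):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    n = het.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = _g2_point(het[idx], valid[idx])
    reps = reps[~np.isnan(reps)]
    se = float(reps.std(ddof=1)) if reps.size >= 2 else float("nan")
    return point, se


# ---------------------------------------------------------------------------
# effective number of haplotypes


def haplotype_windows(
    g: PhasedGenotypeMatrix,
    window: int = 10,
    unit: Literal["haploid", "diploid"] = "haploid",
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping ``window``-SNP windows and
    count phased haplotypes in each.

    Each individual contributes its two phased window-haplotypes
    (``unit='haploid'``, the default) or one unordered pair of them
    (``unit='diploid'``). Individuals with any missing allele in a window are
    dropped from that window only. A trailing remainder of fewer than
    ``window`` SNPs is dropped. Returns one row per window with columns
    chromosome, start (marker index), n_units, n_haplotypes, he.
    """
    g.require_phase("effective haplotype number")
    if not 1 <= window <= 31:
        raise ValueError("window size must be between 1 and 31 SNPs")
    rows = []
    for chrom, sl in g.gmap.chromosome_slices().items():
        n_mark = sl.stop - sl.start
        for w0 in range(0, n_mark - window + 1, window):
            cols = slice(sl.start + w0, sl.start + w0 + window)
            block = g.alleles[:, cols, :]  # (n, window, 2)
            complete = (block != MISSING).all(axis=(1, 2))
            block = block[complete]
            if block.shape[0] == 0:
                rows.append(
                    dict(chromosome=chrom, start=cols.start, n_units=0,
                         n_haplotypes=0, he=np.nan)
                )
                continue
            # encode each window-haplotype as an integer (window <= 31 bits)
            bits = (1 << np.arange(window, dtype=np.int64))[None, :, None]
            codes = (block.astype(np.int64) * bits).sum(axis=1)  # (n, 2)
            if unit == "haploid":
                units = codes.reshape(-1)
            elif unit == "diploid":
                lohi = np.sort(codes, axis=1)
                units = lohi[:, 0] << window | lohi[:, 1]
            else:
                raise ValueError(f"unknown haplotype unit {unit!r}")
            _, counts = np.unique(units, return_counts=True)
            k = counts / counts.sum()
            rows.append(
                dict(
                    chromosome=chrom,
                    start=cols.start,
                    n_units=int(units.size),
                    n_haplotypes=int(counts.size),
                    he=float(1.0 / np.sum(k**2)),
                )
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "n_units", "n_haplotypes", "he"])


def effective_haplotype_number(
    g: PhasedGenotypeMatrix,
    window: int = 10,
    unit: Literal["haploid", "diploid"] = "haploid",
    per_chromosome: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Per-window effective number of haplotypes and its genome-wide mean."""
    table = haplotype_windows(g, window=window, unit=unit)
    if table.empty:
        raise ValueError(f"no chromosome holds a complete window of {window} SNPs")
    names = {c: i for i, c in enumerate(g.gmap.chromosome_names)}
    codes = table["chromosome"].map(names).to_numpy()
    return table, _genomewide_mean(table["he"].to_numpy(), codes, per_chromosome)


# ---------------------------------------------------------------------------
# jackknife subsampling


def jackknife_match(
    metric: Callable[[PhasedGenotypeMatrix], float],
    g: PhasedGenotypeMatrix,
    subset_size: int = 16,
    max_subsets: int = 200,
    seed: int | None = None,
) -> float:
    """Mean of ``metric`` over delete-d jackknife subsets of ``subset_size``
    individuals, for sample-size-matched comparison with population samples.

    All C(n, subset_size) subsets are enumerated when there are at most
    ``max_subsets`` of them; otherwise ``max_subsets`` subsets are drawn
    without replacement of indices (seeded). With fewer individuals than
    ``subset_size`` the metric is evaluated on the full sample with a warning.
    """
    n = g.n_individuals
    if n < subset_size:
        warnings.warn(
            f"only {n} individuals (< {subset_size}); metric computed on the full sample",
            stacklevel=2,
        )
        return float(metric(g))
    if n == subset_size:
        return float(metric(g))
    if comb(n, subset_size) <= max_subsets:
        subsets = [list(c) for c in itertools.combinations(range(n), subset_size)]
    else:
        rng = np.random.default_rng(seed)
        subsets = [
            list(rng.choice(n, size=subset_size, replace=False)) for _ in range(max_subsets)
        ]
    return float(np.mean([metric(g.subset(s)) for s in subsets]))


# ---------------------------------------------------------------------------
# allele-frequency change across episodes


def frequency_change_correlation(
    gA: PhasedGenotypeMatrix, gB: PhasedGenotypeMatrix, gC: PhasedGenotypeMatrix
) -> float:
    """Pearson correlation of per-SNP frequency changes across two episodes.

    A -> B is the first episode (experimental evolution), B -> C the second
    (inbred-line derivation). Only markers polymorphic in A enter. A negative
    correlation means the second episode tends to undo the changes of the
    first — the signature of selection opposing directional differentiation.
    """
    if not (
        gA.gmap.marker_ids == gB.gmap.marker_ids == gC.gmap.marker_ids
    ):
        raise ValueError("the three samples must share an identical marker set")
    pA = allele_frequencies(gA)
    pB = allele_frequencies(gB)
    pC = allele_frequencies(gC)
    keep = (
        ~np.isnan(pA) & ~np.isnan(pB) & ~np.isnan(pC) & (pA > 0.0) & (pA < 1.0)
    )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared polymorphic markers")
    d1 = pB[keep] - pA[keep]
    d2 = pC[keep] - pB[keep]
    r, _ = stats.pearsonr(d1, d2)
    return float(r)


# ---------------------------------------------------------------------------
# report


def diversity_report(
    g: PhasedGenotypeMatrix,
    population: str,
    min_He: float = 0.05,
    window: int = 10,
    n_boot: int = 200,
    seed: int | None = None,
    per_chromosome: bool = True,
) -> DiversityReport:
    """Assemble the genome-wide diversity summary for one population sample."""
    he_m, mean_he_snp = expected_heterozygosity(g, per_chromosome=per_chromosome)
    _, mean_ho = observed_heterozygosity(g, per_chromosome=per_chromosome)
    fis = inbreeding_coefficient(g, min_He=min_He)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g2, g2_se = identity_disequilibrium_g2(g, n_boot=n_boot, seed=seed)
    if g.phased:
        _, mean_hap = effective_haplotype_number(
            g, window=window, per_chromosome=per_chromosome
        )
    else:
        mean_hap = float("nan")
    n_used = int((~np.isnan(he_m) & (he_m >= min_He)).sum())
    return DiversityReport(
        population=population,
        mean_He=mean_he_snp,
        mean_Ho=mean_ho,
        Fis=fis,
        g2=g2,
        g2_se=g2_se,
        mean_he=mean_hap,
        n_markers_used=n_used,
        filters_applied=f"Fis over SNPs with He >= {min_He}; he in {window}-SNP windows",
    )
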