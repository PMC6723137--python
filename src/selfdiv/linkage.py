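"""Pairwise linkage disequilibrium within chromosomes and its decay with
genetic distance.

For each within-chromosome SNP pair with allele frequencies inside a MAF band
(0.05-0.95 by default), the gametic disequilibrium D and the squared
correlation r2 = D^2 / (p_i q_i p_j q_j) are tabulated together with the
genetic distance c (cM) between the pair. On phased data D is counted
directly from gametes, D = P(1,1) - p_i p_j; on unphased data the Burrows
composite estimator is used, D = (E[X Y] - 4 p_i p_j) / 2 with X, Y the ALT
dosages, which needs no haplotype inference.

The decay of r2 with distance is summarised by least-squares fitting of the
drift-recombination expectation E[r2] = 1 / (1 + 4 x c) (Sved's form), where
larger x means faster decay; the fit is log-parameterised so x stays
positive. Replicate populations are fitted separately and pooled by
inverse-variance weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genotype_io import MISSING, PhasedGenotypeMatrix

__all__ = ["LDDecayFit", "pairwise_r2", "ld_expected_r2", "fit_ld_decay", "pool_fits"]


@dataclass
class LDDecayFit:
    """Fitted decay-rate parameter of E[r2] = 1/(1 + 4 x c)."""

    population: str
    x_hat: float
    x_se: float
    n_pairs: int
    model: str = "E[r2] = 1/(1 + 4*x*c)"


def _pair_table(hap: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gametic D, p_i, p_j for all marker pairs from a gamete x marker matrix.

    ``hap`` holds 0/1 alleles, ``valid`` marks non-missing calls; statistics
    for a pair use only gametes typed at both markers (pairwise complete).
    Returns (D, P_i, P_j) as (m, m) arrays.
    """
    h = np.where(valid, hap, 0).astype(float)
    v = valid.astype(float)
    n = v.T @ v
    with np.errstate(invalid="ignore", divide="ignore"):
        p11 = (h.T @ h) / n
        pi = (h.T @ v) / n
        pj = (v.T @ h) / n
    return p11 - pi * pj, pi, pj


def pairwise_r2(
    g: PhasedGenotypeMatrix,
    maf_range: tuple[float, float] = (0.05, 0.95),
    max_cM: float | None = None,
    allow_unphased: bool = True,
) -> pd.DataFrame:
    """LD table of all within-chromosome SNP pairs passing the frequency band.

    Columns: marker_i, marker_j, chromosome, c (cM), D, r2. Markers whose
    overall ALT frequency falls outside ``maf_range`` are excluded; pairs
    farther apart than ``max_cM`` (if set) are dropped.
    """
    if not g.phased and not allow_unphased:
        raise ValueError(
            "unphased genotypes with the composite estimator disabled; "
            "phase the data or pass allow_unphased=True"
        )
    from .diversity import allele_frequencies

    p_all = allele_frequencies(g)
    lo, hi = maf_range
    passing = ~np.isnan(p_all) & (p_all >= lo) & (p_all <= hi)

    frames = []
    for chrom, sl in g.gmap.chromosome_slices().items():
        idx = np.flatnonzero(passing[sl]) + sl.start
        if idx.size < 2:
            continue
        pos = g.gmap.positions_cM[idx]
        if g.phased:
            hap = g.alleles[:, idx, :].transpose(0, 2, 1).reshape(-1, idx.size)
            valid = hap != MISSING
            D, pi, pj = _pair_table(hap, valid)
        else:
            a = g.alleles[:, idx, :]
            complete = (a != MISSING).all(axis=2)
            dose = np.where(complete, a.sum(axis=2), 0).astype(float)
            v = complete.astype(float)
            n = v.T @ v
            with np.errstate(invalid="ignore", divide="ignore"):
                exy = (dose.T @ dose) / n
                pi = (dose.T @ v) / (2.0 * n)
                pj = (v.T @ dose) / (2.0 * n)
            D = (exy - 4.0 * pi * pj) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = pi * (1 - pi) * pj * (1 - pj)
            r2 = np.where(denom > 0, D**2 / denom, np.nan)
        iu, ju = np.triu_indices(idx.size, k=1)
        c = np.abs(pos[ju] - pos[iu])
        keep = ~np.isnan(r2[iu, ju])
        if max_cM is not None:
            keep &= c <= max_cM
        frames.append(
            pd.DataFrame(
                {
                    "marker_i": np.array(g.gmap.marker_ids)[idx[iu[keep]]],
                    "marker_j": np.array(g.gmap.marker_ids)[idx[ju[keep]]],
                    "chromosome": chrom,
                    "c": c[keep],
                    "D": D[iu, ju][keep],
                    "r2": np.clip(r2[iu, ju][keep], 0.0, None),
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome has >= 2 markers passing the frequency band")
    return pd.concat(frames, ignore_index=True)


def ld_expected_r2(c: np.ndarray, x: float) -> np.ndarray:
    """Sved's drift-recombination expectation, 1/(1 + 4 x c); equals 1 at c=0."""
    return 1.0 / (1.0 + 4.0 * x * np.asarray(c, dtype=float))


def fit_ld_decay(
    ld: pd.DataFrame, population: str = "", x0: float = 10.0, n_restarts: int = 4
) -> LDDecayFit:
    """Least-squares fit of E[r2] = 1/(1 + 4 x c) to an LD table.

    ``x`` is fitted on the log scale so the estimate stays positive; the SE is
    the delta-method transform of the curvature-based SE of log x. Restarts
    over a grid of starting values guard against poor initialisation.
    """
    c = ld["c"].to_numpy(dtype=float)
    r2 = ld["r2"].to_numpy(dtype=float)
    ok = ~np.isnan(c) & ~np.isnan(r2)
    c, r2 = c[ok], r2[ok]
    if c.size < 10 or np.ptp(c) <= 0:
        raise ValueError("need >= 10 pairs spanning a positive cM range")

    def model(cc, logx):
        return ld_expected_r2(cc, np.exp(logx))

    best = None
    starts = [x0] + list(np.geomspace(0.1, 1000, n_restarts))
    last_err: Exception | None = None
    for s in starts:
        try:
            with np.errstate(over="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, c, r2, p0=[np.log(s)], maxfev=10_000)
        except RuntimeError as err:  # no convergence from this start
            last_err = err
            continue
        resid = float(np.sum((r2 - model(c, popt[0])) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise RuntimeError(
            f"LD-decay fit failed to converge from {len(starts)} starts "
            f"({c.size} pairs, c range {c.min():.3g}-{c.max():.3g} cM): {last_err}"
        )
    popt, pcov, _ = best
    x_hat = float(np.exp(popt[0]))
    logx_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return LDDecayFit(
        population=population, x_hat=x_hat, x_se=x_hat * logx_se, n_pairs=int(c.size)
    )


def pool_fits(fits: list[LDDecayFit], population: str = "") -> LDDecayFit:
    """Inverse-variance-weighted pooling of per-replicate decay fits."""
    if not fits:
        raise ValueError("no fits to pool")
    x = np.array([f.x_hat for f in fits])
    se = np.array([f.x_se for f in fits])
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        # fall back to an unweighted mean when any replicate lacks a usable SE
        return LDDecayFit(
            population=population,
            x_hat=float(x.mean()),
            x_se=float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan"),
            n_pairs=int(sum(f.n_pairs for f in fits)),
        )
    w = 1.0 / se**2
    return LDDecayFit(
        population=population,
        x_hat=float(np.sum(w * x) / np.sum(w)),
        x_se=float(np.sqrt(1.0 / np.sum(w))),
        n_pairs=int(sum(f.n_pairs for f in fits)),
    )
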