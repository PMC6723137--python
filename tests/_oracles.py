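"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over definitions, deliberately
sharing no code with the package, so agreement is a real cross-check.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def tally_allele_frequency(alleles: np.ndarray) -> np.ndarray:
    """ALT frequency per marker by explicit counting over allele calls."""
    n, m, _ = alleles.shape
    out = np.full(m, np.nan)
    for j in range(m):
        num = den = 0
        for i in range(n):
            for k in (0, 1):
                a = alleles[i, j, k]
                if a != MISSING:
                    den += 1
                    num += int(a)
        if den:
            out[j] = num / den
    return out


def brute_g2(het: np.ndarray, valid: np.ndarray | None = None) -> float:
    """David et al. multilocus identity disequilibrium by explicit loops.

    ``het`` is an (individuals x loci) 0/1 heterozygosity matrix; ``valid``
    marks typed entries (all True for complete data). Per locus pair, only
    individuals typed at both loci enter; the denominator cross-moment runs
    over ordered pairs of distinct individuals.
    """
    n, L = het.shape
    if valid is None:
        valid = np.ones_like(het, dtype=bool)
    num_sum = 0.0
    den_sum = 0.0
    for l in range(L):
        for m in range(L):
            if l == m:
                continue
            ids = [i for i in range(n) if valid[i, l] and valid[i, m]]
            np_pair = len(ids)
            if np_pair < 2:
                continue
            num = sum(het[i, l] * het[i, m] for i in ids) / np_pair
            den = 0.0
            for i in ids:
                for j in ids:
                    if i != j:
                        den += het[i, l] * het[j, m]
            den /= np_pair * (np_pair - 1)
            num_sum += num
            den_sum += den
    if den_sum == 0:
        return float("nan")
    return num_sum / den_sum - 1.0


def brute_r2_phased(haps_a: np.ndarray, haps_b: np.ndarray) -> tuple[float, float]:
    """(D, r2) for two loci from gamete allele vectors via the 2x2 table."""
    pairs = [
        (a, b) for a, b in zip(haps_a, haps_b) if a != MISSING and b != MISSING
    ]
    n = len(pairs)
    p11 = sum(1 for a, b in pairs if a == 1 and b == 1) / n
    pa = sum(a for a, _ in pairs) / n
    pb = sum(b for _, b in pairs) / n
    D = p11 - pa * pb
    r2 = D**2 / (pa * (1 - pa) * pb * (1 - pb))
    return D, r2


def brute_he_window(block: np.ndarray) -> float:
    """Effective number of haplotypes in one complete-data phased window."""
    counts: dict[tuple, int] = {}
    for i in range(block.shape[0]):
        for k in (0, 1):
            key = tuple(int(x) for x in block[i, :, k])
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return 1.0 / sum((c / total) ** 2 for c in counts.values())


def brute_km(durations, events) -> tuple[list[float], list[float]]:
    """Product-limit estimate by explicit risk-set bookkeeping.

    Returns (event_times, S at those times). Censored observations leave the
    risk set after their time (right-censoring convention).
    """
    times = sorted({t for t, e in zip(durations, events) if e})
    S = 1.0
    out_t, out_s = [], []
    for t in times:
        at_risk = sum(1 for d in durations if d >= t)
        d_events = sum(1 for d, e in zip(durations, events) if e and d == t)
        S *= 1.0 - d_events / at_risk
        out_t.append(t)
        out_s.append(S)
    return out_t, out_s
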