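"""Product-limit (Kaplan-Meier) estimation of inbred-line survival.

Line extinction during enforced selfing is right-censored event data: a line
either goes extinct at an observed generation or is alive when the assay ends
(13 or 16 generations) and is censored there. The survival function S(t) is
the probability that a line survives beyond generation t; 1 - S(t) is the
cumulative risk of lineage extinction, the study's measure of genetic load.

Estimation is delegated to ``lifelines.KaplanMeierFitter`` (Greenwood
variance, log-log transformed pointwise 95% bands); this module adapts it to
:class:`~selfdiv.genotype_io.LineRecord` data and a step-function readout.
Hazard regression (Cox models) is intentionally not provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import LineRecord

__all__ = ["SurvivalCurve", "km_estimate", "survival_at"]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate on the generation grid of observed times."""

    population: str
    times: np.ndarray  # increasing generation numbers, starting at 0
    S: np.ndarray  # survival estimates, S[0] = 1 at time 0
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("survival estimates must be non-increasing")


def km_estimate(
    lines: list[LineRecord], population: str = "", conf_level: float = 0.95
) -> SurvivalCurve:
    """Product-limit survival curve from line records.

    Extinct lines contribute events at their recorded generation; censored
    lines contribute to the risk sets only. Pointwise confidence bands are
    Greenwood-based on the log(-log S) scale.
    """
    if not lines:
        raise ValueError("no line records")
    from lifelines import KaplanMeierFitter

    durations = np.array([r.generations_survived for r in lines], dtype=float)
    events = np.array([r.status == "extinct" for r in lines], dtype=bool)
    kmf = KaplanMeierFitter(alpha=1.0 - conf_level)
    kmf.fit(durations, event_observed=events)

    times = kmf.survival_function_.index.to_numpy(dtype=float)
    S = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    table = kmf.event_table
    n_risk = table["at_risk"].to_numpy(dtype=float)
    n_events = table["observed"].to_numpy(dtype=float)
    return SurvivalCurve(
        population=population,
        times=times,
        S=S,
        ci_low=np.minimum(lo, S),
        ci_high=np.maximum(hi, S),
        n_risk=n_risk,
        n_events=n_events,
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step-function evaluation of S at time t.

    Before the first tabulated time this is 1; beyond the last it is the
    final estimate.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.S[idx])
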