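"""Posterior-sample post-processing: moments, HPD intervals, screening.

All summaries operate on plain 1-D arrays of post-burn-in, thinned MCMC
draws.  The HPD interval is the empirical shortest-window interval over the
sorted draws (the convention of post-Gibbs tools in animal breeding), which
is deterministic — no kernel density estimation is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ParameterSummary:
    name: str
    mean: float
    median: float
    sd: float
    hpd_low: float
    hpd_high: float

    @property
    def excludes_zero(self) -> bool:
        return interval_excludes_zero((self.hpd_low, self.hpd_high))


def summarize(samples) -> tuple[float, float, float]:
    """Mean, median and sample SD (ddof=1) of a draw vector."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 draws to summarize")
    return float(x.mean()), float(np.median(x)), float(x.std(ddof=1))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over the sorted draws holding ``mass``.

    The window length is ``ceil(mass * n)`` draws; ties between equally
    short windows are broken toward the lowest (leftmost) window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPD interval")
    k = math.ceil(mass * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(np.argmin(widths))  # argmin takes the first minimum: lowest window
    return float(x[j]), float(x[j + k - 1])


def equal_tailed_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    x = np.asarray(samples, dtype=float)
    a = (1.0 - mass) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def interval_excludes_zero(interval) -> bool:
    """True iff zero lies strictly outside the interval.

    An interval touching zero at either endpoint does NOT exclude it
    (conservative screening convention).
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError("interval lower bound exceeds upper bound")
    return lo > 0.0 or hi < 0.0


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    A proxy for visual trace inspection: compares the mean of the first
    ``first`` fraction against the last ``last`` fraction, with variances
    estimated by segment sample variance over an effective size deflated by
    lag-1 autocorrelation.  |z| > 2 suggests the chain has not stabilized.
    Reported as a diagnostic, never enforced.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)) :]

    def seg_var(seg: np.ndarray) -> float:
        v = seg.var(ddof=1)
        if v == 0.0:
            return 0.0
        r1 = np.corrcoef(seg[:-1], seg[1:])[0, 1] if seg.size > 2 else 0.0
        r1 = min(max(r1, 0.0), 0.99)
        ess = seg.size * (1 - r1) / (1 + r1)
        return v / max(ess, 1.0)

    denom = math.sqrt(seg_var(a) + seg_var(b))
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def summarize_parameter(name: str, samples, mass: float = 0.95) -> ParameterSummary:
    mean, median, sd = summarize(samples)
    lo, hi = hpd_interval(samples, mass)
    return ParameterSummary(name, mean, median, sd, lo, hi)


def summary_table(named_samples: dict[str, np.ndarray], mass: float = 0.95) -> pd.DataFrame:
    """Tabulate posterior summaries, one row per parameter.

    Columns: ``parameter, mean, median, sd, hpd_low, hpd_high`` — the schema
    the CLI writes and re-reads.
    """
    rows = []
    for name, draws in named_samples.items():
        s = summarize_parameter(name, draws, mass)
        rows.append(
            {
                "parameter": s.name,
                "mean": s.mean,
                "median": s.median,
                "sd": s.sd,
                "hpd_low": s.hpd_low,
                "hpd_high": s.hpd_high,
            }
        )
    return pd.DataFrame(rows)


def format_interval(lo: float, hi: float, digits: int = 2) -> str:
    """Render an interval like ``(0.25, 2.27)``."""
    return f"({lo:.{digits}f}, {hi:.{digits}f})"
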