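"""Out-of-specification probability estimation and plausibility checks.

The OOS probability of a sample is the tail area of a normal distribution
fitted with the arithmetic mean and an inflated standard deviation — the
upper 80% confidence bound of the sample sd — beyond the drug-substance
specification limit. The inflation keeps small manufacturing samples
comparable with large simulated samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .unit_models import DomainError, SpecLimit


@dataclass
class OOSResult:
    cqa: str | None
    n: int
    mean: float
    sd: float
    sd_upper80: float
    spec: SpecLimit
    oos_probability: float
    scale_of_fit: str = "raw"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.oos_probability <= 1.0:
            raise DomainError("OOS probability must lie in [0, 1]")
        if self.sd_upper80 < self.sd:
            raise DomainError("inflated sd cannot be below the sample sd")


def upper_sd_ci(s: float, n: int, level: float = 0.80, sided: str = "one") -> float:
    """Upper confidence bound of a normal standard deviation.

    One-sided (default): ``s * sqrt((n-1) / chi2_{1-level, n-1})``;
    ``sided='two'`` gives the upper end of the central two-sided interval.
    Decreases towards ``s`` as n grows.
    """
    if n < 2:
        raise DomainError(f"upper_sd_ci needs n >= 2, got {n}")
    if not s > 0:
        raise DomainError(f"upper_sd_ci needs s > 0, got {s}")
    if not 0.0 < level < 1.0:
        raise DomainError(f"confidence level must be in (0, 1), got {level}")
    if sided == "one":
        alpha = 1.0 - level
    elif sided == "two":
        alpha = (1.0 - level) / 2.0
    else:
        raise DomainError(f"sided must be 'one' or 'two', got {sided!r}")
    q = stats.chi2.ppf(alpha, n - 1)
    return s * math.sqrt((n - 1) / q)


def oos_probability(
    values: Sequence[float],
    spec: SpecLimit,
    cqa: str | None = None,
    fit_scale: str = "raw",
    ci_level: float = 0.80,
    inflate_sd: bool = True,
) -> OOSResult:
    """Normal-fit tail probability of a sample beyond the specification.

    ``fit_scale='log'`` fits on log values (for attributes spanning decades);
    the limits are transformed accordingly. A zero sample sd yields a
    degenerate 0/1 result by the position of the mean.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DomainError(f"OOS estimation needs n >= 2, got {len(v)}")
    lower, upper = spec.lower, spec.upper
    if fit_scale == "log":
        if np.any(~(v > 0)):
            raise DomainError("log-scale OOS fit requires positive values")
        v = np.log(v)
        lower = math.log(lower) if lower is not None else None
        upper = math.log(upper) if upper is not None else None
    elif fit_scale != "raw":
        raise DomainError(f"unknown fit scale {fit_scale!r}")

    n = len(v)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        oos = 0.0
        if upper is not None and mean > upper:
            oos = 1.0
        if lower is not None and mean < lower:
            oos = 1.0
        return OOSResult(cqa, n, mean, sd, sd, spec, oos, fit_scale, degenerate=True)

    sd_used = upper_sd_ci(sd, n, ci_level) if inflate_sd else sd
    oos = 0.0
    if upper is not None:
        oos += float(stats.norm.sf(upper, loc=mean, scale=sd_used))
    if lower is not None:
        oos += float(stats.norm.cdf(lower, loc=mean, scale=sd_used))
    return OOSResult(cqa, n, mean, sd, sd_used if inflate_sd else sd, spec,
                     min(oos, 1.0), fit_scale)


def three_sd_limits(values: Sequence[float]) -> tuple[float, float]:
    """Conventional mean +/- 3 sample standard deviations baseline."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DomainError(f"3SD limits need n >= 2, got {len(v)}")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return mean - 3.0 * sd, mean + 3.0 * sd


@dataclass
class PlausibilityReport:
    """Simulated-vs-manufacturing comparison at target conditions."""

    n_sim: int
    n_mfg: int
    smd: float
    ks_stat: float
    ks_p: float
    oos_sim: OOSResult
    oos_mfg: OOSResult
    hist_edges: list[float]
    hist_sim: list[float]
    hist_mfg: list[float]
    passed: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_sim": self.n_sim,
            "n_mfg": self.n_mfg,
            "smd": self.smd,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
            "oos_sim": self.oos_sim.oos_probability,
            "oos_mfg": self.oos_mfg.oos_probability,
            "hist_edges": self.hist_edges,
            "hist_sim": self.hist_sim,
            "hist_mfg": self.hist_mfg,
            "passed": self.passed,
            "flags": self.flags,
        }


def plausibility_check(
    sim_values: Sequence[float],
    manufacturing_values: Sequence[float],
    spec: SpecLimit,
    cqa: str | None = None,
    fit_scale: str = "raw",
    oos_ratio_limit: float = 10.0,
    oos_floor: float = 1e-4,
    smd_limit: float = 1.5,
    bins: int = 20,
) -> PlausibilityReport:
    """Compare a simulated DS distribution with manufacturing runs.

    The verdict passes when the two OOS probabilities are in the same range
    (within ``oos_ratio_limit`` of each other, or both below ``oos_floor``)
    and the standardized mean difference stays within ``smd_limit``. The
    histogram overlays are density-normalized (bin areas integrate to 1).
    """
    sim = np.asarray(sim_values, dtype=float)
    mfg = np.asarray(manufacturing_values, dtype=float)
    if len(sim) < 2 or len(mfg) < 2:
        raise DomainError("both samples need n >= 2")

    pooled_sd = math.sqrt(0.5 * (np.var(sim, ddof=1) + np.var(mfg, ddof=1)))
    smd = float((np.mean(sim) - np.mean(mfg)) / pooled_sd) if pooled_sd > 0 else 0.0
    ks_stat, ks_p = stats.ks_2samp(sim, mfg)

    oos_sim = oos_probability(sim, spec, cqa, fit_scale=fit_scale)
    oos_mfg = oos_probability(mfg, spec, cqa, fit_scale=fit_scale)

    lo = min(sim.min(), mfg.min())
    hi = max(sim.max(), mfg.max())
    edges = np.linspace(lo, hi, bins + 1) if hi > lo else np.linspace(lo - 0.5, lo + 0.5, bins + 1)
    h_sim, _ = np.histogram(sim, bins=edges, density=True)
    h_mfg, _ = np.histogram(mfg, bins=edges, density=True)

    flags: list[str] = []
    a, b = oos_sim.oos_probability, oos_mfg.oos_probability
    both_negligible = a < oos_floor and b < oos_floor
    if not both_negligible:
        ratio = max(a, oos_floor) / max(b, oos_floor)
        if not (1.0 / oos_ratio_limit <= ratio <= oos_ratio_limit):
            flags.append(
                f"OOS probabilities differ by more than {oos_ratio_limit}x "
                f"(simulated {a:.3g} vs manufacturing {b:.3g})"
            )
    if abs(smd) > smd_limit:
        flags.append(f"standardized mean difference {smd:.2f} exceeds {smd_limit}")

    return PlausibilityReport(
        n_sim=len(sim),
        n_mfg=len(mfg),
        smd=smd,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        oos_sim=oos_sim,
        oos_mfg=oos_mfg,
        hist_edges=[float(x) for x in edges],
        hist_sim=[float(x) for x in h_sim],
        hist_mfg=[float(x) for x in h_mfg],
        passed=not flags,
        flags=flags,
    )
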