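"""Intermediate acceptance criteria via pool-value sensitivity analysis.

For each (unit operation, CQA) pair, the pool value leaving the unit
operation is imposed on a screening grid, the downstream chain is simulated,
and the drug-substance OOS probability is recorded per grid point. The
acceptance criterion is the pool value at which a monotone fit of that curve
crosses the pre-defined OOS threshold (default 5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .ipm_engine import ProcessChain, SimulationConfig, simulate
from .oos_stats import oos_probability, three_sd_limits
from .unit_models import IMPURITY, DomainError, QualityAttribute

NOT_DERIVABLE = "not_derivable"


@dataclass
class ScreeningGrid:
    """Imposed pool values spanning mean +/- width_sd sample sds, ordered from
    the safe towards the risky side of the specification."""

    uo_id: int
    cqa: str
    grid_values: np.ndarray
    mfg_mean: float
    mfg_sd: float
    width_sd: float
    n_points: int
    clipped: bool

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_values, dtype=float)
        if len(g) < 2:
            raise DomainError("screening grid needs at least 2 points")
        d = np.diff(g)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DomainError("screening grid must be strictly monotone")
        if np.any(~(g > 0)):
            raise DomainError("screening grid values must be positive")


def screening_grid(
    pool_values: Sequence[float],
    cqa: QualityAttribute,
    uo_id: int,
    n_points: int = 15,
    width_sd: float = 10.0,
    eps_rel: float = 1e-6,
) -> ScreeningGrid:
    """Equidistant grid of mean +/- ``width_sd`` sds of manufacturing pools.

    Negative lower bounds are clipped to a small positive epsilon and the
    grid is re-spaced; percent attributes are additionally capped at 100.
    The grid runs towards the risky side: ascending for impurities,
    descending for purities.
    """
    v = np.asarray(pool_values, dtype=float)
    if len(v) < 2:
        raise DomainError("screening grid needs >= 2 manufacturing pool values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DomainError(
            "zero pool standard deviation: no screening range can be built; "
            "set the fallback iac_equals_ds_spec for this unit operation"
        )
    lo_raw = mean - width_sd * sd
    hi_raw = mean + width_sd * sd
    clipped = False
    lo = lo_raw
    hi = hi_raw
    if lo <= 0:
        lo = eps_rel * mean
        clipped = True
    if cqa.is_percent and hi > 100.0:
        hi = 100.0
        clipped = True
    grid = np.linspace(lo, hi, n_points)
    if cqa.direction != IMPURITY:
        grid = grid[::-1].copy()
    return ScreeningGrid(
        uo_id=uo_id,
        cqa=cqa.name,
        grid_values=grid,
        mfg_mean=mean,
        mfg_sd=sd,
        width_sd=width_sd,
        n_points=n_points,
        clipped=clipped,
    )


@dataclass
class PSAResult:
    """OOS-vs-imposed-pool curve and (after derivation) the iAC."""

    grid: ScreeningGrid
    oos_per_point: np.ndarray
    n_runs: int
    seed: int
    threshold: float | None = None
    smoothed_oos: np.ndarray | None = None
    iac: float | str | None = None
    side: str = "upper"
    guidance: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pool_value": self.grid.grid_values,
                "oos_probability": self.oos_per_point,
            }
        )
        if self.smoothed_oos is not None:
            df["oos_smoothed"] = self.smoothed_oos
        return df


def psa_curve(
    chain: ProcessChain,
    uo_id: int,
    cqa_name: str,
    grid: ScreeningGrid,
    config: SimulationConfig,
    oos_fit_scale: str = "raw",
) -> PSAResult:
    """Estimate the OOS probability at drug substance per imposed pool value.

    All grid points reuse the same per-run random substreams (common random
    numbers), so the curve differs only through the imposed pool value.
    """
    cqa = chain.cqa(cqa_name)
    start, end = chain.modelled_ranges[cqa_name]
    if not start <= uo_id <= end:
        raise DomainError(
            f"UO {uo_id} is outside the modelled range {start}..{end} of {cqa_name!r}"
        )
    cqa_index = [c.name for c in chain.cqas].index(cqa_name)
    oos = np.empty(len(grid.grid_values))
    for j, value in enumerate(grid.grid_values):
        cfg = replace(
            config,
            fixed_pool_overrides={(uo_id, cqa_name): float(value)},
            stream_key=(*config.stream_key, 7001, uo_id, cqa_index),
        )
        res = simulate(chain, cfg)
        ds = res.ds_values(cqa_name)
        oos[j] = oos_probability(ds, cqa.ds_spec, cqa_name, fit_scale=oos_fit_scale).oos_probability
    return PSAResult(
        grid=grid,
        oos_per_point=oos,
        n_runs=config.n_runs,
        seed=config.seed,
        side=cqa.risky_side,
    )


def derive_iac(psa: PSAResult, threshold: float = 0.05) -> PSAResult:
    """Invert the OOS curve at the threshold.

    An isotonic (non-decreasing towards the risky side) fit absorbs Monte
    Carlo noise; the crossing is located between the bracketing grid points
    by interpolating the probit of the OOS probability against the log pool
    value (exact for normal-tail OOS curves, where linear interpolation on
    the raw scale is biased by curvature). A curve that never brackets the
    threshold within the grid yields ``not_derivable`` — no extrapolation.
    """
    x = np.arange(len(psa.grid.grid_values), dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    smoothed = iso.fit_transform(x, psa.oos_per_point)
    psa.threshold = threshold
    psa.smoothed_oos = smoothed

    g = psa.grid.grid_values
    above = smoothed >= threshold
    if not above.any():
        psa.iac = NOT_DERIVABLE
        psa.guidance = (
            "the OOS curve never reaches the threshold inside the screening grid; "
            "extend width_sd to widen the grid"
        )
        return psa
    j = int(np.argmax(above))
    if j == 0:
        psa.iac = NOT_DERIVABLE
        psa.guidance = (
            "the OOS probability already exceeds the threshold at the safest grid "
            "point; extend width_sd towards the safe side"
        )
        return psa
    y0, y1 = smoothed[j - 1], smoothed[j]
    if y1 == y0:
        psa.iac = float(g[j])
    else:
        from scipy.stats import norm

        z0, z1, zt = norm.ppf(np.clip([y0, y1, threshold], 1e-300, 1 - 1e-12))
        frac = (zt - z0) / (z1 - z0)
        psa.iac = float(math.exp(
            math.log(g[j - 1]) + frac * (math.log(g[j]) - math.log(g[j - 1]))
        ))
    return psa


def derive_all_iacs(
    chain: ProcessChain,
    config: SimulationConfig,
    threshold: float = 0.05,
    n_points: int = 15,
    width_sd: float = 10.0,
    oos_fit_scale: str | dict[str, str] = "raw",
) -> pd.DataFrame:
    """iAC table over every (UO, CQA) cell of the chain.

    PSA-derived where a model path to drug substance exists; the final
    modelled UO and fallback-flagged UOs carry the DS specification limit.
    3SD baseline columns from manufacturing pool data are included for
    comparison; failures are recorded per cell, not raised.
    """
    rows = []
    for cqa in chain.cqas:
        start, end = chain.modelled_ranges[cqa.name]
        ds_spec_value = cqa.ds_spec.upper if cqa.direction == IMPURITY else cqa.ds_spec.lower
        fit_scale = (
            oos_fit_scale.get(cqa.name, "raw") if isinstance(oos_fit_scale, dict) else oos_fit_scale
        )
        for uo in chain.unit_operations:
            if uo.id < start:
                continue
            pool_obs = chain.pool_observations.get((uo.id, cqa.name))
            sd3 = three_sd_limits(pool_obs) if pool_obs and len(pool_obs) >= 2 else (None, None)
            base = {
                "uo_id": uo.id,
                "cqa": cqa.name,
                "side": cqa.risky_side,
                "threshold": threshold,
                "n_runs": config.n_runs,
                "seed": config.seed,
                "sd3_lower": sd3[0],
                "sd3_upper": sd3[1],
                "mfg_mean": float(np.mean(pool_obs)) if pool_obs else None,
                "mfg_sd": float(np.std(pool_obs, ddof=1)) if pool_obs and len(pool_obs) > 1 else None,
            }
            if uo.id > end or cqa.name in uo.fallback_ds_spec or uo.id == end:
                rows.append({**base, "iac": ds_spec_value, "method": "ds_spec_fallback"
                             if uo.id != end else "ds_spec", "status": "ok"})
                continue
            if not pool_obs or len(pool_obs) < 2:
                rows.append({**base, "iac": ds_spec_value, "method": "ds_spec_fallback",
                             "status": "no manufacturing pool data"})
                continue
            try:
                grid = screening_grid(pool_obs, cqa, uo.id, n_points=n_points, width_sd=width_sd)
                psa = psa_curve(chain, uo.id, cqa.name, grid, config, oos_fit_scale=fit_scale)
                psa = derive_iac(psa, threshold)
                if psa.iac == NOT_DERIVABLE:
                    rows.append({**base, "iac": None, "method": "psa",
                                 "status": f"{NOT_DERIVABLE}: {psa.guidance}"})
                else:
                    rows.append({**base, "iac": psa.iac, "method": "psa", "status": "ok"})
            except DomainError as exc:
                rows.append({**base, "iac": ds_spec_value, "method": "ds_spec_fallback",
                             "status": str(exc)})
    return pd.DataFrame(rows)


def compare_3sd(iac_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell comparison of PSA-derived iACs with the 3SD baseline.

    For impurities the relevant baseline is the upper 3SD limit; for purities
    the lower one. ``sd3_tighter`` is True where the 3SD limit would raise an
    alert before the OOS-based criterion does.
    """
    df = iac_table.copy()
    baseline = np.where(df["side"] == "upper", df["sd3_upper"], df["sd3_lower"])
    df["sd3_baseline"] = baseline
    with np.errstate(invalid="ignore"):
        tighter = np.where(
            df["side"] == "upper",
            df["sd3_baseline"] < df["iac"].astype(float),
            df["sd3_baseline"] > df["iac"].astype(float),
        )
    df["sd3_tighter"] = pd.array(tighter, dtype="boolean")
    df.loc[df["iac"].isna() | df["sd3_baseline"].isna(), "sd3_tighter"] = pd.NA
    return df
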