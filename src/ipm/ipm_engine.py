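"""Monte-Carlo concatenation of unit-operation models into a process chain.

Each simulated run draws process parameters from their normal operating
ranges, draws a performance value per unit operation from the fitted model's
predictive distribution, and passes each pool on as the next load. The result
is a drug-substance distribution per quality attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .unit_models import (
    IMPURITY,
    PREDICTIVE_T,
    RESPONSE_CLEARANCE,
    DomainError,
    Model,
    ProcessParameter,
    QualityAttribute,
    UnitOperation,
    model_clamps,
    predict_performance,
)


class SimulationError(RuntimeError):
    """Raised when the simulation itself is inconsistent (e.g. too many aborts)."""


class ConfigError(ValueError):
    """Raised for invalid chain/configuration structures; carries all violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


# ---------------------------------------------------------------------------
# Chain and configuration
# ---------------------------------------------------------------------------


@dataclass
class ProcessChain:
    """Ordered unit operations plus per-CQA modelled sub-ranges and inputs.

    ``initial_loads`` maps CQA name to (mean_log, sd_log) of the lognormal
    load entering the first modelled unit operation. ``pool_observations``
    holds manufacturing pool values per (uo_id, cqa) used for screening grids
    and 3SD baselines.
    """

    unit_operations: list[UnitOperation]
    cqas: list[QualityAttribute]
    modelled_ranges: dict[str, tuple[int, int]]
    initial_loads: dict[str, tuple[float, float]]
    pool_observations: dict[tuple[int, str], list[float]] = field(default_factory=dict)
    name: str = "process"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs: list[str] = []
        ids = [uo.id for uo in self.unit_operations]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            errs.append(f"unit operation ids must be strictly increasing, got {ids}")
        known = set(ids)
        cqa_names = {c.name for c in self.cqas}
        for cqa in self.cqas:
            rng = self.modelled_ranges.get(cqa.name)
            if rng is None:
                errs.append(f"no modelled range for CQA {cqa.name!r}")
                continue
            start, end = rng
            if start > end or start not in known or end not in known:
                errs.append(f"invalid modelled range {rng} for CQA {cqa.name!r}")
                continue
            if cqa.name not in self.initial_loads:
                errs.append(f"no initial load distribution for CQA {cqa.name!r}")
            for uo in self.unit_operations:
                if start <= uo.id <= end:
                    if uo.model_for(cqa.name) is None and cqa.name not in uo.fallback_ds_spec:
                        errs.append(
                            f"UO {uo.id} has neither a model nor a fallback flag for "
                            f"CQA {cqa.name!r}"
                        )
        for name in self.modelled_ranges:
            if name not in cqa_names:
                errs.append(f"modelled range given for unknown CQA {name!r}")
        if errs:
            raise ConfigError(errs)

    # -- lookups ----------------------------------------------------------
    def cqa(self, name: str) -> QualityAttribute:
        for c in self.cqas:
            if c.name == name:
                return c
        raise KeyError(name)

    def uo(self, uo_id: int) -> UnitOperation:
        for uo in self.unit_operations:
            if uo.id == uo_id:
                return uo
        raise KeyError(uo_id)

    def uo_index(self, uo_id: int) -> int:
        for i, uo in enumerate(self.unit_operations):
            if uo.id == uo_id:
                return i
        raise KeyError(uo_id)

    def modelled_uos(self, cqa: str) -> list[UnitOperation]:
        start, end = self.modelled_ranges[cqa]
        return [uo for uo in self.unit_operations if start <= uo.id <= end]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings; ``stream_key`` namespaces the RNG substreams so
    that e.g. sensitivity-analysis grid points share common random numbers."""

    n_runs: int = 800
    seed: int = 0
    pi_level: float = 0.95
    uncertainty_sampling: str = PREDICTIVE_T
    fixed_pool_overrides: Mapping[tuple[int, str], float] | None = None
    stream_key: tuple[int, ...] = ()
    max_abort_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigError([f"n_runs must be >= 1, got {self.n_runs}"])
        if not 0.0 < self.pi_level < 1.0:
            raise ConfigError([f"pi_level must be in (0, 1), got {self.pi_level}"])


@dataclass
class SimulationResult:
    """Pool trajectories per run, unit operation and CQA, plus event counts."""

    pools: np.ndarray  # [run, uo, cqa], NaN where not modelled / aborted
    uo_ids: list[int]
    cqa_names: list[str]
    aborted: np.ndarray  # bool [run, cqa]
    clamp_count: dict[str, int]
    cap_count: dict[str, int]
    override_count: dict[str, int]
    config: SimulationConfig
    ds_uo_id: dict[str, int]

    def ds_values(self, cqa: str) -> np.ndarray:
        ci = self.cqa_names.index(cqa)
        ui = self.uo_ids.index(self.ds_uo_id[cqa])
        vals = self.pools[~self.aborted[:, ci], ui, ci]
        return vals[np.isfinite(vals)]

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.pools.shape[0]):
            for ui, uo_id in enumerate(self.uo_ids):
                for ci, cqa in enumerate(self.cqa_names):
                    v = self.pools[r, ui, ci]
                    if np.isfinite(v):
                        rows.append((r, uo_id, cqa, v))
        return pd.DataFrame(rows, columns=["run", "uo_id", "cqa", "pool_value"])

    def summary(self) -> dict:
        out: dict = {
            "seed": self.config.seed,
            "n_runs": self.config.n_runs,
            "clamp_count": dict(self.clamp_count),
            "cap_count": dict(self.cap_count),
            "override_count": dict(self.override_count),
            "aborted": {c: int(self.aborted[:, i].sum()) for i, c in enumerate(self.cqa_names)},
            "ds": {},
        }
        for cqa in self.cqa_names:
            v = self.ds_values(cqa)
            out["ds"][cqa] = {
                "n": int(v.size),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "q05": float(np.quantile(v, 0.05)),
                "median": float(np.median(v)),
                "q95": float(np.quantile(v, 0.95)),
            }
        return out


# ---------------------------------------------------------------------------
# NOR sampling
# ---------------------------------------------------------------------------


def sample_nor(pp: ProcessParameter, rng: np.random.Generator) -> float:
    """Draw a process-parameter value from its normal operating range.

    Default: Normal(set_point, cv * |set_point|). The uniform variant matches
    that standard deviation; the truncated variant cuts at +/- 3 sd.
    """
    if pp.set_point == 0:
        raise DomainError(
            f"process parameter {pp.name!r}: set-point 0 needs an absolute sd, "
            "a coefficient of variation is undefined"
        )
    sd = pp.cv * abs(pp.set_point)
    if pp.distribution == "normal":
        return float(rng.normal(pp.set_point, sd))
    if pp.distribution == "uniform":
        half = math.sqrt(3.0) * sd
        return float(rng.uniform(pp.set_point - half, pp.set_point + half))
    # truncated_normal at +/- 3 sd via inverse-CDF on a bounded uniform
    from scipy import stats as _st

    a, b = -3.0, 3.0
    u = rng.uniform(_st.norm.cdf(a), _st.norm.cdf(b))
    return float(pp.set_point + sd * _st.norm.ppf(u))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _run_rng(config: SimulationConfig, cqa_index: int, run: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *config.stream_key, cqa_index, run])


def simulate_run(
    chain: ProcessChain,
    cqa: QualityAttribute,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, int]]:
    """One trajectory of pool values for a CQA through its modelled UO range.

    Returns (trajectory over all chain UOs, event counters). When a fixed
    pool override exists for this CQA, the simulation starts at the override
    (upstream UOs are skipped).
    """
    n_uos = len(chain.unit_operations)
    traj = np.full(n_uos, np.nan)
    events = {"clamped": 0, "capped": 0, "overridden": 0, "aborted": 0}

    uos = chain.modelled_uos(cqa.name)
    overrides = {
        uo_id: v
        for (uo_id, c), v in (config.fixed_pool_overrides or {}).items()
        if c == cqa.name
    }

    start_idx = 0
    if overrides:
        ov_uo = max(overrides)
        if not any(uo.id == ov_uo for uo in uos):
            raise DomainError(
                f"override UO {ov_uo} is outside the modelled range for {cqa.name!r}"
            )
        load = overrides[ov_uo]
        traj[chain.uo_index(ov_uo)] = load
        events["overridden"] += 1
        start_idx = next(i for i, uo in enumerate(uos) if uo.id == ov_uo) + 1
    else:
        mean_log, sd_log = chain.initial_loads[cqa.name]
        load = math.exp(mean_log + sd_log * rng.standard_normal())
    events["init_load"] = load

    for uo in uos[start_idx:]:
        model = uo.model_for(cqa.name)
        if model is None:
            pool = load  # fallback-flagged step: attribute assumed unchanged
        else:
            pp_values = {pp.name: sample_nor(pp, rng) for pp in uo.process_parameters}
            try:
                perf = predict_performance(
                    model,
                    pp_values,
                    load,
                    rng,
                    sampling=config.uncertainty_sampling,
                    pi_level=config.pi_level,
                )
            except OverflowError:
                events["aborted"] = 1
                return traj, events
            if model_clamps(model, load):
                events["clamped"] += 1
            if model.response_kind == RESPONSE_CLEARANCE:
                pool = load / perf
            else:
                pool = load * perf
        if cqa.is_percent and pool > 100.0:
            pool = 100.0
            events["capped"] += 1
        if not (np.isfinite(pool) and pool > 0):
            events["aborted"] = 1
            return traj, events
        traj[chain.uo_index(uo.id)] = pool
        load = pool
    return traj, events


def simulate(chain: ProcessChain, config: SimulationConfig) -> SimulationResult:
    """Run ``config.n_runs`` independent trajectories per CQA.

    Bit-for-bit reproducible for a fixed seed: every (cqa, run) pair owns an
    independent, deterministically derived RNG substream.
    """
    n_uos = len(chain.unit_operations)
    cqa_names = [c.name for c in chain.cqas]
    pools = np.full((config.n_runs, n_uos, len(cqa_names)), np.nan)
    aborted = np.zeros((config.n_runs, len(cqa_names)), dtype=bool)
    clamp_count = {c: 0 for c in cqa_names}
    cap_count = {c: 0 for c in cqa_names}
    override_count = {c: 0 for c in cqa_names}

    for ci, cqa in enumerate(chain.cqas):
        for r in range(config.n_runs):
            rng = _run_rng(config, ci, r)
            traj, events = simulate_run(chain, cqa, config, rng)
            pools[r, :, ci] = traj
            clamp_count[cqa.name] += events["clamped"]
            cap_count[cqa.name] += events["capped"]
            override_count[cqa.name] += events["overridden"]
            if events["aborted"]:
                aborted[r, ci] = True
        frac = aborted[:, ci].mean()
        if frac > config.max_abort_fraction:
            raise SimulationError(
                f"{frac:.0%} of runs aborted for CQA {cqa.name!r}: model/config inconsistency"
            )

    ds_uo_id = {c.name: chain.modelled_ranges[c.name][1] for c in chain.cqas}
    return SimulationResult(
        pools=pools,
        uo_ids=[uo.id for uo in chain.unit_operations],
        cqa_names=cqa_names,
        aborted=aborted,
        clamp_count=clamp_count,
        cap_count=cap_count,
        override_count=override_count,
        config=config,
        ds_uo_id=ds_uo_id,
    )


# ---------------------------------------------------------------------------
# Convergence scan
# ---------------------------------------------------------------------------


def convergence_scan(
    chain: ProcessChain,
    cqa: str,
    cycles: Sequence[int],
    n_repeats: int = 20,
    config: SimulationConfig | None = None,
    mean_center: bool = False,
) -> pd.DataFrame:
    """Across-repeat variance of the DS median and MAD vs. run count.

    For each cycle count, ``n_repeats`` independent simulations are run and
    the variance (over repeats) of the median and of the median absolute
    deviation of the drug-substance distribution is reported.
    """
    if n_repeats < 2:
        raise ConfigError(["n_repeats must be >= 2"])
    base = config or SimulationConfig()
    rows = []
    for n in cycles:
        medians = np.empty(n_repeats)
        mads = np.empty(n_repeats)
        for rep in range(n_repeats):
            cfg = replace(base, n_runs=int(n), stream_key=(*base.stream_key, int(n), rep))
            res = simulate(chain, cfg)
            ds = res.ds_values(cqa)
            medians[rep] = np.median(ds)
            mads[rep] = np.median(np.abs(ds - np.median(ds)))
        rows.append((int(n), float(np.var(medians, ddof=1)), float(np.var(mads, ddof=1))))
    out = pd.DataFrame(rows, columns=["cycles", "var_median", "var_mad"])
    if mean_center:
        out["var_median_centered"] = out["var_median"] - out["var_median"].mean()
        out["var_mad_centered"] = out["var_mad"] - out["var_mad"].mean()
    return out
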