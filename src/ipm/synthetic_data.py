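"""Synthetic processes, datasets and closed-form oracles.

Everything the other modules need for testing without proprietary data: a
fully specified 9-unit-operation downstream process with three quality
attributes and known generating models, designed-experiment and
manufacturing-run generators that write the package's CSV dialects, and an
analytic oracle for chains built purely from lognormal clearance
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ipm_engine import ProcessChain, SimulationConfig, simulate_run
from .unit_models import (
    IMPURITY,
    PURITY,
    RESPONSE_CLEARANCE,
    RESPONSE_YIELD,
    CombinedModel,
    DoEDataset,
    DoEModel,
    DomainError,
    FittedTerm,
    ManufacturingSC,
    ProcessParameter,
    QualityAttribute,
    SCModel,
    SpecLimit,
    Term,
    UnitOperation,
    scale_factor,
)

# ---------------------------------------------------------------------------
# Experimental designs
# ---------------------------------------------------------------------------


def design_table(
    design: str,
    factor_ranges: dict[str, tuple[float, float]],
    n_center: int = 3,
) -> pd.DataFrame:
    """Native-unit factor settings for one of the supported designs.

    * ``ofat`` — each factor at its low/high level with the others at center,
      plus one center run (5 levels for a single factor).
    * ``ccf`` — face-centered central composite: corners, face centers and
      ``n_center`` center runs (17 runs for 3 factors with 3 centers).
    * ``grid5x3`` — first factor at 5 levels crossed with the second at its
      extremes, plus one center run (11 runs).
    """
    factors = list(factor_ranges)
    centers = {f: 0.5 * (lo + hi) for f, (lo, hi) in factor_ranges.items()}
    rows: list[dict[str, float]] = []

    if design == "ofat":
        if len(factors) == 1:
            f = factors[0]
            lo, hi = factor_ranges[f]
            for v in np.linspace(lo, hi, 5):
                rows.append({f: float(v)})
        else:
            for f in factors:
                lo, hi = factor_ranges[f]
                for v in (lo, hi):
                    row = dict(centers)
                    row[f] = v
                    rows.append(row)
            rows.append(dict(centers))
    elif design == "ccf":
        import itertools

        for corner in itertools.product(*[factor_ranges[f] for f in factors]):
            rows.append(dict(zip(factors, corner)))
        for f in factors:
            for v in factor_ranges[f]:
                row = dict(centers)
                row[f] = v
                rows.append(row)
        for _ in range(n_center):
            rows.append(dict(centers))
    elif design == "grid5x3":
        if len(factors) != 2:
            raise DomainError("grid5x3 needs exactly 2 factors")
        f1, f2 = factors
        lo1, hi1 = factor_ranges[f1]
        lo2, hi2 = factor_ranges[f2]
        for v1 in np.linspace(lo1, hi1, 5):
            for v2 in (lo2, hi2):
                rows.append({f1: float(v1), f2: float(v2)})
        rows.append(dict(centers))
    else:
        raise DomainError(f"unknown design {design!r}")

    df = pd.DataFrame(rows)
    df.insert(0, "run_id", [f"R{i + 1:02d}" for i in range(len(df))])
    return df


@dataclass
class DoEStudy:
    """A generated designed experiment at one unit operation: factor settings
    in native units plus one response column per CQA."""

    uo_id: int
    design: str
    table: pd.DataFrame
    factor_ranges: dict[str, tuple[float, float]]
    slc: dict[str, float]
    response_kinds: dict[str, str]

    def response_col(self, cqa: str) -> str:
        return f"response_{cqa}"

    def to_doe_dataset(self, cqa: str) -> DoEDataset:
        return DoEDataset(
            cqa=cqa,
            response_kind=self.response_kinds[cqa],
            table=self.table,
            factor_ranges=dict(self.factor_ranges),
            response_col=self.response_col(cqa),
            slc_doe=self.slc[cqa],
            design=self.design,
        )


# ---------------------------------------------------------------------------
# True-model construction helpers
# ---------------------------------------------------------------------------


def _true_doe_model(
    cqa: str,
    response_kind: str,
    design: str,
    factor_ranges: dict[str, tuple[float, float]],
    intercept: float,
    effects: dict[Term, float],
    residual_sd: float,
    slc_doe: float,
    n_center: int = 3,
) -> DoEModel:
    """A DoEModel with chosen true coefficients whose prediction-variance
    bookkeeping comes from the canonical design matrix of ``design``."""
    tbl = design_table(design, factor_ranges, n_center=n_center)
    coded = {
        f: np.array([scale_factor(v, factor_ranges[f]) for v in tbl[f]]) for f in factor_ranges
    }
    terms = [Term("intercept")] + list(effects)
    cols = []
    for t in terms:
        if t.kind == "intercept":
            cols.append(np.ones(len(tbl)))
        elif t.kind == "main":
            cols.append(coded[t.factors[0]])
        elif t.kind == "quadratic":
            cols.append(coded[t.factors[0]] ** 2)
        else:
            cols.append(coded[t.factors[0]] * coded[t.factors[1]])
    X = np.column_stack(cols)
    xtx_inv = np.linalg.inv(X.T @ X)
    coeffs = [intercept] + [effects[t] for t in effects]
    fitted_terms = [FittedTerm(t, float(c)) for t, c in zip(terms, coeffs)]
    return DoEModel(
        cqa=cqa,
        response_kind=response_kind,
        terms=fitted_terms,
        residual_sd=residual_sd,
        dof=len(tbl) - len(terms),
        xtx_inv=xtx_inv,
        factor_ranges=dict(factor_ranges),
        slc_doe=slc_doe,
    )


def _true_sc_model(
    cqa: str,
    response_kind: str,
    mean_log_at: tuple[float, float],
    slope: float,
    residual_sd: float,
    training_load_range: tuple[float, float],
    n: int = 10,
) -> SCModel:
    """SCModel with a chosen slope, anchored so the mean log-response at load
    ``mean_log_at[0]`` equals ``mean_log_at[1]``."""
    anchor_load, anchor_log = mean_log_at
    intercept = anchor_log - slope * math.log(anchor_load)
    lo, hi = training_load_range
    lx = np.log(np.linspace(lo, hi, n))
    return SCModel(
        cqa=cqa,
        response_kind=response_kind,
        intercept=intercept,
        slope=slope,
        residual_sd=residual_sd,
        dof=n - 2,
        n=n,
        mean_logx=float(np.mean(lx)),
        sxx=float(np.sum((lx - np.mean(lx)) ** 2)),
        training_load_range=training_load_range,
        slope_p=0.001,
    )


# ---------------------------------------------------------------------------
# Default 9-UO process
# ---------------------------------------------------------------------------

HCP = "HCP"
AGG = "Aggregates"
MONO = "Monomer"


@dataclass
class SyntheticProcessSpec:
    """A synthetic process with known ground truth."""

    chain: ProcessChain
    doe_designs: dict[int, str]
    doe_n_center: dict[int, int]
    loq: dict[tuple[int, str], float]
    seed: int

    @property
    def cqas(self) -> list[QualityAttribute]:
        return self.chain.cqas


def _m(t: str) -> Term:
    return Term("main", (t,))


def make_default_process(seed: int = 0) -> SyntheticProcessSpec:
    """A 9-unit-operation downstream process with three quality attributes.

    One host-cell-protein-like impurity spanning four decades (modelled over
    UO 1-6), one aggregate-like percent impurity and one monomer-like percent
    purity (both modelled over UO 2-9). Model types mix DoE, load-dependence,
    combined and lognormal manufacturing descriptions; UO 7 is flagged to
    fall back to the drug-substance limit for the impurity whose assay
    saturates at the limit of quantification there.
    """
    cqas = [
        QualityAttribute(HCP, IMPURITY, "ng/mg", SpecLimit(upper=100.0)),
        QualityAttribute(AGG, IMPURITY, "%", SpecLimit(upper=2.0)),
        QualityAttribute(MONO, PURITY, "%", SpecLimit(lower=98.0)),
    ]

    pp_capture = [
        ProcessParameter("load_density", 30.0, design_range=(20.0, 40.0)),
        ProcessParameter("elution_pH", 3.6, design_range=(3.2, 4.0)),
    ]
    pp_vi = [ProcessParameter("stirrer_speed", 200.0, design_range=(150.0, 250.0))]
    pp_aex = [ProcessParameter("equilibration_pH", 7.5, design_range=(7.0, 8.0))]
    pp_cex = [
        ProcessParameter("elution_cond", 8.0, design_range=(6.0, 10.0)),
        ProcessParameter("elution_buffer_pH", 5.0, design_range=(4.5, 5.5)),
    ]
    pp_hic = [
        ProcessParameter("loading_pH", 7.0, design_range=(6.5, 7.5)),
        ProcessParameter("loading_cond", 5.0, design_range=(3.0, 7.0)),
        ProcessParameter("loading_temp", 22.0, design_range=(18.0, 26.0)),
    ]

    capture_ranges = {pp.name: pp.design_range for pp in pp_capture}
    cex_ranges = {pp.name: pp.design_range for pp in pp_cex}
    hic_ranges = {pp.name: pp.design_range for pp in pp_hic}

    # UO2 capture: HCP combined model (OFAT DoE + load dependence)
    hcp_capture_doe = _true_doe_model(
        HCP, RESPONSE_CLEARANCE, "ofat", capture_ranges,
        intercept=math.log(100.0),
        effects={_m("load_density"): 0.30, _m("elution_pH"): 0.10},
        residual_sd=0.08, slc_doe=4.8e5,
    )
    hcp_capture_sc = _true_sc_model(
        HCP, RESPONSE_CLEARANCE, mean_log_at=(4.8e5, math.log(100.0)),
        slope=0.25, residual_sd=0.06, training_load_range=(1.5e5, 1.5e6),
    )

    # UO6 CEX DoE models
    hcp_cex_doe = _true_doe_model(
        HCP, RESPONSE_CLEARANCE, "grid5x3", cex_ranges,
        intercept=math.log(3.0),
        effects={_m("elution_cond"): 0.25, _m("elution_buffer_pH"): 0.12},
        residual_sd=0.08, slc_doe=160.0, n_center=1,
    )
    agg_cex_doe = _true_doe_model(
        AGG, RESPONSE_CLEARANCE, "grid5x3", cex_ranges,
        intercept=math.log(1.5),
        effects={_m("elution_cond"): 0.10, _m("elution_buffer_pH"): -0.06},
        residual_sd=0.04, slc_doe=3.2, n_center=1,
    )
    mono_cex_doe = _true_doe_model(
        MONO, RESPONSE_YIELD, "grid5x3", cex_ranges,
        intercept=math.log(1.012),
        effects={_m("elution_cond"): 0.004},
        residual_sd=0.002, slc_doe=95.5, n_center=1,
    )
    mono_cex_sc = _true_sc_model(
        MONO, RESPONSE_YIELD, mean_log_at=(95.5, math.log(1.012)),
        slope=0.02, residual_sd=0.0015, training_load_range=(92.0, 99.0),
    )

    # UO8 HIC DoE model for aggregates
    agg_hic_doe = _true_doe_model(
        AGG, RESPONSE_CLEARANCE, "ccf", hic_ranges,
        intercept=math.log(1.6),
        effects={
            _m("loading_pH"): 0.12,
            _m("loading_cond"): 0.08,
            Term("interaction", ("loading_cond", "loading_pH")): 0.05,
        },
        residual_sd=0.05, slc_doe=2.1,
    )

    uos = [
        UnitOperation(1, "Harvest", [
            ProcessParameter("pool_temperature", 12.0, design_range=(8.0, 16.0)),
        ], {
            HCP: ManufacturingSC(HCP, RESPONSE_CLEARANCE, math.log(1.05), 0.06, 10),
        }),
        UnitOperation(2, "Capture Chromatography", pp_capture, {
            HCP: CombinedModel(hcp_capture_doe, hcp_capture_sc),
            AGG: ManufacturingSC(AGG, RESPONSE_CLEARANCE, math.log(1.5), 0.05, 10),
            MONO: ManufacturingSC(MONO, RESPONSE_YIELD, math.log(1.020), 0.0025, 10),
        }),
        UnitOperation(3, "Virus Inactivation", pp_vi, {
            HCP: ManufacturingSC(HCP, RESPONSE_CLEARANCE, math.log(1.2), 0.05, 10),
            AGG: ManufacturingSC(AGG, RESPONSE_CLEARANCE, math.log(1.0), 0.03, 10),
            MONO: ManufacturingSC(MONO, RESPONSE_YIELD, 0.0, 0.0015, 10),
        }),
        UnitOperation(4, "Depth Filtration", [], {
            HCP: _true_sc_model(HCP, RESPONSE_CLEARANCE, (4000.0, math.log(2.2)),
                                slope=0.20, residual_sd=0.07,
                                training_load_range=(1500.0, 9000.0)),
            AGG: _true_sc_model(AGG, RESPONSE_CLEARANCE, (4.0, math.log(1.05)),
                                slope=0.15, residual_sd=0.03,
                                training_load_range=(2.0, 7.0)),
            MONO: _true_sc_model(MONO, RESPONSE_YIELD, (94.9, math.log(1.010)),
                                 slope=0.05, residual_sd=0.0015,
                                 training_load_range=(90.0, 98.0)),
        }),
        UnitOperation(5, "AEX Chromatography", pp_aex, {
            HCP: _true_sc_model(HCP, RESPONSE_CLEARANCE, (1900.0, math.log(12.0)),
                                slope=0.30, residual_sd=0.10,
                                training_load_range=(700.0, 4500.0)),
            AGG: _true_sc_model(AGG, RESPONSE_CLEARANCE, (3.8, math.log(1.2)),
                                slope=0.10, residual_sd=0.04,
                                training_load_range=(2.0, 6.5)),
            MONO: ManufacturingSC(MONO, RESPONSE_YIELD, math.log(1.012), 0.002, 10),
        }),
        UnitOperation(6, "CEX Chromatography", pp_cex, {
            HCP: hcp_cex_doe,
            AGG: agg_cex_doe,
            MONO: CombinedModel(mono_cex_doe, mono_cex_sc),
        }),
        UnitOperation(7, "Viral Filtration", [], {
            AGG: ManufacturingSC(AGG, RESPONSE_CLEARANCE, math.log(1.02), 0.01, 10),
            MONO: ManufacturingSC(MONO, RESPONSE_YIELD, math.log(1.001), 0.001, 10),
        }, fallback_ds_spec={HCP}),
        UnitOperation(8, "HIC Chromatography", pp_hic, {
            AGG: agg_hic_doe,
            MONO: _true_sc_model(MONO, RESPONSE_YIELD, (98.2, math.log(1.010)),
                                 slope=0.04, residual_sd=0.002,
                                 training_load_range=(95.0, 100.0)),
        }),
        UnitOperation(9, "Ultra/Diafiltration", [], {
            AGG: ManufacturingSC(AGG, RESPONSE_CLEARANCE, 0.0, 0.03, 10),
            MONO: ManufacturingSC(MONO, RESPONSE_YIELD, 0.0, 0.001, 10),
        }),
    ]

    chain = ProcessChain(
        unit_operations=uos,
        cqas=cqas,
        modelled_ranges={HCP: (1, 6), AGG: (2, 9), MONO: (2, 9)},
        initial_loads={
            HCP: (math.log(5.0e5), 0.15),
            AGG: (math.log(6.0), 0.12),
            MONO: (math.log(93.0), 0.004),
        },
        name="synthetic-mab-downstream",
    )
    return SyntheticProcessSpec(
        chain=chain,
        doe_designs={2: "ofat", 6: "grid5x3", 8: "ccf"},
        doe_n_center={2: 1, 6: 1, 8: 3},
        loq={(7, HCP): 0.5},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_manufacturing_runs(
    spec: SyntheticProcessSpec, n: int = 10, seed: int | None = None
) -> pd.DataFrame:
    """Paired load/pool values per batch, UO and CQA from the true chain.

    Runs are simulated at set-point conditions with NOR-sampled process
    parameters. CQAs flagged with a limit of quantification at a UO are
    written as ``<LOQ:x`` markers instead of numeric pools.
    """
    seed = spec.seed if seed is None else seed
    chain = spec.chain
    cfg = SimulationConfig(n_runs=n, seed=seed, stream_key=(101,))
    rows: list[tuple] = []
    for ci, cqa in enumerate(chain.cqas):
        start, _end = chain.modelled_ranges[cqa.name]
        for r in range(n):
            rng = np.random.default_rng([cfg.seed, *cfg.stream_key, ci, r])
            traj, events = simulate_run(chain, cqa, cfg, rng)
            load = events["init_load"]
            batch = f"B{r + 1:03d}"
            for uo in chain.modelled_uos(cqa.name):
                pool = traj[chain.uo_index(uo.id)]
                if not np.isfinite(pool):
                    break
                rows.append((batch, uo.id, cqa.name, load, float(pool), "manufacturing"))
                load = float(pool)
    df = pd.DataFrame(
        rows, columns=["batch_id", "uo_id", "cqa", "load_value", "pool_value", "scale"]
    )
    # LOQ-saturated cells: the assay reports only its quantification limit.
    loq_rows = []
    for (uo_id, cqa_name), loq in spec.loq.items():
        for r in range(n):
            loq_rows.append(
                (f"B{r + 1:03d}", uo_id, cqa_name, f"<LOQ:{loq}", f"<LOQ:{loq}", "manufacturing")
            )
    if loq_rows:
        df = pd.concat(
            [df, pd.DataFrame(loq_rows, columns=df.columns)], ignore_index=True
        )
    return df.sort_values(["cqa", "uo_id", "batch_id"], kind="stable").reset_index(drop=True)


def generate_doe(
    spec: SyntheticProcessSpec,
    uo_id: int,
    design: str | None = None,
    n_center: int | None = None,
    seed: int | None = None,
) -> DoEStudy:
    """Designed-experiment dataset for a UO from its true DoE models."""
    seed = spec.seed if seed is None else seed
    chain = spec.chain
    uo = chain.uo(uo_id)
    design = design or spec.doe_designs.get(uo_id)
    if design is None:
        raise DomainError(f"UO {uo_id} has no designed experiment")
    n_center = spec.doe_n_center.get(uo_id, 3) if n_center is None else n_center

    doe_models: dict[str, DoEModel] = {}
    for cqa_name, model in uo.models.items():
        if isinstance(model, DoEModel):
            doe_models[cqa_name] = model
        elif isinstance(model, CombinedModel):
            doe_models[cqa_name] = model.doe
    if not doe_models:
        raise DomainError(f"UO {uo_id} has no DoE-backed models")

    factor_ranges = {
        pp.name: pp.design_range for pp in uo.process_parameters if pp.design_range
    }
    tbl = design_table(design, factor_ranges, n_center=n_center)
    rng = np.random.default_rng([seed, 202, uo_id])
    slc: dict[str, float] = {}
    response_kinds: dict[str, str] = {}
    for cqa_name, model in sorted(doe_models.items()):
        means = np.array(
            [model.mean_log({f: row[f] for f in factor_ranges}) for _, row in tbl.iterrows()]
        )
        noise = rng.standard_normal(len(tbl)) * model.residual_sd
        tbl[f"response_{cqa_name}"] = np.exp(means + noise)
        slc[cqa_name] = model.slc_doe
        response_kinds[cqa_name] = model.response_kind
    return DoEStudy(
        uo_id=uo_id,
        design=design,
        table=tbl,
        factor_ranges=factor_ranges,
        slc=slc,
        response_kinds=response_kinds,
    )


def attach_pool_observations(chain: ProcessChain, mfg: pd.DataFrame) -> None:
    """Populate the chain's per-(UO, CQA) manufacturing pool observations."""
    numeric = mfg[pd.to_numeric(mfg["pool_value"], errors="coerce").notna()]
    for (uo_id, cqa), grp in numeric.groupby(["uo_id", "cqa"]):
        chain.pool_observations[(int(uo_id), str(cqa))] = [
            float(v) for v in grp["pool_value"]
        ]


# ---------------------------------------------------------------------------
# Analytic oracle chains
# ---------------------------------------------------------------------------


def make_oracle_chain(
    n_uos: int = 4,
    clearance: float = 10.0,
    sd_log: float = 0.1,
    init_mean: float = 1.0e4,
    init_sd_log: float = 0.1,
    upper_limit: float = 1.7,
    cqa_name: str = "imp",
) -> ProcessChain:
    """An impurity chain of pure lognormal clearances with closed-form DS
    distribution, OOS probability and acceptance-criterion inverse."""
    cqa = QualityAttribute(cqa_name, IMPURITY, "ng/mg", SpecLimit(upper=upper_limit))
    uos = [
        UnitOperation(k, f"UO{k}", [], {
            cqa_name: ManufacturingSC(cqa_name, RESPONSE_CLEARANCE, math.log(clearance), sd_log, 10),
        })
        for k in range(1, n_uos + 1)
    ]
    return ProcessChain(
        unit_operations=uos,
        cqas=[cqa],
        modelled_ranges={cqa_name: (1, n_uos)},
        initial_loads={cqa_name: (math.log(init_mean), init_sd_log)},
        name="oracle-chain",
    )


def seed_pool_observations(chain: ProcessChain, n: int = 10, seed: int = 0) -> None:
    """Draw manufacturing-like pool observations from the analytic pool
    distributions of a lognormal-clearance-only chain."""
    for cqa in chain.cqas:
        oracle = analytic_chain_oracle(chain, cqa.name)
        for uo_id, (m, s) in oracle.pool_log_params.items():
            rng = np.random.default_rng([seed, 303, uo_id])
            chain.pool_observations[(uo_id, cqa.name)] = [
                float(v) for v in np.exp(rng.normal(m, s, size=n))
            ]


def make_tight_3sd_process(seed: int = 0) -> ProcessChain:
    """A constructed impurity process whose 3SD pool limits are strictly
    tighter than the OOS-derived acceptance criteria at every early UO (the
    generous-specification, well-controlled-process regime).

    The DS limit is placed so that every upstream acceptance criterion sits
    between ~4 and ~7 pool standard deviations above the pool mean: inside
    the +/- 10 SD screening range but well above the 3 SD baseline.
    """
    chain = make_oracle_chain(upper_limit=2.5)
    seed_pool_observations(chain, n=24, seed=seed)
    return chain


@dataclass
class ChainOracle:
    """Closed-form summaries of a lognormal-clearance chain."""

    cqa: str
    ds_mean_log: float
    ds_sd_log: float
    spec: SpecLimit
    direction: str
    # per-UO analytic pool distribution (log-mean, log-sd) at set point
    pool_log_params: dict[int, tuple[float, float]] = field(default_factory=dict)
    # downstream aggregates per UO: sum of mean logs / rssq of sd logs below it
    downstream: dict[int, tuple[float, float]] = field(default_factory=dict)

    @staticmethod
    def _tail(diff: float, sd: float, upper: bool) -> float:
        if sd == 0.0:  # degenerate chain: a step at the limit
            beyond = diff < 0.0 if upper else diff > 0.0
            return 1.0 if beyond else 0.0
        return float(stats.norm.sf(diff / sd) if upper else stats.norm.cdf(diff / sd))

    def oos(self) -> float:
        """Tail area of the DS log-distribution beyond the (log) limit."""
        if self.direction == IMPURITY:
            return self._tail(math.log(self.spec.upper) - self.ds_mean_log,
                              self.ds_sd_log, upper=True)
        return self._tail(math.log(self.spec.lower) - self.ds_mean_log,
                          self.ds_sd_log, upper=False)

    def oos_at_pool(self, uo_id: int, pool: float) -> float:
        m_down, s_down = self.downstream[uo_id]
        if self.direction == IMPURITY:
            return self._tail(
                math.log(self.spec.upper) - (math.log(pool) - m_down), s_down, upper=True
            )
        return self._tail(
            math.log(self.spec.lower) - (math.log(pool) + m_down), s_down, upper=False
        )

    def iac(self, uo_id: int, threshold: float = 0.05) -> float:
        """Imposed pool at ``uo_id`` solving OOS(pool) = threshold."""
        m_down, s_down = self.downstream[uo_id]
        z = stats.norm.ppf(1.0 - threshold)
        if self.direction == IMPURITY:
            return math.exp(math.log(self.spec.upper) + m_down - z * s_down)
        return math.exp(math.log(self.spec.lower) - m_down + z * s_down)


def analytic_chain_oracle(chain: ProcessChain, cqa_name: str) -> ChainOracle:
    """Closed forms for a chain whose models are all lognormal clearances.

    On the log scale the drug-substance value is normal: the initial log-load
    minus (impurity) or plus (purity) the sum of the per-UO log means, with
    variances adding in quadrature.
    """
    cqa = chain.cqa(cqa_name)
    sign = -1.0 if cqa.direction == IMPURITY else 1.0
    uos = chain.modelled_uos(cqa_name)
    for uo in uos:
        model = uo.model_for(cqa_name)
        if not isinstance(model, ManufacturingSC):
            raise DomainError(
                f"analytic oracle requires pure ManufacturingSC models; UO {uo.id} has "
                f"{type(model).__name__}"
            )
    m0, s0 = chain.initial_loads[cqa_name]
    mean = m0
    var = s0**2
    pool_params: dict[int, tuple[float, float]] = {}
    for uo in uos:
        model = uo.model_for(cqa_name)
        mean += sign * model.mean_log
        var += model.sd_log**2
        pool_params[uo.id] = (mean, math.sqrt(var))

    downstream: dict[int, tuple[float, float]] = {}
    for i, uo in enumerate(uos):
        m_d = sum(u.model_for(cqa_name).mean_log for u in uos[i + 1:])
        v_d = sum(u.model_for(cqa_name).sd_log ** 2 for u in uos[i + 1:])
        downstream[uo.id] = (m_d, math.sqrt(v_d) if v_d > 0 else 0.0)

    ds_mean, ds_sd = pool_params[uos[-1].id]
    return ChainOracle(
        cqa=cqa_name,
        ds_mean_log=ds_mean,
        ds_sd_log=ds_sd,
        spec=cqa.ds_spec,
        direction=cqa.direction,
        pool_log_params=pool_params,
        downstream=downstream,
    )
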