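"""Domain types and per-unit-operation performance models.

A unit operation's performance for a quality attribute is described by one of
four model variants, all operating on the natural-log scale of the response
(specific clearance for impurities, yield for purities):

* :class:`DoEModel` — OLS regression of log-response on scaled process
  parameters, selected by exhaustive best-subset search under a strong
  heredity constraint.
* :class:`SCModel` — OLS regression of log-response on the log specific load
  concentration, fitted to manufacturing data.
* :class:`ManufacturingSC` — a normal distribution fitted to log-responses of
  manufacturing runs.
* :class:`CombinedModel` — a DoE model corrected multiplicatively by the
  load-dependence model, anchored at the DoE starting-material concentration.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

IMPURITY = "impurity"
PURITY = "purity"

RESPONSE_CLEARANCE = "specific_clearance"
RESPONSE_YIELD = "yield"

_PERCENT_UNITS = {"%", "percent"}


class DomainError(ValueError):
    """Raised when an input violates a model-domain precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecLimit:
    """One- or two-sided drug-substance specification limit."""

    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise DomainError("a specification limit needs at least one side")
        for side, v in (("lower", self.lower), ("upper", self.upper)):
            if v is not None and not math.isfinite(v):
                raise DomainError(f"{side} specification limit must be finite, got {v!r}")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise DomainError("lower specification limit must be below the upper limit")


@dataclass(frozen=True)
class QualityAttribute:
    """A critical quality attribute with its direction and DS specification.

    Impurities are cleared downwards and carry an upper limit; purities are
    kept up and carry a lower limit.
    """

    name: str
    direction: str
    unit: str
    ds_spec: SpecLimit

    def __post_init__(self) -> None:
        if self.direction not in (IMPURITY, PURITY):
            raise DomainError(f"direction must be impurity or purity, got {self.direction!r}")
        if self.direction == IMPURITY and self.ds_spec.upper is None:
            raise DomainError(f"impurity CQA {self.name!r} requires an upper specification limit")
        if self.direction == PURITY and self.ds_spec.lower is None:
            raise DomainError(f"purity CQA {self.name!r} requires a lower specification limit")
        if self.is_percent:
            for v in (self.ds_spec.lower, self.ds_spec.upper):
                if v is not None and not 0.0 <= v <= 100.0:
                    raise DomainError(
                        f"percent CQA {self.name!r} has out-of-range spec limit {v}"
                    )

    @property
    def is_percent(self) -> bool:
        return self.unit.strip().lower() in _PERCENT_UNITS

    @property
    def response_kind(self) -> str:
        return RESPONSE_CLEARANCE if self.direction == IMPURITY else RESPONSE_YIELD

    @property
    def risky_side(self) -> str:
        """Side of the spec towards which the attribute drifts out of spec."""
        return "upper" if self.direction == IMPURITY else "lower"


@dataclass(frozen=True)
class ProcessParameter:
    """A process parameter with its set-point and normal-operating-range width.

    The NOR is realised as a distribution around the set-point with standard
    deviation ``cv * |set_point|`` (default cv 3%).
    """

    name: str
    set_point: float
    cv: float = 0.03
    distribution: str = "normal"
    design_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise DomainError(f"process parameter {self.name!r}: cv must be > 0")
        if self.distribution not in ("normal", "uniform", "truncated_normal"):
            raise DomainError(
                f"process parameter {self.name!r}: unknown distribution {self.distribution!r}"
            )
        if self.design_range is not None:
            lo, hi = self.design_range
            if not lo < hi:
                raise DomainError(f"process parameter {self.name!r}: degenerate design range")
            if not lo <= self.set_point <= hi:
                raise DomainError(
                    f"process parameter {self.name!r}: set-point {self.set_point} outside "
                    f"design range [{lo}, {hi}]"
                )


# ---------------------------------------------------------------------------
# Performance indicators and factor scaling
# ---------------------------------------------------------------------------


def compute_specific_clearance(load: float, pool: float) -> float:
    """Load-to-pool ratio of specific concentrations; > 1 means clearance."""
    if not load > 0:
        raise DomainError(f"load must be positive, got {load}")
    if not pool > 0:
        raise DomainError(f"pool must be positive, got {pool}")
    return load / pool


def compute_yield(load: float, pool: float) -> float:
    """Pool-to-load ratio; the reciprocal of the specific clearance."""
    if not load > 0:
        raise DomainError(f"load must be positive, got {load}")
    if not pool > 0:
        raise DomainError(f"pool must be positive, got {pool}")
    return pool / load


def scale_factor(value: float, design_range: tuple[float, float]) -> float:
    """Affine map of a native value onto the [-1, 1] coded factor scale."""
    lo, hi = design_range
    if not lo < hi:
        raise DomainError(f"degenerate design range [{lo}, {hi}]")
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return (value - mid) / half


def unscale_factor(coded: float, design_range: tuple[float, float]) -> float:
    """Inverse of :func:`scale_factor`."""
    lo, hi = design_range
    if not lo < hi:
        raise DomainError(f"degenerate design range [{lo}, {hi}]")
    return 0.5 * (lo + hi) + coded * 0.5 * (hi - lo)


# ---------------------------------------------------------------------------
# Model terms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One candidate model term over coded factors."""

    kind: str  # intercept | main | interaction | quadratic | scale
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expect = {"intercept": 0, "main": 1, "interaction": 2, "quadratic": 1, "scale": 0}
        if self.kind not in expect:
            raise DomainError(f"unknown term kind {self.kind!r}")
        if len(self.factors) != expect[self.kind]:
            raise DomainError(f"term kind {self.kind!r} takes {expect[self.kind]} factor(s)")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "Intercept"
        if self.kind == "scale":
            return "scale"
        if self.kind == "main":
            return self.factors[0]
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return ":".join(self.factors)

    @property
    def parents(self) -> tuple["Term", ...]:
        """Main-effect terms implied by strong heredity."""
        if self.kind in ("interaction", "quadratic"):
            return tuple(Term("main", (f,)) for f in self.factors)
        return ()


@dataclass(frozen=True)
class FittedTerm:
    term: Term
    coefficient: float
    p_value: float | None = None


def _heredity_ok(terms: Sequence[Term]) -> bool:
    present = set(terms)
    return all(parent in present for t in terms for parent in t.parents)


# ---------------------------------------------------------------------------
# Plain OLS backend (fast enough for exhaustive best-subset enumeration)
# ---------------------------------------------------------------------------


@dataclass
class _OLSFit:
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    residual_sd: float
    dof: int
    xtx_inv: np.ndarray


def _ols(X: np.ndarray, y: np.ndarray) -> _OLSFit | None:
    """OLS fit returning None for singular or saturated designs."""
    n, p = X.shape
    dof = n - p
    if dof < 1:
        return None
    xtx = X.T @ X
    # Singular candidate designs are skipped, not force-inverted.
    if np.linalg.cond(xtx) > 1e10:
        return None
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    residuals = y - fitted
    rss = float(residuals @ residuals)
    sigma2 = rss / dof
    residual_sd = math.sqrt(sigma2)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    p_values = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return _OLSFit(beta, se, p_values, residuals, fitted, residual_sd, dof, xtx_inv)


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------


@dataclass
class DoEModel:
    """OLS model of log-response on coded process parameters."""

    cqa: str
    response_kind: str
    terms: list[FittedTerm]
    residual_sd: float
    dof: int
    xtx_inv: np.ndarray
    factor_ranges: dict[str, tuple[float, float]]
    slc_doe: float
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    selection_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise DomainError("residual_sd must be >= 0")
        if self.dof < 1:
            raise DomainError("dof must be >= 1")
        if not _heredity_ok([ft.term for ft in self.terms]):
            raise DomainError("term set violates strong heredity")
        for ft in self.terms:
            for f in ft.term.factors:
                if f not in self.factor_ranges:
                    raise DomainError(f"no design range stored for factor {f!r}")

    @property
    def factor_names(self) -> list[str]:
        seen: list[str] = []
        for ft in self.terms:
            for f in ft.term.factors:
                if f not in seen:
                    seen.append(f)
        return seen

    def design_vector(self, pp_values: Mapping[str, float]) -> np.ndarray:
        """Model-matrix row for native-unit PP values (manufacturing scale)."""
        coded: dict[str, float] = {}
        for f in self.factor_names:
            if f not in pp_values:
                raise DomainError(f"missing process parameter {f!r} for DoE prediction")
            coded[f] = scale_factor(pp_values[f], self.factor_ranges[f])
        row = np.empty(len(self.terms))
        for j, ft in enumerate(self.terms):
            t = ft.term
            if t.kind == "intercept":
                row[j] = 1.0
            elif t.kind == "scale":
                row[j] = 1.0  # predictions are made at the manufacturing level
            elif t.kind == "main":
                row[j] = coded[t.factors[0]]
            elif t.kind == "quadratic":
                row[j] = coded[t.factors[0]] ** 2
            else:
                row[j] = coded[t.factors[0]] * coded[t.factors[1]]
        return row

    def mean_log(self, pp_values: Mapping[str, float]) -> float:
        row = self.design_vector(pp_values)
        return float(row @ np.array([ft.coefficient for ft in self.terms]))

    def prediction_se(self, pp_values: Mapping[str, float]) -> float:
        """Std. error of a new observation (parameter + residual variance)."""
        row = self.design_vector(pp_values)
        leverage = float(row @ self.xtx_inv @ row)
        return self.residual_sd * math.sqrt(1.0 + max(leverage, 0.0))


@dataclass
class SCModel:
    """OLS model of log-response on log specific load concentration."""

    cqa: str
    response_kind: str
    intercept: float
    slope: float
    residual_sd: float
    dof: int
    n: int
    mean_logx: float
    sxx: float
    training_load_range: tuple[float, float]
    slope_p: float
    significant: bool = True
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.training_load_range[0] <= 0:
            raise DomainError("training load range must be positive")
        if self.residual_sd < 0:
            raise DomainError("residual_sd must be >= 0")

    def clamp_load(self, slc: float) -> tuple[float, bool]:
        """No-extrapolation rule: hold the response constant outside the
        observed load range (both sides)."""
        lo, hi = self.training_load_range
        if slc < lo:
            return lo, True
        if slc > hi:
            return hi, True
        return slc, False

    def mean_log(self, slc: float) -> float:
        if not slc > 0:
            raise DomainError(f"specific load concentration must be positive, got {slc}")
        slc_c, _ = self.clamp_load(slc)
        return self.intercept + self.slope * math.log(slc_c)

    def prediction_se(self, slc: float) -> float:
        slc_c, _ = self.clamp_load(slc)
        lx = math.log(slc_c)
        extra = 1.0 / self.n + (lx - self.mean_logx) ** 2 / self.sxx if self.sxx > 0 else 1.0 / self.n
        return self.residual_sd * math.sqrt(1.0 + extra)


@dataclass
class ManufacturingSC:
    """Lognormal description of the response from manufacturing runs."""

    cqa: str
    response_kind: str
    mean_log: float
    sd_log: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_log < 0:
            raise DomainError("sd_log must be >= 0")
        if self.n < 2:
            raise DomainError("ManufacturingSC requires n >= 2")


@dataclass
class CombinedModel:
    """DoE model with a deterministic load-dependence correction factor.

    The correction is the ratio of the SC-model mean prediction at the
    simulation load to the mean prediction at the DoE starting-material load,
    so the DoE model draw is the only stochastic component.
    """

    doe: DoEModel
    sc: SCModel

    def __post_init__(self) -> None:
        if self.doe.cqa != self.sc.cqa:
            raise DomainError("combined model parts must describe the same CQA")

    @property
    def cqa(self) -> str:
        return self.doe.cqa

    @property
    def response_kind(self) -> str:
        return self.doe.response_kind

    def log_correction(self, slc: float) -> float:
        return self.sc.mean_log(slc) - self.sc.mean_log(self.doe.slc_doe)


Model = DoEModel | SCModel | ManufacturingSC | CombinedModel


@dataclass
class UnitOperation:
    """One process step: its parameters and per-CQA performance models."""

    id: int
    name: str
    process_parameters: list[ProcessParameter] = field(default_factory=list)
    models: dict[str, Model] = field(default_factory=dict)
    fallback_ds_spec: set[str] = field(default_factory=set)

    def model_for(self, cqa: str) -> Model | None:
        return self.models.get(cqa)

    def pp_map(self) -> dict[str, ProcessParameter]:
        return {pp.name: pp for pp in self.process_parameters}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class DoEDataset:
    """A designed-experiment dataset for one UO x CQA response.

    ``table`` holds one row per run with native-unit factor columns and a
    strictly positive response column; ``design`` controls which candidate
    terms the resolution admits.
    """

    cqa: str
    response_kind: str
    table: "object"  # pandas.DataFrame
    factor_ranges: dict[str, tuple[float, float]]
    response_col: str
    slc_doe: float
    design: str = "ccf"  # ofat | ccf | grid5x3
    scale_col: str | None = None


def candidate_terms(design: str, factors: Sequence[str]) -> list[Term]:
    """Admissible non-intercept terms for a design's resolution."""
    mains = [Term("main", (f,)) for f in factors]
    if design == "ofat":
        return mains
    quads = [Term("quadratic", (f,)) for f in factors]
    if design == "grid5x3":
        return mains + quads
    if design == "ccf":
        inters = [
            Term("interaction", pair) for pair in itertools.combinations(sorted(factors), 2)
        ]
        return mains + inters + quads
    raise DomainError(f"unknown design {design!r}")


def _term_column(t: Term, coded: "dict[str, np.ndarray]", scale_ind: np.ndarray | None) -> np.ndarray:
    if t.kind == "intercept":
        return np.ones(len(next(iter(coded.values()))))
    if t.kind == "scale":
        assert scale_ind is not None
        return scale_ind
    if t.kind == "main":
        return coded[t.factors[0]]
    if t.kind == "quadratic":
        return coded[t.factors[0]] ** 2
    return coded[t.factors[0]] * coded[t.factors[1]]


def fit_doe_model(doe: DoEDataset, p_threshold: float = 0.1) -> DoEModel:
    """Best-subset OLS on the log response under strong heredity.

    Every heredity-respecting subset of the design's candidate terms is
    fitted; a subset is admissible when every term that is not forced in
    (heredity parents, scale fixed effect) has a partial-t p-value below
    ``p_threshold``. Among admissible subsets the largest wins, ties broken
    by the smallest residual standard deviation.
    """
    tbl = doe.table
    resp = np.asarray(tbl[doe.response_col], dtype=float)
    if np.any(~(resp > 0)):
        raise DomainError("responses must be strictly positive for the log transform")
    y = np.log(resp)

    factors = list(doe.factor_ranges)
    coded = {
        f: np.array([scale_factor(v, doe.factor_ranges[f]) for v in tbl[f]]) for f in factors
    }
    scale_ind: np.ndarray | None = None
    forced_base: list[Term] = []
    if doe.scale_col is not None and tbl[doe.scale_col].nunique() > 1:
        scale_ind = (np.asarray(tbl[doe.scale_col]) == "manufacturing").astype(float)
        forced_base.append(Term("scale"))

    cands = candidate_terms(doe.design, factors)
    selection_log: list[str] = []
    best: tuple[tuple[int, float], list[Term], _OLSFit] | None = None

    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            subset = list(combo)
            if not _heredity_ok(subset):
                continue
            terms = [Term("intercept")] + forced_base + subset
            X = np.column_stack([_term_column(t, coded, scale_ind) for t in terms])
            fit = _ols(X, y)
            if fit is None:
                selection_log.append(
                    f"skipped singular/saturated subset {[t.name for t in subset]}"
                )
                continue
            forced = set(forced_base)
            for t in subset:
                forced.update(t.parents)
            admissible = all(
                fit.p_values[j] < p_threshold
                for j, t in enumerate(terms)
                if t.kind != "intercept" and t not in forced
            )
            if not admissible:
                continue
            key = (len(subset), -fit.residual_sd)
            if best is None or key > best[0]:
                best = (key, terms, fit)

    if best is None:  # intercept-only always fits unless n < 2
        logger.warning("no admissible subset found for %s; falling back to intercept-only", doe.cqa)
        terms = [Term("intercept")]
        fit = _ols(np.ones((len(y), 1)), y)
        if fit is None:
            raise DomainError("too few runs to fit even an intercept-only model")
        selection_log.append("fallback: intercept-only")
    else:
        _, terms, fit = best

    fitted_terms = [
        FittedTerm(t, float(fit.beta[j]), float(fit.p_values[j])) for j, t in enumerate(terms)
    ]
    return DoEModel(
        cqa=doe.cqa,
        response_kind=doe.response_kind,
        terms=fitted_terms,
        residual_sd=fit.residual_sd,
        dof=fit.dof,
        xtx_inv=fit.xtx_inv,
        factor_ranges=dict(doe.factor_ranges),
        slc_doe=doe.slc_doe,
        residuals=fit.residuals,
        fitted=fit.fitted,
        selection_log=selection_log,
    )


def fit_sc_model(
    load: Sequence[float],
    pool: Sequence[float],
    cqa: str,
    response_kind: str = RESPONSE_CLEARANCE,
    p_threshold: float = 0.1,
) -> SCModel:
    """Log-log OLS of the performance indicator on the specific load
    concentration from paired manufacturing load/pool records."""
    load = np.asarray(load, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if len(load) != len(pool):
        raise DomainError("load and pool must be paired")
    if len(load) < 4:
        raise DomainError(f"SC model needs >= 4 records, got {len(load)}")
    if np.any(~(load > 0)) or np.any(~(pool > 0)):
        raise DomainError("all load and pool values must be positive")
    if response_kind == RESPONSE_CLEARANCE:
        resp = load / pool
    elif response_kind == RESPONSE_YIELD:
        resp = pool / load
    else:
        raise DomainError(f"unknown response kind {response_kind!r}")

    x = np.log(load)
    y = np.log(resp)
    X = np.column_stack([np.ones_like(x), x])
    fit = _ols(X, y)
    if fit is None:
        # Degenerate regressor (all loads equal): fall back to a flat line.
        mean = float(np.mean(y))
        sd = float(np.std(y, ddof=1))
        return SCModel(
            cqa=cqa,
            response_kind=response_kind,
            intercept=mean,
            slope=0.0,
            residual_sd=sd,
            dof=len(y) - 1,
            n=len(y),
            mean_logx=float(np.mean(x)),
            sxx=0.0,
            training_load_range=(float(load.min()), float(load.max())),
            slope_p=1.0,
            significant=False,
            residuals=y - mean,
            fitted=np.full_like(y, mean),
        )
    slope_p = float(fit.p_values[1])
    return SCModel(
        cqa=cqa,
        response_kind=response_kind,
        intercept=float(fit.beta[0]),
        slope=float(fit.beta[1]),
        residual_sd=fit.residual_sd,
        dof=fit.dof,
        n=len(y),
        mean_logx=float(np.mean(x)),
        sxx=float(np.sum((x - np.mean(x)) ** 2)),
        training_load_range=(float(load.min()), float(load.max())),
        slope_p=slope_p,
        significant=slope_p < p_threshold,
        residuals=fit.residuals,
        fitted=fit.fitted,
    )


def fit_manufacturing_sc(
    values: Sequence[float], cqa: str, response_kind: str = RESPONSE_CLEARANCE
) -> ManufacturingSC:
    """Normal fit to log performance values of manufacturing runs."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DomainError(f"ManufacturingSC needs n >= 2, got {len(v)}")
    if np.any(~(v > 0)):
        raise DomainError("all values must be positive")
    lv = np.log(v)
    return ManufacturingSC(
        cqa=cqa,
        response_kind=response_kind,
        mean_log=float(np.mean(lv)),
        sd_log=float(np.std(lv, ddof=1)),
        n=len(v),
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

PREDICTIVE_T = "predictive_t"
TRUNCATED_95 = "truncated_95"


def _t_draw(rng: np.random.Generator, dof: int, sampling: str, pi_level: float) -> float:
    if sampling == PREDICTIVE_T:
        return float(rng.standard_t(dof))
    if sampling == TRUNCATED_95:
        # Literal reading: the draw never leaves the central prediction interval.
        alpha = 0.5 * (1.0 - pi_level)
        u = rng.uniform(alpha, 1.0 - alpha)
        return float(stats.t.ppf(u, dof))
    raise DomainError(f"unknown uncertainty sampling mode {sampling!r}")


def predict_performance(
    model: Model,
    pp_values: Mapping[str, float] | None,
    slc: float,
    rng: np.random.Generator,
    sampling: str = PREDICTIVE_T,
    pi_level: float = 0.95,
) -> float:
    """One stochastic draw of the performance indicator on the natural scale.

    DoE and SC models draw a t-distributed prediction error around the mean
    log-prediction (scaled by the prediction standard error); manufacturing
    distributions draw from the fitted lognormal. Combined models multiply the
    DoE draw by a deterministic load-correction factor. SC-model loads are
    clamped to the training range (no extrapolation).
    """
    if not slc > 0:
        raise DomainError(f"specific load concentration must be positive, got {slc}")
    if isinstance(model, DoEModel):
        mean = model.mean_log(pp_values or {})
        if model.residual_sd == 0:
            return math.exp(mean)
        se = model.prediction_se(pp_values or {})
        return math.exp(mean + _t_draw(rng, model.dof, sampling, pi_level) * se)
    if isinstance(model, SCModel):
        mean = model.mean_log(slc)
        if model.residual_sd == 0:
            return math.exp(mean)
        se = model.prediction_se(slc)
        return math.exp(mean + _t_draw(rng, model.dof, sampling, pi_level) * se)
    if isinstance(model, ManufacturingSC):
        if model.sd_log == 0:
            return math.exp(model.mean_log)
        return math.exp(model.mean_log + model.sd_log * rng.standard_normal())
    if isinstance(model, CombinedModel):
        doe_draw = predict_performance(model.doe, pp_values, model.doe.slc_doe, rng, sampling, pi_level)
        return doe_draw * math.exp(model.log_correction(slc))
    raise DomainError(f"unknown model type {type(model).__name__}")


def model_clamps(model: Model, slc: float) -> bool:
    """True when the no-extrapolation clamp is active for this load value."""
    if isinstance(model, SCModel):
        return model.clamp_load(slc)[1]
    if isinstance(model, CombinedModel):
        return model.sc.clamp_load(slc)[1]
    return False


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Advisory residual checks: normality, constant variance, independence."""

    n: int
    normality_stat: float | None
    normality_p: float | None
    hetero_rho: float | None
    hetero_p: float | None
    lag1_autocorr: float | None
    degenerate: bool
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


def residual_diagnostics(model: Model, data: object | None = None) -> DiagnosticsReport:
    """Residual checks on a fitted OLS-backed model (DoE or SC variant)."""
    residuals = getattr(model, "residuals", None)
    fitted = getattr(model, "fitted", None)
    if residuals is None or fitted is None:
        raise DomainError("model carries no stored residuals")
    r = np.asarray(residuals, dtype=float)
    f = np.asarray(fitted, dtype=float)
    n = len(r)
    flags: list[str] = []

    if np.allclose(r, 0.0, atol=1e-12) or n < 3:
        return DiagnosticsReport(n, None, None, None, None, None, degenerate=True,
                                 flags=["degenerate: residuals are (numerically) zero or n < 3"])

    norm_stat, norm_p = stats.shapiro(r)
    if norm_p < 0.05:
        flags.append(f"normality rejected (Shapiro p={norm_p:.3g})")

    if np.ptp(f) > 0:
        het_rho, het_p = stats.spearmanr(np.abs(r), f)
        if het_p < 0.05:
            flags.append(f"heteroscedasticity suspected (|resid| vs fitted p={het_p:.3g})")
    else:
        het_rho, het_p = 0.0, 1.0

    lag1 = float(np.corrcoef(r[:-1], r[1:])[0, 1]) if n >= 4 else 0.0
    if abs(lag1) > 2.0 / math.sqrt(n):
        flags.append(f"run-order dependence suspected (lag-1 autocorr {lag1:.2f})")

    return DiagnosticsReport(
        n=n,
        normality_stat=float(norm_stat),
        normality_p=float(norm_p),
        hetero_rho=float(het_rho),
        hetero_p=float(het_p),
        lag1_autocorr=lag1,
        degenerate=False,
        flags=flags,
    )
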