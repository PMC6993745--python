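"""Specification-curve fitting, bootstrap inference, and summaries.

Each specification is an ordinary least-squares regression on the listwise
complete rows for its day type, with the outcome, the technology predictor,
and all continuous covariates z-scored on the analysed subsample (dichotomous
predictors included, so every coefficient lives on one standardized axis) and
factor covariates dummy-coded against their lowest level.  Classical
(non-robust) standard errors; two-sided coefficient t-tests.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import measures
from .grid import FIELDS, Specification

OUTCOME_COLUMNS = {
    "bedtime_retro": "bedtime_retro",
    "bedtime_diary": "onset_score",
    "total_sleep_retro": "total_sleep_retro",
}
PREDICTOR_COLUMNS = {
    "participation": "participation",
    "bedtime_use": "bedtime_use",
    "time_spent_diary": "time_spent",
    "time_spent_retro": "composite_screen",
}


class EngineError(ValueError):
    pass


class DegenerateSpecError(EngineError):
    """Zero variance in outcome or predictor after listwise deletion."""


class InsufficientDataError(EngineError):
    """Fewer analysed rows than model parameters."""


@dataclasses.dataclass
class SpecResult:
    spec_id: str
    beta: float
    se: float
    p: float
    n: int
    r2: float
    significant: bool
    status: str = "ok"
    spec: Specification | None = None
    error: str | None = None

    @classmethod
    def failed(cls, spec: Specification, status: str, error: str) -> "SpecResult":
        return cls(
            spec_id=spec.spec_id,
            beta=float("nan"),
            se=float("nan"),
            p=float("nan"),
            n=0,
            r2=float("nan"),
            significant=False,
            status=status,
            spec=spec,
            error=error,
        )


@dataclasses.dataclass
class BootstrapConfig:
    n_reps: int = 500
    seed: int = 0
    ci_level: float = 0.95

    def validate(self) -> None:
        if self.n_reps < 1:
            raise EngineError("n_reps must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise EngineError("ci_level must lie in (0, 1)")


@dataclasses.dataclass
class BootstrapResult:
    spec_ci: dict[str, tuple[float, float]]
    median_ci: dict[str, tuple[float, float]]
    rep_betas: np.ndarray  # n_reps x n_specs, grid order
    config: BootstrapConfig


@dataclasses.dataclass
class DayComparison:
    t_statistic: float
    df: int
    p: float
    mean_difference: float


@dataclasses.dataclass
class CorrelationMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    flagged: tuple[str, ...] = ()

    def r(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclasses.dataclass
class SCACurve:
    """Specification results ranked by beta, with optional bootstrap CIs."""

    results: list[SpecResult]
    alpha: float
    boot: BootstrapResult | None = None

    def ok_results(self) -> list[SpecResult]:
        return [r for r in self.results if r.status == "ok"]

    def median_beta(
        self,
        predicate: Callable[[Specification], bool] | None = None,
        **field_values: str,
    ) -> float:
        selected = [
            r.beta
            for r in self.ok_results()
            if (predicate is None or r.spec is None or predicate(r.spec))
            and all(getattr(r.spec, f) == v for f, v in field_values.items())
        ]
        if not selected:
            raise EngineError("median_beta: empty selection")
        return float(np.median(selected))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            row = {
                "rank": rank,
                "spec_id": r.spec_id,
                **{f: getattr(r.spec, f) if r.spec else "" for f in FIELDS},
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n": r.n,
                "r2": r.r2,
                "significant": r.significant,
                "status": r.status,
            }
            if self.boot is not None and r.spec_id in self.boot.spec_ci:
                row["ci_lower"], row["ci_upper"] = self.boot.spec_ci[r.spec_id]
            else:
                row["ci_lower"] = row["ci_upper"] = float("nan")
            rows.append(row)
        return pd.DataFrame(rows)


def curve_from_frame(frame: pd.DataFrame, alpha: float = 0.05) -> SCACurve:
    """Rebuild a curve from a results CSV (round-trips :meth:`to_frame`)."""
    results = []
    boot_ci: dict[str, tuple[float, float]] = {}
    for _, row in frame.iterrows():
        spec = Specification.from_id(row["spec_id"]) if "|" in str(row["spec_id"]) else None
        results.append(
            SpecResult(
                spec_id=row["spec_id"],
                beta=float(row["beta"]),
                se=float(row["se"]),
                p=float(row["p"]),
                n=int(row["n"]),
                r2=float(row["r2"]),
                significant=bool(row["significant"]),
                status=str(row["status"]),
                spec=spec,
            )
        )
        if "ci_lower" in row and np.isfinite(row.get("ci_lower", float("nan"))):
            boot_ci[row["spec_id"]] = (float(row["ci_lower"]), float(row["ci_upper"]))
    curve = SCACurve(results=results, alpha=alpha)
    if boot_ci:
        curve.boot = BootstrapResult(
            spec_ci=boot_ci, median_ci={}, rep_betas=np.empty((0, 0)), config=BootstrapConfig()
        )
    return curve


class _DayCache:
    """Numeric column arrays plus factor dummies for one day type."""

    def __init__(self, df: pd.DataFrame):
        self.n = len(df)
        self.cols: dict[str, np.ndarray] = {}
        for col in df.columns:
            if col in ("day_type",):
                continue
            if pd.api.types.is_numeric_dtype(df[col]) or pd.api.types.is_bool_dtype(df[col]):
                self.cols[col] = df[col].to_numpy(dtype=float)
        self.factor_dummies: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for factor in measures.FACTOR_COVARIATES:
            if factor not in df.columns:
                continue
            values = df[factor].to_numpy(dtype=float)
            ok = np.isfinite(values)
            levels = np.unique(values[ok])
            dummies = (
                (values[:, None] == levels[None, 1:]).astype(float)
                if levels.size > 1
                else np.empty((self.n, 0))
            )
            self.factor_dummies[factor] = (dummies, ok)


def _zscore(values: np.ndarray, what: str) -> np.ndarray:
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateSpecError(f"zero variance in {what} after listwise deletion")
    return (values - values.mean()) / sd


def _fit_ols(y: np.ndarray, X: np.ndarray, alpha: float) -> tuple[float, float, float, float]:
    """OLS of z-scored y on X (intercept in column 0, predictor in column 1)."""
    n, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        coef = np.linalg.solve(XtX, Xty)
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX)
        coef = XtX_inv @ Xty
    resid = y - X @ coef
    dof = n - k
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = rss / dof
    se = float(np.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se > 0:
        t_stat = beta / se
        p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    else:
        p = 0.0 if beta != 0 else 1.0
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return beta, se, p, float(np.clip(r2, 0.0, 1.0))


def _fit_from_cache(
    cache: _DayCache,
    outcome_col: str,
    predictor_col: str,
    control_cols: Sequence[str],
    alpha: float,
    spec_id: str,
    spec: Specification | None,
) -> SpecResult:
    y_raw = cache.cols[outcome_col]
    x_raw = cache.cols[predictor_col]
    mask = np.isfinite(y_raw) & np.isfinite(x_raw)
    continuous, factors = [], []
    for col in control_cols:
        if col in measures.FACTOR_COVARIATES:
            factors.append(col)
            mask &= cache.factor_dummies[col][1]
        else:
            continuous.append(col)
            mask &= np.isfinite(cache.cols[col])

    n = int(mask.sum())
    if n <= 2:
        raise InsufficientDataError(
            f"{spec_id}: n = {n} after listwise deletion"
        )
    columns = [np.ones(n), None]  # intercept + predictor placeholder
    y = _zscore(y_raw[mask], "outcome")
    columns[1] = _zscore(x_raw[mask], "predictor")
    for col in continuous:
        values = cache.cols[col][mask]
        sd = values.std(ddof=1) if values.size > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            continue  # constant covariate: collinear with the intercept, drop
        columns.append((values - values.mean()) / sd)
    for col in factors:
        dummies = cache.factor_dummies[col][0][mask]
        keep = dummies.sum(axis=0) > 0
        for j in np.flatnonzero(keep):
            columns.append(dummies[:, j])

    X = np.column_stack(columns)
    if n <= X.shape[1]:
        raise InsufficientDataError(
            f"{spec_id}: n = {n} <= {X.shape[1]} parameters after listwise deletion"
        )
    beta, se, p, r2 = _fit_ols(y, X, alpha)
    return SpecResult(
        spec_id=spec_id,
        beta=beta,
        se=se,
        p=p,
        n=n,
        r2=r2,
        significant=bool(p < alpha),
        spec=spec,
    )


def _day_caches(data: pd.DataFrame) -> dict[str, _DayCache]:
    return {
        str(day): _DayCache(group)
        for day, group in data.groupby("day_type", sort=True)
    }


def fit_spec(data: pd.DataFrame, spec: Specification, alpha: float = 0.05) -> SpecResult:
    """Fit one specification on the long derived-measures table.

    Raises :class:`DegenerateSpecError` / :class:`InsufficientDataError`;
    :func:`run_sca` converts these into flagged results instead.
    """
    cache = _DayCache(data[data["day_type"] == spec.day_type])
    return _fit_from_cache(
        cache,
        OUTCOME_COLUMNS[spec.sleep_measure],
        PREDICTOR_COLUMNS[spec.tech_measure],
        measures.covariate_set(spec.control_set),
        alpha,
        spec.spec_id,
        spec,
    )


def run_sca(
    data: pd.DataFrame, grid: Sequence[Specification], alpha: float = 0.05
) -> SCACurve:
    """Fit every specification and rank results by beta (failures flagged)."""
    if not grid:
        raise EngineError("empty specification grid")
    caches = _day_caches(data)
    results = []
    for spec in grid:
        try:
            cache = caches[spec.day_type]
            results.append(
                _fit_from_cache(
                    cache,
                    OUTCOME_COLUMNS[spec.sleep_measure],
                    PREDICTOR_COLUMNS[spec.tech_measure],
                    measures.covariate_set(spec.control_set),
                    alpha,
                    spec.spec_id,
                    spec,
                )
            )
        except DegenerateSpecError as exc:
            results.append(SpecResult.failed(spec, "degenerate", str(exc)))
        except (InsufficientDataError, KeyError) as exc:
            results.append(SpecResult.failed(spec, "insufficient_data", str(exc)))
    results.sort(key=lambda r: (np.isnan(r.beta), r.beta))
    return SCACurve(results=results, alpha=alpha)


def bootstrap_sca(
    data: pd.DataFrame,
    grid: Sequence[Specification],
    cfg: BootstrapConfig,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap over participants, re-running the full SCA.

    Each replicate resamples the participant table once (with replacement, at
    the original number of participants) and reuses it for every
    specification, preserving the cross-specification correlation of the
    curve.  Deterministic for a fixed seed.
    """
    cfg.validate()
    if not grid:
        raise EngineError("empty specification grid")
    rng = np.random.default_rng(cfg.seed)
    persons = np.sort(data["person_id"].unique())
    indexed = data.set_index("person_id")
    spec_ids = [s.spec_id for s in grid]
    day_types = sorted({s.day_type for s in grid})

    rep_betas = np.full((cfg.n_reps, len(grid)), np.nan)
    rep_medians: dict[str, np.ndarray] = {
        key: np.full(cfg.n_reps, np.nan) for key in ["overall", *day_types]
    }
    for rep in range(cfg.n_reps):
        ids = rng.choice(persons, size=persons.size, replace=True)
        sample = indexed.loc[ids].reset_index()
        curve = run_sca(sample, grid, alpha)
        betas = {r.spec_id: r.beta for r in curve.results}
        rep_betas[rep] = [betas[sid] for sid in spec_ids]
        ok = [r.beta for r in curve.ok_results()]
        if ok:
            rep_medians["overall"][rep] = np.median(ok)
        for day in day_types:
            day_ok = [r.beta for r in curve.ok_results() if r.spec and r.spec.day_type == day]
            if day_ok:
                rep_medians[day][rep] = np.median(day_ok)

    lo_q = 100.0 * (1.0 - cfg.ci_level) / 2.0
    hi_q = 100.0 - lo_q
    spec_ci = {}
    for j, sid in enumerate(spec_ids):
        col = rep_betas[:, j]
        finite = col[np.isfinite(col)]
        if finite.size:
            spec_ci[sid] = (
                float(np.percentile(finite, lo_q)),
                float(np.percentile(finite, hi_q)),
            )
        else:
            spec_ci[sid] = (float("nan"), float("nan"))
    median_ci = {}
    for key, values in rep_medians.items():
        finite = values[np.isfinite(values)]
        if finite.size:
            median_ci[key] = (
                float(np.percentile(finite, lo_q)),
                float(np.percentile(finite, hi_q)),
            )
    return BootstrapResult(
        spec_ci=spec_ci, median_ci=median_ci, rep_betas=rep_betas, config=cfg
    )


def compare_day_types(curve: SCACurve) -> DayComparison:
    """Paired two-sided t-test over weekday/weekend betas matched on the
    remaining three analytical decisions."""
    pairs: dict[tuple[str, str, str], dict[str, float]] = {}
    for r in curve.ok_results():
        if r.spec is None:
            continue
        key = (r.spec.sleep_measure, r.spec.tech_measure, r.spec.control_set)
        pairs.setdefault(key, {})[r.spec.day_type] = r.beta
    diffs = []
    for key, by_day in pairs.items():
        if set(by_day) != {"weekday", "weekend"}:
            raise EngineError(f"unmatched weekday/weekend pair for {key}")
        diffs.append(by_day["weekday"] - by_day["weekend"])
    if len(diffs) < 2:
        raise EngineError("need at least two matched pairs")
    d = np.asarray(diffs)
    k = d.size
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0.0:
        return DayComparison(t_statistic=0.0, df=k - 1, p=1.0, mean_difference=mean)
    t_stat = mean / (sd / np.sqrt(k))
    p = float(2.0 * stats.t.sf(abs(t_stat), k - 1))
    return DayComparison(t_statistic=float(t_stat), df=k - 1, p=p, mean_difference=mean)


def correlation_matrix(data: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations (zero-variance columns flagged)."""
    if len(variables) < 2:
        raise EngineError("correlation_matrix needs at least two variables")
    frame = data[list(variables)].astype(float)
    corr = frame.corr(method="pearson", min_periods=2)
    flagged = tuple(
        v for v in variables if frame[v].std(skipna=True) == 0 or frame[v].notna().sum() < 2
    )
    return CorrelationMatrix(
        labels=tuple(variables), values=corr.to_numpy(), flagged=flagged
    )


def difficulties_regression(
    data: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> SpecResult:
    """Standardized OLS of a sleep-difficulty item on the composite screen
    score with the full control set (person-level, day-invariant)."""
    if outcome not in ("fall_asleep_time", "night_waking"):
        raise EngineError(f"unknown difficulty outcome {outcome!r}")
    person_level = data.drop_duplicates(subset="person_id")
    cache = _DayCache(person_level)
    return _fit_from_cache(
        cache,
        outcome,
        "composite_screen",
        measures.covariate_set("all"),
        alpha,
        f"difficulties|{outcome}",
        None,
    )


@dataclasses.dataclass
class MinutesSeconds:
    sign: int
    minutes: int
    seconds: int


def coef_to_minutes(raw_coef: float) -> MinutesSeconds:
    """Translate an hours-scale raw coefficient into minutes and seconds."""
    total_seconds = int(round(abs(float(raw_coef)) * 3600.0))
    sign = 0 if raw_coef == 0 else (1 if raw_coef > 0 else -1)
    return MinutesSeconds(sign=sign, minutes=total_seconds // 60, seconds=total_seconds % 60)


def summarize(curve: SCACurve, by: str) -> pd.DataFrame:
    """Median beta, spec count, and significant count per level of a field."""
    if by not in FIELDS:
        raise EngineError(f"cannot summarize by {by!r}")
    rows = []
    levels = sorted({getattr(r.spec, by) for r in curve.ok_results() if r.spec})
    for level in levels:
        sel = [r for r in curve.ok_results() if r.spec and getattr(r.spec, by) == level]
        rows.append(
            {
                by: level,
                "median_beta": float(np.median([r.beta for r in sel])),
                "n_specs": len(sel),
                "n_significant": sum(r.significant for r in sel),
            }
        )
    return pd.DataFrame(rows)
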