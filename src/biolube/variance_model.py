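"""Pooled Taguchi ANOVA and the linear conversion model in physical units.

The ANOVA response is the raw per-run conversion.  Factor sums of squares
use the balanced-design form ``SS_j = r * sum_k (mean_jk - grand)^2`` with
``r`` runs per level; the saturated L9 leaves no error degrees of freedom,
so the smallest-SS factors are pooled into the error row until the error
has at least 2 DF.  Contributions are factor SS as a percentage of the
non-pooled factor SS.

The predictive model is an ordinary-least-squares fit of conversion on the
four factors in physical units (not level codes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from biolube.design import DesignTable, FactorSpec, validate_orthogonality

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "LinearModel",
    "ContourGrid",
    "ExtrapolationWarning",
    "taguchi_anova",
    "fit_linear_model",
    "predict_conversion",
    "contour_grid",
    "parity_data",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the design's factor ranges."""


@dataclass
class AnovaRow:
    name: str
    df: int
    ss: float
    ms: float | None
    f: float | None
    p: float | None
    contribution: float | None
    pooled: bool = False


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    error_df: int
    error_ss: float
    error_ms: float
    total_df: int
    total_ss: float
    degenerate: bool = False

    @property
    def pooled_factors(self) -> list[str]:
        return [r.name for r in self.rows if r.pooled]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "factor": r.name,
                "df": r.df,
                "ss": r.ss,
                "ms": r.ms,
                "F": r.f,
                "p": r.p,
                "contribution_pct": r.contribution,
                "pooled": r.pooled,
            }
            for r in self.rows
        ]
        recs.append(
            {
                "factor": "error (pooled)",
                "df": self.error_df,
                "ss": self.error_ss,
                "ms": self.error_ms,
                "F": None,
                "p": None,
                "contribution_pct": None,
                "pooled": False,
            }
        )
        recs.append(
            {
                "factor": "total",
                "df": self.total_df,
                "ss": self.total_ss,
                "ms": None,
                "F": None,
                "p": None,
                "contribution_pct": None,
                "pooled": False,
            }
        )
        return pd.DataFrame(recs)


@dataclass
class LinearModel:
    """Additive conversion model ``X = b0 + sum_j b_j * v_j`` (physical units)."""

    factor_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    residuals: np.ndarray
    r_squared: float
    design_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class ContourGrid:
    x_factor: str
    y_factor: str
    fixed: dict[str, float]
    x_values: np.ndarray
    y_values: np.ndarray
    grid: np.ndarray  # shape (len(y_values), len(x_values))


def taguchi_anova(
    design: DesignTable,
    responses: list[float],
    n_pool: int | None = None,
    min_error_df: int = 2,
) -> AnovaTable:
    """Balanced 3-level ANOVA with smallest-SS factor pooling.

    Parameters
    ----------
    responses : one conversion per run, in design run order.
    n_pool : number of factors to pool into the error row.  Default: pool
        smallest-SS factors one at a time until the error has at least
        ``min_error_df`` degrees of freedom (one factor for the L9).
    """
    report = validate_orthogonality(design)
    if not report.passed:
        raise ValueError(f"design is not balanced: {report.violations}")
    y = np.asarray(responses, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError("one response per run required")

    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())
    r = design.n_runs // 3  # runs per level

    ss: dict[str, float] = {}
    for j, name in enumerate(design.factor_names):
        col = design.levels[:, j]
        ss[name] = float(
            r * sum((y[col == k].mean() - grand) ** 2 for k in (1, 2, 3))
        )

    names = list(design.factor_names)
    if n_pool is None:
        n_pool = 0
        while n_pool * 2 < min_error_df:
            n_pool += 1
    if n_pool >= len(names):
        raise ValueError("cannot pool all factors")
    pooled = set(sorted(names, key=lambda f: (ss[f], names.index(f)))[:n_pool])

    error_df = 2 * len(pooled)
    error_ss = sum(ss[f] for f in pooled)
    error_ms = error_ss / error_df if error_df else float("nan")
    kept_ss = sum(ss[f] for f in names if f not in pooled)
    degenerate = kept_ss <= 0

    rows: list[AnovaRow] = []
    for name in names:
        if name in pooled:
            rows.append(
                AnovaRow(name=name, df=2, ss=ss[name], ms=None, f=None, p=None,
                         contribution=None, pooled=True)
            )
            continue
        ms = ss[name] / 2
        fstat = ms / error_ms if error_ms > 0 else float("inf")
        p = float(stats.f.sf(fstat, 2, error_df)) if np.isfinite(fstat) else 0.0
        contrib = 0.0 if degenerate else ss[name] / kept_ss * 100.0
        rows.append(
            AnovaRow(name=name, df=2, ss=ss[name], ms=ms, f=fstat, p=p,
                     contribution=contrib)
        )

    return AnovaTable(
        rows=rows,
        error_df=error_df,
        error_ss=error_ss,
        error_ms=error_ms,
        total_df=design.n_runs - 1,
        total_ss=total_ss,
        degenerate=degenerate,
    )


def fit_linear_model(physical: pd.DataFrame, responses: list[float]) -> LinearModel:
    """OLS of conversion on the factors in physical units.

    ``physical`` is the run x factor table of physical settings (a ``run``
    column, if present, is ignored).  Requires at least 5 runs and a
    full-rank design matrix.
    """
    cols = [c for c in physical.columns if c != "run"]
    y = np.asarray(responses, dtype=float)
    if len(y) != len(physical):
        raise ValueError("one response per run required")
    if len(y) < 5:
        raise ValueError("at least 5 runs required to fit 4 slopes + intercept")
    X = np.column_stack([np.ones(len(y))] + [physical[c].to_numpy(float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by checking rank without each one
        collinear = [
            c
            for i, c in enumerate(["intercept"] + cols)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    ranges = {c: (float(physical[c].min()), float(physical[c].max())) for c in cols}
    return LinearModel(
        factor_names=tuple(cols),
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        residuals=resid,
        r_squared=r2,
        design_ranges=ranges,
    )


def predict_conversion(
    model: LinearModel, settings: dict[str, float]
) -> tuple[float, bool]:
    """Predicted conversion (%) at physical settings, clamped to [0, 100].

    Returns ``(value, clamped)``.  Settings outside the fitted design range
    trigger an :class:`ExtrapolationWarning` but are not blocked.
    """
    x = model.intercept
    for f in model.factor_names:
        if f not in settings:
            raise ValueError(f"missing setting for factor {f!r}")
        v = float(settings[f])
        lo_hi = model.design_ranges.get(f)
        if lo_hi and not (lo_hi[0] <= v <= lo_hi[1]):
            warnings.warn(
                f"setting {f}={v} outside design range {lo_hi}", ExtrapolationWarning,
                stacklevel=2,
            )
        x += model.coefficients[f] * v
    clamped = not (0.0 <= x <= 100.0)
    return min(max(x, 0.0), 100.0), clamped


def contour_grid(
    model: LinearModel,
    x_factor: str,
    y_factor: str,
    fixed: dict[str, float],
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    resolution: int = 50,
) -> ContourGrid:
    """Predicted-conversion grid over two factors with the others fixed."""
    for f in (x_factor, y_factor):
        if f not in model.factor_names:
            raise ValueError(f"unknown factor {f!r}")
    if x_factor == y_factor:
        raise ValueError("x and y factors must differ")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    x_range = x_range or model.design_ranges[x_factor]
    y_range = y_range or model.design_ranges[y_factor]
    xs = np.linspace(x_range[0], x_range[1], resolution)
    ys = np.linspace(y_range[0], y_range[1], resolution)
    grid = np.empty((resolution, resolution))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        for iy, yv in enumerate(ys):
            for ix, xv in enumerate(xs):
                settings = dict(fixed)
                settings[x_factor] = xv
                settings[y_factor] = yv
                grid[iy, ix], _ = predict_conversion(model, settings)
    return ContourGrid(
        x_factor=x_factor, y_factor=y_factor, fixed=dict(fixed),
        x_values=xs, y_values=ys, grid=grid,
    )


def parity_data(
    model: LinearModel, physical: pd.DataFrame, responses: list[float]
) -> tuple[list[tuple[float, float]], float]:
    """(observed, predicted) pairs per run plus the max |residual|."""
    if len(responses) != len(physical):
        raise ValueError("responses length must match the design table")
    pairs: list[tuple[float, float]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        for obs, (_, row) in zip(responses, physical.iterrows()):
            settings = {f: float(row[f]) for f in model.factor_names}
            pred = model.intercept + sum(
                model.coefficients[f] * settings[f] for f in model.factor_names
            )
            pairs.append((float(obs), float(pred)))
    max_resid = max(abs(o - p) for o, p in pairs) if pairs else 0.0
    return pairs, max_resid


def ols_slope_closed_form(
    design: DesignTable, factor: str, spec: FactorSpec, responses: list[float]
) -> float:
    """Balanced-design closed form for a single factor's OLS slope.

    ``sum_k r (v_k - v_bar)(ybar_k - ybar) / sum_k r (v_k - v_bar)^2``.
    Provided for cross-checking against the full OLS fit; valid only on a
    balanced orthogonal design.
    """
    j = design.factor_names.index(factor)
    y = np.asarray(responses, dtype=float)
    col = design.levels[:, j]
    r = design.n_runs // 3
    vbar = np.mean(spec.levels)
    ybar = y.mean()
    num = sum(
        r * (spec.levels[k - 1] - vbar) * (y[col == k].mean() - ybar) for k in (1, 2, 3)
    )
    den = sum(r * (spec.levels[k - 1] - vbar) ** 2 for k in (1, 2, 3))
    return float(num / den)
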