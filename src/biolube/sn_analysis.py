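"""Larger-is-better signal-to-noise analysis for a balanced 3-level design.

All computation keeps full precision; the 2-decimal truncating and
half-up-rounding formatters are presentation-layer helpers that mirror the
display conventions commonly used when such tables are typeset.  Deltas in
the response table are computed from the half-up displayed level means so
the printed delta equals the difference of the printed means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np

from biolube.design import DesignTable, validate_orthogonality
from biolube.titration import RunResult

__all__ = [
    "SNEntry",
    "ResponseTable",
    "OptimumPrediction",
    "sn_larger_is_better",
    "sn_table",
    "response_table",
    "select_optimum",
    "predict_sn",
    "sn_to_response",
    "truncate2",
    "round_half_up",
]


def truncate2(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (display helper)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display helper)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SNEntry:
    run_id: int
    responses: list[float]
    n: int
    sn: float


@dataclass
class ResponseTable:
    """Per-factor level means of S/N (dB), deltas and ranks.

    ``level_means[f][k]`` is the full-precision mean S/N of the runs at
    level ``k+1`` of factor ``f``.  ``deltas`` are max - min of the
    2-decimal displayed level means; ``ranks`` assign 1 to the largest
    delta (ties broken by factor column order).
    """

    factor_names: tuple[str, ...]
    level_means: dict[str, list[float]]
    deltas: dict[str, float]
    ranks: dict[str, int]
    grand_mean: float

    def displayed_means(self, ndigits: int = 2) -> dict[str, list[float]]:
        return {
            f: [round_half_up(m, ndigits) for m in means]
            for f, means in self.level_means.items()
        }


@dataclass
class OptimumPrediction:
    levels: dict[str, int]
    predicted_sn_db: float
    predicted_conversion_pct: float
    capped: bool


def sn_larger_is_better(responses: list[float]) -> float:
    """Larger-is-better S/N in dB: ``-10 log10(mean(1/y_i^2))``.

    For a single response this reduces to ``20 log10(y)``.
    """
    if len(responses) < 1:
        raise ValueError("at least one response required")
    for y in responses:
        if y <= 0:
            raise ValueError(f"responses must be > 0, got {y}")
    mean_inv_sq = sum(1.0 / y**2 for y in responses) / len(responses)
    return -10.0 * math.log10(mean_inv_sq)


def sn_table(design: DesignTable, results: list[RunResult]) -> list[SNEntry]:
    """Per-run S/N from each run's mean conversion (n=1).

    The replicate-level values are typically unavailable downstream of
    aggregation, so the S/N is computed from the mean response; this is the
    n=1 form of the larger-is-better statistic.
    """
    by_run = {r.run_id: r for r in results}
    entries: list[SNEntry] = []
    for run_id in design.run_ids:
        if run_id not in by_run:
            raise ValueError(f"missing result for run {run_id}")
        r = by_run[run_id]
        entries.append(
            SNEntry(
                run_id=run_id,
                responses=[r.mean],
                n=1,
                sn=sn_larger_is_better([r.mean]),
            )
        )
    return entries


def response_table(design: DesignTable, sn: list[SNEntry]) -> ResponseTable:
    """Level means of S/N per factor, with deltas and delta ranking."""
    report = validate_orthogonality(design)
    if not report.passed:
        raise ValueError(f"design is not balanced: {report.violations}")
    by_run = {e.run_id: e.sn for e in sn}
    sn_vec = np.array([by_run[r] for r in design.run_ids])
    grand = float(sn_vec.mean())

    level_means: dict[str, list[float]] = {}
    deltas: dict[str, float] = {}
    for j, name in enumerate(design.factor_names):
        col = design.levels[:, j]
        means = [float(sn_vec[col == k].mean()) for k in (1, 2, 3)]
        level_means[name] = means
        disp = [round_half_up(m) for m in means]
        deltas[name] = round(max(disp) - min(disp), 10)

    order = sorted(
        range(len(design.factor_names)),
        key=lambda j: (-deltas[design.factor_names[j]], j),
    )
    ranks = {design.factor_names[j]: r + 1 for r, j in enumerate(order)}
    return ResponseTable(
        factor_names=design.factor_names,
        level_means=level_means,
        deltas=deltas,
        ranks=ranks,
        grand_mean=grand,
    )


def select_optimum(
    rt: ResponseTable, explicit_levels: dict[str, int] | None = None
) -> dict[str, int]:
    """Pick a level per factor.

    Default (argmax policy): the level with the largest mean S/N, ties
    resolved toward the lowest level index.  An ``explicit_levels`` mapping
    overrides the argmax choice verbatim (e.g. to reproduce a
    domain-motivated selection).
    """
    if explicit_levels is not None:
        for f, lvl in explicit_levels.items():
            if f not in rt.level_means:
                raise ValueError(f"unknown factor {f!r}")
            if lvl not in (1, 2, 3):
                raise ValueError(f"level for {f!r} must be 1..3, got {lvl}")
        return {f: int(explicit_levels[f]) for f in rt.factor_names}
    chosen: dict[str, int] = {}
    for f in rt.factor_names:
        means = rt.level_means[f]
        best = max(range(3), key=lambda k: (means[k], -k))
        chosen[f] = best + 1
    return chosen


def predict_sn(
    rt: ResponseTable,
    levels: dict[str, int],
    include_factors: list[str] | None = None,
) -> float:
    """Additive predicted S/N at the chosen levels.

    ``S/N_pred = grand + sum_j (mean_j(level_j) - grand)`` over the included
    factors (default: all), using full-precision level means.
    """
    factors = list(include_factors) if include_factors is not None else list(
        rt.factor_names
    )
    total = rt.grand_mean
    for f in factors:
        if f not in rt.level_means:
            raise ValueError(f"unknown factor {f!r}")
        lvl = levels[f]
        if lvl not in (1, 2, 3):
            raise ValueError(f"level for {f!r} must be 1..3, got {lvl}")
        total += rt.level_means[f][lvl - 1] - rt.grand_mean
    return total


def sn_to_response(sn: float) -> tuple[float, bool]:
    """Back-transform an n=1 S/N (dB) to a conversion (%): ``10^(sn/20)``.

    Values above 100% are capped at 100 with the capped flag set.
    """
    if not math.isfinite(sn):
        raise ValueError("sn must be finite")
    y = 10.0 ** (sn / 20.0)
    if y > 100.0:
        return 100.0, True
    return y, False


def predict_optimum(
    rt: ResponseTable,
    levels: dict[str, int],
    include_factors: list[str] | None = None,
) -> OptimumPrediction:
    """Bundle chosen levels, predicted S/N and back-transformed conversion."""
    sn = predict_sn(rt, levels, include_factors)
    conv, capped = sn_to_response(sn)
    return OptimumPrediction(
        levels=dict(levels),
        predicted_sn_db=sn,
        predicted_conversion_pct=conv,
        capped=capped,
    )
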