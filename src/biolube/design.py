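"""Taguchi L9(3^4) orthogonal array: construction, validation, level mapping.

Level indices are 1-based (L1..L3).  Physical factor values are bound to
level indices through :class:`FactorSpec`; the molar ratio is stored as the
numeric alcohol:acid mole ratio (1, 5, 9) — the ``1:n`` notation is a
display format only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "OrthogonalityReport",
    "build_l9",
    "map_levels",
    "invert_levels",
    "validate_orthogonality",
    "DEFAULT_FACTOR_NAMES",
]

DEFAULT_FACTOR_NAMES = ("MR", "Cat", "BL", "t")

# Canonical L9(3^4): columns are (A, B, A+B, A+2B) over GF(3), 1-based.
_L9 = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with exactly three ascending physical levels."""

    name: str
    unit: str
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if not self.unit:
            raise ValueError(f"factor {self.name!r}: unit must be non-empty")
        levels = tuple(float(v) for v in self.levels)
        if len(levels) != 3:
            raise ValueError(f"factor {self.name!r}: exactly 3 levels required")
        if not (levels[0] < levels[1] < levels[2]):
            raise ValueError(
                f"factor {self.name!r}: levels must be strictly increasing, got {levels}"
            )
        object.__setattr__(self, "levels", levels)

    def value(self, level_index: int) -> float:
        """Physical value at a 1-based level index."""
        if level_index not in (1, 2, 3):
            raise ValueError(f"level index must be 1..3, got {level_index}")
        return self.levels[level_index - 1]

    def level_of(self, value: float) -> int:
        """Invert a physical value back to its 1-based level index."""
        for i, v in enumerate(self.levels, start=1):
            if np.isclose(v, value, rtol=1e-9, atol=1e-12):
                return i
        raise ValueError(
            f"factor {self.name!r}: value {value} is not one of the declared levels {self.levels}"
        )


@dataclass
class DesignTable:
    """Run x factor layout of level indices (1..3), optionally with specs."""

    levels: np.ndarray  # shape (n_runs, n_factors), 1-based level indices
    factor_names: tuple[str, ...] = DEFAULT_FACTOR_NAMES
    factors: tuple[FactorSpec, ...] | None = None
    run_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.ndim != 2:
            raise ValueError("levels must be a 2-D run x factor array")
        if self.levels.shape[1] != len(self.factor_names):
            raise ValueError("factor_names length must match the number of columns")
        if not self.run_ids:
            self.run_ids = tuple(range(1, self.levels.shape[0] + 1))

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.factor_names))
        df.insert(0, "run", list(self.run_ids))
        return df


@dataclass
class OrthogonalityReport:
    passed: bool
    violations: list[str]


def build_l9(factor_names: tuple[str, ...] = DEFAULT_FACTOR_NAMES) -> DesignTable:
    """Return the canonical L9(3^4) orthogonal array as level indices."""
    if len(factor_names) != 4:
        raise ValueError("L9(3^4) accommodates exactly 4 factors")
    return DesignTable(levels=_L9.copy(), factor_names=tuple(factor_names))


def map_levels(design: DesignTable, factors: list[FactorSpec]) -> pd.DataFrame:
    """Map a design's level indices to physical settings per run.

    Returns a DataFrame with a ``run`` column followed by one physical-value
    column per factor (named after the factor specs).
    """
    if len(factors) != design.n_factors:
        raise ValueError(
            f"factor count mismatch: design has {design.n_factors} columns, "
            f"got {len(factors)} specs"
        )
    data = {"run": list(design.run_ids)}
    for j, spec in enumerate(factors):
        data[spec.name] = [spec.value(int(l)) for l in design.levels[:, j]]
    return pd.DataFrame(data)


def invert_levels(physical: pd.DataFrame, factors: list[FactorSpec]) -> DesignTable:
    """Invert a table of physical settings back to level indices."""
    levels = np.empty((len(physical), len(factors)), dtype=int)
    for j, spec in enumerate(factors):
        if spec.name not in physical.columns:
            raise ValueError(f"missing column {spec.name!r} in physical table")
        levels[:, j] = [spec.level_of(v) for v in physical[spec.name]]
    run_ids = (
        tuple(int(r) for r in physical["run"]) if "run" in physical.columns else ()
    )
    return DesignTable(
        levels=levels,
        factor_names=tuple(s.name for s in factors),
        factors=tuple(factors),
        run_ids=run_ids,
    )


def validate_orthogonality(design: DesignTable) -> OrthogonalityReport:
    """Check single-column balance and pairwise level-combination balance.

    Passes iff every level index appears equally often in each column and,
    for every pair of columns, each ordered level pair appears equally often
    (exactly once for the L9).
    """
    if design.n_runs < 1:
        raise ValueError("design must have at least one run")
    violations: list[str] = []
    n_levels = 3
    per_level = design.n_runs / n_levels
    for j, name in enumerate(design.factor_names):
        counts = np.bincount(design.levels[:, j], minlength=n_levels + 1)[1:]
        if not np.all(counts == per_level):
            violations.append(
                f"column {name!r} unbalanced: level counts {counts.tolist()}"
            )
    per_pair = design.n_runs / n_levels**2
    for (j1, n1), (j2, n2) in itertools.combinations(
        enumerate(design.factor_names), 2
    ):
        pairs = {}
        for a, b in zip(design.levels[:, j1], design.levels[:, j2]):
            pairs[(int(a), int(b))] = pairs.get((int(a), int(b)), 0) + 1
        bad = {p: c for p, c in pairs.items() if c != per_pair}
        if len(pairs) != n_levels**2 or bad:
            violations.append(f"columns ({n1!r}, {n2!r}) not pairwise balanced")
    return OrthogonalityReport(passed=not violations, violations=violations)
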