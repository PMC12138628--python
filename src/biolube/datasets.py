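"""Bundled example dataset: L9 esterification screening of a neem/tilapia
oil blend with a liquid lipase.

Four factors at three levels — alcohol:acid molar ratio (MR, stored as the
numeric ratio), biocatalyst load (Cat, %), oil blend (BL, % reference oil)
and reaction time (t, h) — with the measured conversion mean and triplicate
sd per run.  Used by the test suite and the acceptance script as a known
real-world input.
"""

from __future__ import annotations

from biolube.design import DesignTable, FactorSpec, build_l9
from biolube.titration import RunResult

__all__ = ["esterification_factors", "esterification_results", "esterification_design"]


def esterification_factors() -> list[FactorSpec]:
    return [
        FactorSpec("MR", "mol alcohol per mol acid", (1.0, 5.0, 9.0)),
        FactorSpec("Cat", "%", (5.0, 10.0, 15.0)),
        FactorSpec("BL", "%", (20.0, 50.0, 80.0)),
        FactorSpec("t", "h", (48.0, 72.0, 96.0)),
    ]


# (run, mean conversion %, triplicate sd %)
_RESULTS = [
    (1, 89.1, 0.1),
    (2, 86.0, 0.1),
    (3, 68.9, 0.1),
    (4, 81.0, 0.6),
    (5, 73.6, 0.3),
    (6, 78.6, 0.6),
    (7, 53.3, 0.2),
    (8, 82.0, 0.5),
    (9, 63.6, 0.6),
]


def esterification_results() -> list[RunResult]:
    return [RunResult.from_mean(r, m, s) for r, m, s in _RESULTS]


def esterification_design() -> DesignTable:
    design = build_l9()
    design.factors = tuple(esterification_factors())
    return design
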