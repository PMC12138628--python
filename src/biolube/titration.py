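"""Acidity index and fatty-acid conversion from NaOH titration records.

The acidity index is expressed in mg NaOH per g sample; with the titrant
volume in mL and the NaOH molar mass in g/mol the formula
``AI = MW * M * f * V / m`` yields mg/g directly.  Conversion is the
relative drop of the acidity index between the initial and final sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InvalidMeasurementError(ValueError):
    """A titration record violates its physical invariants."""


class NegativeConversionError(ValueError):
    """Final acidity exceeds initial acidity (titration inconsistency)."""


@dataclass(frozen=True)
class TitrationRecord:
    """One titration measurement.

    Parameters
    ----------
    mw_naoh : molar mass of NaOH in g/mol (caller-supplied, typically 40.00)
    molarity : NaOH solution molarity in mol/L
    f : standardization correction factor (dimensionless)
    v_naoh : titrant volume consumed, mL
    m : sample mass, g
    """

    mw_naoh: float
    molarity: float
    f: float
    v_naoh: float
    m: float

    def __post_init__(self) -> None:
        if self.mw_naoh <= 0:
            raise InvalidMeasurementError("mw_naoh must be > 0")
        if self.molarity <= 0:
            raise InvalidMeasurementError("molarity must be > 0")
        if self.f <= 0:
            raise InvalidMeasurementError("correction factor f must be > 0")
        if self.v_naoh < 0:
            raise InvalidMeasurementError("v_naoh must be >= 0")
        if self.m <= 0:
            raise InvalidMeasurementError("sample mass m must be > 0")


@dataclass(frozen=True)
class AcidityPair:
    """Initial and final acidity indices of one sample (mg NaOH/g)."""

    ai0: float
    ai: float

    def __post_init__(self) -> None:
        if self.ai0 <= 0:
            raise InvalidMeasurementError("initial acidity ai0 must be > 0")
        if self.ai < 0:
            raise InvalidMeasurementError("final acidity ai must be >= 0")


@dataclass
class RunResult:
    """Per-run conversion response: replicates, mean and sample sd (%)."""

    run_id: int
    replicates: list[float] = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")

    @classmethod
    def from_mean(cls, run_id: int, mean: float, sd: float = 0.0) -> "RunResult":
        return cls(run_id=run_id, replicates=[], mean=float(mean), sd=float(sd))


def acidity_index(rec: TitrationRecord) -> float:
    """Acidity index in mg NaOH per g sample: ``MW * M * f * V / m``."""
    return rec.mw_naoh * rec.molarity * rec.f * rec.v_naoh / rec.m


def conversion(pair: AcidityPair, clamp_negative: bool = False) -> float:
    """Fatty-acid conversion X (%) from the acidity drop.

    ``X = (ai0 - ai) / ai0 * 100``.  A final acidity above the initial one
    would imply negative conversion; that signals a measurement
    inconsistency and raises :class:`NegativeConversionError` unless
    ``clamp_negative`` is set, in which case 0 is returned.
    """
    x = (pair.ai0 - pair.ai) / pair.ai0 * 100.0
    if x < 0:
        if clamp_negative:
            return 0.0
        raise NegativeConversionError(
            f"final acidity {pair.ai} exceeds initial {pair.ai0}"
        )
    return x


def aggregate_replicates(run_id: int, conversions: list[float]) -> RunResult:
    """Aggregate replicate conversions into mean and sample sd (n-1).

    With a single replicate the sd is defined as 0.
    """
    if not conversions:
        raise ValueError("at least one replicate required")
    vals = [float(v) for v in conversions]
    n = len(vals)
    mean = sum(vals) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return RunResult(run_id=run_id, replicates=vals, mean=mean, sd=sd)
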