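"""Seeded synthetic-experiment generators and a parameter-recovery harness.

The generator emulates an additive linear factor->conversion response over
an L9 design with Gaussian run-level and replicate-level noise, and can
invert the titration equations to produce raw titration records whose
derived conversions hit specified targets exactly (before optional
volumetric noise).

Draw order (single seeded stream per experiment): for each run in design
order, one run-level normal draw, then ``n_replicates`` replicate-level
draws.  ``recovery_study`` spawns one child seed per replicate from a
:class:`numpy.random.SeedSequence`, so extending ``n_reps`` with the same
seed reproduces the earlier replicates verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from biolube.design import DesignTable, FactorSpec, map_levels
from biolube.sn_analysis import response_table, select_optimum, sn_table
from biolube.titration import RunResult, TitrationRecord, aggregate_replicates
from biolube.variance_model import fit_linear_model

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_titration_series",
    "recovery_study",
]

CLAMP_LO = 1.0  # keeps the S/N log defined
CLAMP_HI = 100.0


@dataclass
class GeneratorConfig:
    """Ground truth and noise structure for synthetic experiments."""

    beta0: float
    betas: dict[str, float]
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    n_replicates: int = 3
    replicate_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    beta0: float
    betas: dict[str, float]
    true_means: list[float]
    optimal_levels: dict[str, int]
    clamp_events: list[int]  # run ids whose true mean was clamped


def _true_mean(cfg: GeneratorConfig, settings: dict[str, float]) -> float:
    mu = cfg.beta0 + sum(cfg.betas[f] * settings[f] for f in cfg.betas)
    for (f1, f2), c in cfg.interactions.items():
        mu += c * settings[f1] * settings[f2]
    return mu


def _optimal_levels(cfg: GeneratorConfig, factors: list[FactorSpec]) -> dict[str, int]:
    # argmax of the additive true response per factor; ties -> lowest level
    out: dict[str, int] = {}
    for spec in factors:
        beta = cfg.betas.get(spec.name, 0.0)
        vals = [beta * v for v in spec.levels]
        out[spec.name] = max(range(3), key=lambda k: (vals[k], -k)) + 1
    return out


def generate_experiment(
    cfg: GeneratorConfig, design: DesignTable, factors: list[FactorSpec]
) -> tuple[list[RunResult], GroundTruth]:
    """Simulate replicate conversions for every run of the design.

    Replicates are ``clamp(mu) + run_noise + replicate_noise`` clamped to
    [1, 100]; clamp events on the deterministic means are logged and
    recorded in the ground-truth block.
    """
    rng = np.random.default_rng(cfg.seed)
    physical = map_levels(design, factors)
    results: list[RunResult] = []
    true_means: list[float] = []
    clamp_events: list[int] = []
    for run_id, (_, row) in zip(design.run_ids, physical.iterrows()):
        settings = {f.name: float(row[f.name]) for f in factors}
        mu = _true_mean(cfg, settings)
        mu_c = min(max(mu, CLAMP_LO), CLAMP_HI)
        if mu_c != mu:
            clamp_events.append(run_id)
            logger.warning("run %d: true mean %.3f clamped to %.3f", run_id, mu, mu_c)
        true_means.append(mu_c)
        run_eps = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        reps = []
        for _ in range(cfg.n_replicates):
            rep_eps = rng.normal(0.0, cfg.replicate_sd) if cfg.replicate_sd > 0 else 0.0
            reps.append(min(max(mu_c + run_eps + rep_eps, CLAMP_LO), CLAMP_HI))
        results.append(aggregate_replicates(run_id, reps))
    truth = GroundTruth(
        beta0=cfg.beta0,
        betas=dict(cfg.betas),
        true_means=true_means,
        optimal_levels=_optimal_levels(cfg, factors),
        clamp_events=clamp_events,
    )
    return results, truth


def generate_titration_series(
    targets: list[float],
    ai0: float,
    n_replicates: int = 3,
    mw_naoh: float = 40.0,
    molarity: float = 0.1,
    f: float = 1.0,
    sample_mass: float = 0.2,
    volume_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[list[tuple[TitrationRecord, TitrationRecord]]]:
    """Emit (initial, final) titration record pairs hitting target conversions.

    The titrant volumes are chosen by inverting the acidity-index and
    conversion formulas, so before noise the derived conversion equals the
    target exactly.  Optional Gaussian volumetric noise perturbs the final
    titrant volume (truncated at 0).
    """
    if ai0 <= 0:
        raise ValueError("ai0 must be > 0")
    rng = np.random.default_rng(seed)
    scale = mw_naoh * molarity * f / sample_mass  # AI per mL of titrant
    v0 = ai0 / scale
    series: list[list[tuple[TitrationRecord, TitrationRecord]]] = []
    for x in targets:
        if not (0.0 <= x <= 100.0):
            raise ValueError(f"target conversion must be in [0, 100], got {x}")
        pairs = []
        for _ in range(n_replicates):
            ai_final = ai0 * (1.0 - x / 100.0)
            v_final = ai_final / scale
            if volume_noise_sd > 0:
                v_final = max(v_final + rng.normal(0.0, volume_noise_sd), 0.0)
            initial = TitrationRecord(mw_naoh, molarity, f, v0, sample_mass)
            final = TitrationRecord(mw_naoh, molarity, f, v_final, sample_mass)
            pairs.append((initial, final))
        series.append(pairs)
    return series


def recovery_study(
    cfg: GeneratorConfig,
    design: DesignTable,
    factors: list[FactorSpec],
    n_reps: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate -> analyze ``n_reps`` synthetic experiments; summarize recovery.

    Each replicate regenerates the experiment with a spawned child seed,
    refits the linear model and recomputes the argmax-S/N optimum.  Returns
    a tidy summary with one row per coefficient (bias, RMSE) and one row
    per factor for the optimum-identification rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = base.spawn(n_reps)
    names = ["beta0"] + [f.name for f in factors]
    truth_vec = np.array(
        [cfg.beta0] + [cfg.betas.get(f.name, 0.0) for f in factors]
    )
    errors = np.empty((n_reps, len(names)))
    hits = np.zeros((n_reps, len(factors)), dtype=bool)

    cfg_rep = GeneratorConfig(
        beta0=cfg.beta0,
        betas=dict(cfg.betas),
        interactions=dict(cfg.interactions),
        noise_sd=cfg.noise_sd,
        n_replicates=cfg.n_replicates,
        replicate_sd=cfg.replicate_sd,
        seed=cfg.seed,
    )
    physical = map_levels(design, factors)
    for i, child in enumerate(children):
        cfg_rep.seed = child
        results, truth = generate_experiment(cfg_rep, design, factors)
        model = fit_linear_model(physical, [r.mean for r in results])
        est = np.array(
            [model.intercept] + [model.coefficients[f.name] for f in factors]
        )
        errors[i] = est - truth_vec
        rt = response_table(design, sn_table(design, results))
        chosen = select_optimum(rt)
        for j, spec in enumerate(factors):
            hits[i, j] = chosen[spec.name] == truth.optimal_levels[spec.name]

    rows = []
    for j, name in enumerate(names):
        rows.append(
            {
                "quantity": f"coef:{name}",
                "bias": float(errors[:, j].mean()),
                "rmse": float(np.sqrt((errors[:, j] ** 2).mean())),
                "identification_rate": np.nan,
            }
        )
    for j, spec in enumerate(factors):
        rows.append(
            {
                "quantity": f"optimum:{spec.name}",
                "bias": np.nan,
                "rmse": np.nan,
                "identification_rate": float(hits[:, j].mean()),
            }
        )
    rows.append(
        {
            "quantity": "optimum:overall",
            "bias": np.nan,
            "rmse": np.nan,
            "identification_rate": float(hits.all(axis=1).mean()),
        }
    )
    return pd.DataFrame(rows)
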