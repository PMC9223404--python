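"""Self-contained validation experiments: simulate, estimate, compare.

These runners wire the simulator and the estimator into the three perfect
model experiments used to validate the method: parameter recovery on
synthetic equilibria, AIC selection recovery across generator/estimator
model pairs, and the vertex-noise robustness protocol. They are used by the
``validate-suite`` CLI command, the test suite and the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimation import (
    PreprocessConfig,
    estimate,
    model_select,
    preprocess,
    recovered_parameters,
)
from .models import (
    ANISO_SPRING,
    CONVENTIONAL,
    ModelSpec,
    ParameterSet,
    all_aniso_spring_specs,
)
from .robustness import NoiseConfig, noise_resistance_test, true_normalized
from .simulator import SimConfig, SimResult, simulate_dataset

__all__ = [
    "REFERENCE_PARAMS",
    "CONVENTIONAL_PARAMS",
    "generator_params",
    "reference_sim_config",
    "sim_preprocess_config",
    "RecoveryResult",
    "run_recovery",
    "run_selection_matrix",
    "run_noise_test",
]

# reference parameter set of the anisotropic spring model:
# (lambda0, mu0, lambda1, mu1, k) = (0.2, 0.15, 0.03, 0.5, 1.0), A0 = 1
REFERENCE_PARAMS = ParameterSet(lambda0=0.2, mu0=0.15, phi0=0.0,
                                lambda1=0.03, mu1=0.5, phi1=0.0,
                                k=1.0, A0=1.0)

# typical conventional-model parameter set (Lambda0, Gamma) = (0.12, 0.04)
CONVENTIONAL_PARAMS = ParameterSet(lambda0=0.12, Gamma0=0.04, k=1.0, A0=1.0)


def generator_params(variant: str) -> ParameterSet:
    """Reference parameters restricted to one anisotropic-spring variant."""
    p = REFERENCE_PARAMS
    if variant == "A":
        return p
    if variant == "B":
        return p.replace(mu1=0.0)
    if variant == "C":
        return p.replace(mu0=0.0, mu1=0.0)
    if variant == "D":
        return p.replace(lambda1=0.0, mu1=0.0)
    if variant == "E":
        return p.replace(mu0=0.0, lambda1=0.0, mu1=0.0)
    raise ValueError(variant)


def reference_sim_config(variant: str = "A", tile: tuple[int, int] = (20, 20),
                         t_end: float = 5000.0, seed: int = 0,
                         family: str = ANISO_SPRING) -> SimConfig:
    """Simulation protocol for one generator model: dt = 0.1, t = 5000,
    followed by the simulator's default settling tail."""
    if family == CONVENTIONAL:
        spec = ModelSpec(CONVENTIONAL, "isotropic")
        params = CONVENTIONAL_PARAMS
    else:
        spec = ModelSpec(ANISO_SPRING, variant)
        params = generator_params(variant)
    return SimConfig(spec=spec, params=params, tile=tile, A0=params.A0,
                     dt=0.1, t_end=t_end, seed=seed)


def sim_preprocess_config(A0: float = 1.0) -> PreprocessConfig:
    """Preprocessing for simulated tissues: junction threshold 0.05 sqrt(A0)."""
    return PreprocessConfig(min_junction_length=0.05 * math.sqrt(A0))


@dataclass
class RecoveryResult:
    sim: SimResult
    estimates: dict[str, float]
    truth: dict[str, float]
    errors_pct: dict[str, float]   # signed 100 * (est - true) / true
    max_abs_error_pct: float
    aic: float


def run_recovery(sim_config: SimConfig, fit_spec: ModelSpec | None = None,
                 sim: SimResult | None = None) -> RecoveryResult:
    """Simulate one tissue and fit the generating (or given) model.

    Errors are reported on the dimensionless parameters (lambda0 and
    lambda1/Gamma0 normalized by k-hat and the target area) against the
    generator's ground truth, in percent.
    """
    if sim is None:
        sim = simulate_dataset(sim_config)
    spec = fit_spec if fit_spec is not None else sim_config.spec
    fit_result, report = estimate(sim.tissue, spec,
                                  sim_preprocess_config(sim_config.A0))
    est = recovered_parameters(fit_result, report, sim_config.A0)
    truth = true_normalized(spec, sim_config.params.replace(A0=sim_config.A0))
    errors = {k: 100.0 * (est[k] - v) / v
              for k, v in truth.items() if k in est and k != "k_rel"}
    return RecoveryResult(
        sim=sim,
        estimates=est,
        truth=truth,
        errors_pct=errors,
        max_abs_error_pct=max(abs(e) for e in errors.values()),
        aic=fit_result.aic,
    )


def run_selection_matrix(tile: tuple[int, int] = (10, 10), t_end: float = 2000.0,
                         seed: int = 0) -> dict:
    """Generate one dataset per model A-E and fit all five; return the AIC
    matrix (rows: generator, columns: estimator) and the diagonal check."""
    variants = "ABCDE"
    matrix = np.full((5, 5), np.nan)
    selected = []
    for gi, gen in enumerate(variants):
        cfg = reference_sim_config(gen, tile=tile, t_end=t_end, seed=seed + gi)
        sim = simulate_dataset(cfg)
        pre, report = preprocess(sim.tissue, sim_preprocess_config(cfg.A0))
        best, table = model_select(pre, all_aniso_spring_specs(),
                                   exclusions=report)
        for rec in table:
            matrix[gi, variants.index(rec["spec"].variant)] = rec["aic"]
        selected.append(best.variant)
    diagonal_hits = sum(sel == gen for sel, gen in zip(selected, variants))
    return {
        "variants": variants,
        "aic_matrix": matrix,
        "selected": selected,
        "diagonal_hits": diagonal_hits,
    }


def run_noise_test(sim: SimResult, noise_config: NoiseConfig,
                   fit_spec: ModelSpec | None = None):
    """Noise-resistance protocol on a simulated tissue with known truth."""
    spec = fit_spec if fit_spec is not None else sim.spec
    A0 = sim.truth.A0
    return noise_resistance_test(
        sim.tissue, spec, noise_config,
        pre_config=sim_preprocess_config(A0),
        truth=sim.truth, A0_true=A0,
    )
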