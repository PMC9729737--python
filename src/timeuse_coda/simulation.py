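"""Monte-Carlo validation experiments used by the test-suite and the
acceptance script: type-I-error calibration of the composition F-test and
parameter recovery of the generated ilr / pivot coefficients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import PARTS, contrast_matrix, sbp_order
from .inference import COMPOSITION_TERM, ModelSpec, fit_model, type2_anova
from .synthetic import CohortConfig, OutcomeEffects, generate_cohort

#: analysis model used in the simulations: all main effects, no interactions
_SIM_SPEC = ModelSpec(outcome="y", interactions=())


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _one_outcome_config(n: int, seed: int, effects: OutcomeEffects) -> CohortConfig:
    return CohortConfig(n=n, seed=seed, outcomes={"y": effects})


def composition_pvalue(n: int = 384, seed: int = 0, effects: OutcomeEffects | None = None) -> float:
    """Type II p-value of the 3-df composition block on one simulated cohort."""
    cohort = generate_cohort(_one_outcome_config(n, seed, effects or OutcomeEffects()))
    tt = type2_anova(cohort, _SIM_SPEC).set_index("term")
    return float(tt.loc[COMPOSITION_TERM, "p"])


def composition_null_size(
    n_reps: int = 1000, n: int = 384, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical rejection rate of the composition F-test under the null.

    Cohorts carry no composition effect, so the rate estimates the test's
    type-I error; its binomial 95% interval around ``alpha`` is the
    calibration band.
    """
    seeds = _spawn_seeds(seed, n_reps)
    rejections = sum(composition_pvalue(n=n, seed=s) < alpha for s in seeds)
    return rejections / n_reps


def true_pivot_betas(beta_composition) -> dict[str, float]:
    """Analytic behaviour-vs-remaining slopes implied by a default-basis beta.

    With y depending on the composition through ``beta' z`` (default pivot
    basis), the clr coefficient vector is ``theta = Psi' beta`` and the
    pivot slope of part i is ``(2/sqrt(3)) * theta_i`` — the first pivot
    coordinate of part i is ``(2/sqrt(3))`` times its clr component, and
    the pivot rotations are orthonormal changes of basis.
    """
    theta = contrast_matrix().T @ np.asarray(beta_composition, dtype=float)
    return {part: float(2.0 / np.sqrt(3.0) * theta[i]) for i, part in enumerate(PARTS)}


def pivot_betas_to_default_basis(pivot_betas) -> np.ndarray:
    """Default-basis ilr coefficients reproducing given pivot slopes.

    ``pivot_betas`` maps each part to its behaviour-vs-remaining slope; the
    four values must (up to rounding) sum to zero, and are projected onto
    the zero-sum subspace before inversion.
    """
    b = np.array([pivot_betas[p] for p in PARTS], dtype=float)
    theta = np.sqrt(3.0) / 2.0 * (b - b.mean())
    return contrast_matrix() @ theta


@dataclass
class RecoveryResult:
    beta_true: np.ndarray          # generated ilr coefficients (default basis)
    beta_hat: np.ndarray
    beta_se: np.ndarray
    pivot_true: dict[str, float]
    pivot_hat: dict[str, float]
    pivot_se: dict[str, float]
    n: int


def parameter_recovery(
    n: int = 5000,
    beta_composition=(0.3, -0.2, 0.1),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> RecoveryResult:
    """Fit the analysis model to one generated cohort with known effects.

    Returns estimates and standard errors for the three default-basis ilr
    coefficients and for the four pivot rotations; the 3-standard-error
    band is the recovery criterion used by the callers.
    """
    effects = OutcomeEffects(beta_composition=tuple(beta_composition), noise_sd=noise_sd)
    cohort = generate_cohort(_one_outcome_config(n, seed, effects))
    fm = fit_model(cohort, _SIM_SPEC)
    beta_hat = fm.result.params[["z1", "z2", "z3"]].to_numpy()
    beta_se = fm.result.bse[["z1", "z2", "z3"]].to_numpy()
    pivot_hat, pivot_se = {}, {}
    for part in PARTS:
        rot = fit_model(cohort, _SIM_SPEC, order=sbp_order(part))
        pivot_hat[part] = float(rot.result.params["z1"])
        pivot_se[part] = float(rot.result.bse["z1"])
    return RecoveryResult(
        beta_true=np.asarray(beta_composition, dtype=float),
        beta_hat=beta_hat,
        beta_se=beta_se,
        pivot_true=true_pivot_betas(beta_composition),
        pivot_hat=pivot_hat,
        pivot_se=pivot_se,
        n=n,
    )
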