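"""One-for-remaining time-reallocation prediction curves.

Starting from a base day, a focal behaviour is varied in fixed increments
(15 min by default); the remaining three behaviours are scaled
proportionally so the day still sums to 1440 min.  Each reallocated day is
pushed through a fitted outcome model at a fixed covariate/moderator
profile, giving a predicted response curve with a delta-method confidence
band from the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .composition import DAY_MINUTES, PARTS, ilr_transform
from .inference import CATEGORY_LEVELS, FittedModel


@dataclass
class ReallocationGrid:
    focal: str
    deltas: np.ndarray          # minutes added to the focal behaviour
    compositions: np.ndarray    # (len(deltas), 4) in PARTS order, each sums to 1440
    truncated: bool             # True when the simplex boundary cut the requested range


def one_for_remaining_grid(
    base, focal: str, max_delta: float = 60.0, step: float = 15.0
) -> ReallocationGrid:
    """Grid of compositions reallocating the focal behaviour vs the rest.

    For each delta in ``-max_delta .. +max_delta`` (multiples of ``step``),
    the focal part becomes ``focal + delta`` and every remaining part is
    scaled by ``(1440 - focal') / (1440 - focal)``.  Rows that would push
    any part to zero or below are dropped and the grid is flagged truncated.
    """
    if focal not in PARTS:
        raise ValueError(f"unknown behaviour {focal!r}")
    if step <= 0:
        raise ValueError("step must be positive")
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0) or abs(base.sum() - DAY_MINUTES) > 1e-6:
        raise ValueError("base must be strictly positive and closed to 1440")
    i = PARTS.index(focal)
    nsteps = int(np.floor(max_delta / step + 1e-9))
    deltas = np.arange(-nsteps, nsteps + 1) * step
    rows, kept, truncated = [], [], False
    for d in deltas:
        new_focal = base[i] + d
        if new_focal <= 0 or new_focal >= DAY_MINUTES:
            truncated = True
            continue
        scale = (DAY_MINUTES - new_focal) / (DAY_MINUTES - base[i])
        comp = base * scale
        comp[i] = new_focal
        if np.any(comp <= 0):
            truncated = True
            continue
        rows.append(comp)
        kept.append(d)
    return ReallocationGrid(
        focal=focal,
        deltas=np.asarray(kept, dtype=float),
        compositions=np.asarray(rows),
        truncated=truncated,
    )


def predict_response_curve(
    model: FittedModel,
    grid: ReallocationGrid,
    profile: dict[str, float | str],
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Predicted outcome per reallocation with a pointwise confidence band.

    ``profile`` fixes every non-composition term of the model: numeric
    covariates as values, categorical covariates/moderators as level names.
    The band is ``prediction ± t * sqrt(x' Cov(beta) x)`` with the model's
    residual df (the delta-method band on the mean response).  With no
    interaction terms, curves at different moderator levels differ only by
    an intercept shift; with interactions they diverge in shape.
    """
    spec = model.spec
    columns = list(model.design.X.columns)
    rows = np.zeros((len(grid.deltas), len(columns)))
    col_idx = {c: j for j, c in enumerate(columns)}
    rows[:, col_idx["const"]] = 1.0

    dummy_values: dict[str, float] = {}
    for var in spec.covariates + spec.moderators:
        if var not in profile:
            raise ValueError(f"profile is missing a value for {var!r}")
        if var in CATEGORY_LEVELS:
            level = profile[var]
            if level not in CATEGORY_LEVELS[var]:
                raise ValueError(f"unknown level {level!r} for {var!r}")
            for lev in CATEGORY_LEVELS[var][1:]:
                dummy_values[f"{var}_{lev}"] = float(level == lev)
        else:
            dummy_values[var] = float(profile[var])
    for name, value in dummy_values.items():
        rows[:, col_idx[name]] = value

    if spec.composition:
        z = ilr_transform(grid.compositions)
        for k, zname in enumerate(("z1", "z2", "z3")):
            rows[:, col_idx[zname]] = z[:, k]
        for mod in spec.interactions:
            for lev in CATEGORY_LEVELS[mod][1:]:
                dummy = f"{mod}_{lev}"
                for k, zname in enumerate(("z1", "z2", "z3")):
                    rows[:, col_idx[f"{zname}:{dummy}"]] = z[:, k] * dummy_values[dummy]

    beta = model.result.params.to_numpy()
    cov = model.result.cov_params().to_numpy()
    pred = rows @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", rows, cov, rows))
    tcrit = scipy.stats.t.ppf(0.5 + conf_level / 2.0, model.result.df_resid)
    return pd.DataFrame(
        {
            "delta": grid.deltas,
            "predicted": pred,
            "lower": pred - tcrit * se,
            "upper": pred + tcrit * se,
        }
    )
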