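"""Cognitive outcome construction.

Global cognition is the ACE-III total (0-100), used as-is.  Four domain
composites — long-term memory, short-term memory, executive function and
processing speed — are built from thirteen CANTAB outcome measures:
measures where lower is better (latencies, error counts) are sign-reversed,
each measure is z-scored against the sample, and a composite is the
unweighted mean of its component z-scores.  A composite is missing for a
participant unless every component is present and every accuracy-based
inclusion rule affecting that composite is met (accuracy strictly below the
threshold masks the participant from the affected composites only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DOMAINS = ("ltm", "stm", "exec", "speed")
OUTCOMES = ("global_cognition",) + DOMAINS


@dataclass(frozen=True)
class MeasureDefinition:
    name: str
    test: str
    domain: str  # one of DOMAINS
    reversed: bool
    score_range: tuple[float, float]


#: CANTAB outcome measures feeding the four domain composites.
MEASURES: tuple[MeasureDefinition, ...] = (
    MeasureDefinition("vrm_delayed_recognition", "VRM", "ltm", False, (0, 36)),
    MeasureDefinition("vrm_immediate_recognition", "VRM", "stm", False, (0, 36)),
    MeasureDefinition("vrm_immediate_free_recall", "VRM", "stm", False, (0, 18)),
    MeasureDefinition("pal_total_errors_adjusted", "PAL", "stm", True, (0, 70)),
    MeasureDefinition("pal_first_attempt_memory", "PAL", "stm", False, (0, 20)),
    MeasureDefinition("mtt_total_incorrect", "MTT", "exec", True, (0, 160)),
    MeasureDefinition("mtt_multitasking_cost", "MTT", "exec", True, (-1900, 1900)),
    MeasureDefinition("mtt_incongruency_cost", "MTT", "exec", True, (-1900, 1900)),
    MeasureDefinition("ots_problems_first_choice", "OTS", "exec", False, (0, 15)),
    MeasureDefinition("ots_median_latency_first_choice", "OTS", "exec", True, (0, np.inf)),
    MeasureDefinition("rti_simple_reaction_time", "RTI", "speed", True, (100, 5100)),
    MeasureDefinition("rti_choice_reaction_time", "RTI", "speed", True, (100, 5100)),
    MeasureDefinition("rti_simple_movement_time", "RTI", "speed", True, (100, 5100)),
    MeasureDefinition("rti_choice_movement_time", "RTI", "speed", True, (100, 5100)),
)

_BY_NAME = {m.name: m for m in MEASURES}


@dataclass(frozen=True)
class InclusionRule:
    """Mask participants with accuracy strictly below ``threshold`` on
    ``accuracy_column`` out of the listed composites (and only those)."""

    accuracy_column: str
    threshold: float = 0.5
    composites: tuple[str, ...] = ()


#: default rules: each test's accuracy gates the composites it feeds
DEFAULT_INCLUSION_RULES: tuple[InclusionRule, ...] = (
    InclusionRule("vrm_accuracy", 0.5, ("ltm", "stm")),
    InclusionRule("pal_accuracy", 0.5, ("stm",)),
    InclusionRule("mtt_accuracy", 0.5, ("exec",)),
    InclusionRule("ots_accuracy", 0.5, ("exec",)),
    InclusionRule("rti_accuracy", 0.5, ("speed",)),
)


def reverse_scores(values: pd.DataFrame, definitions=MEASURES) -> pd.DataFrame:
    """Orient all measures so that higher = better (reversed measures × −1)."""
    known = {m.name for m in definitions}
    unknown = [c for c in values.columns if c not in known]
    if unknown:
        raise KeyError(f"unknown measure columns: {unknown}")
    out = values.copy()
    by_name = {m.name: m for m in definitions}
    for col in out.columns:
        if by_name[col].reversed:
            out[col] = -out[col]
    return out


def zscore_columns(values: pd.DataFrame) -> pd.DataFrame:
    """Columnwise (x − mean)/SD with the n−1 SD; missing values propagate."""
    out = values.copy()
    for col in out.columns:
        x = out[col]
        if x.notna().sum() < 2:
            raise ValueError(f"measure {col!r} has fewer than 2 observed values")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"measure {col!r} has zero spread; cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


def apply_inclusion_criteria(
    scores: pd.DataFrame, rules=DEFAULT_INCLUSION_RULES
) -> pd.DataFrame:
    """Boolean eligibility mask, one column per domain composite.

    Accuracy strictly below a rule's threshold (<50% by default) drops the
    participant from the affected composites; accuracy exactly at the
    threshold is retained.  Missing accuracy is treated as eligible — the
    completeness rule handles missing data separately.
    """
    mask = pd.DataFrame(True, index=scores.index, columns=list(DOMAINS))
    for rule in rules:
        if rule.accuracy_column not in scores.columns:
            raise KeyError(f"inclusion rule references unknown column {rule.accuracy_column!r}")
        for comp in rule.composites:
            if comp not in DOMAINS:
                raise KeyError(f"inclusion rule references unknown composite {comp!r}")
        failing = scores[rule.accuracy_column] < rule.threshold
        failing = failing.fillna(False)
        for comp in rule.composites:
            mask.loc[failing, comp] = False
    return mask


def build_composites(
    zvalues: pd.DataFrame,
    definitions=MEASURES,
    mask: pd.DataFrame | None = None,
    ace_total: pd.Series | None = None,
) -> pd.DataFrame:
    """Domain composites as unweighted means of component z-scores.

    A composite is NaN whenever any component is missing or the inclusion
    mask excludes the participant.  ``global_cognition`` is the raw ACE-III
    total passed through unchanged (it is its own 0-100 scale, not z-scored).
    """
    out = pd.DataFrame(index=zvalues.index, columns=list(OUTCOMES), dtype=float)
    out["global_cognition"] = ace_total if ace_total is not None else np.nan
    for domain in DOMAINS:
        comps = [m.name for m in definitions if m.domain == domain]
        block = zvalues[comps]
        value = block.mean(axis=1).where(block.notna().all(axis=1))
        if mask is not None:
            value = value.where(mask[domain])
        out[domain] = value
    return out


def composites_from_raw(
    raw: pd.DataFrame, rules=DEFAULT_INCLUSION_RULES
) -> pd.DataFrame:
    """Raw score table → composite table (reversal, z-scoring, masking, means).

    ``raw`` holds one row per participant with the measure columns of
    :data:`MEASURES`, per-test accuracy columns, and ``ace_iii_total``.
    """
    measures = raw[[m.name for m in MEASURES]]
    z = zscore_columns(reverse_scores(measures))
    mask = apply_inclusion_criteria(raw, rules)
    return build_composites(z, MEASURES, mask, ace_total=raw.get("ace_iii_total"))
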