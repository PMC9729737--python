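"""Regression engine for time-use composition vs cognition.

The analysis model for each cognitive outcome is an ordinary least-squares
regression on demographic covariates (age, sex, site, education, smoking),
behaviour-context moderators (TV-watching tertile, recreational-PA category,
sleep quality), the three ilr coordinates of the 24-h time-use composition
entered as one 3-df block, and optional composition x moderator interaction
blocks.  Inference follows a fixed procedure:

1. backward selection starting from the full model — interaction blocks are
   removed one at a time in order of largest type II p-value while that
   p >= alpha; the composition block is then tested (removable only once no
   interaction remains); covariates and moderator main effects are finally
   tested collectively with a single joint F;
2. type II F-tests on the final model: each term group is tested by the
   residual-sum-of-squares drop when it is added to the model containing
   every term that does not include it (marginality), against the full
   model's mean squared error;
3. Benjamini-Hochberg FDR adjustment of the p-values within each outcome's
   final model (the FDR family is the terms of one model);
4. pivot coefficients: the final model is refit under the four part orders
   placing each behaviour first, giving the "behaviour vs remaining" slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .composition import PARTS, ilr_transform, sbp_order

COVARIATES = ("age", "sex", "site", "education", "smoking")
MODERATORS = ("tv", "recpa", "sleep_quality")
COMPOSITION_TERM = "composition"

#: categorical levels; the first level is the dummy-coding reference
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "site": ("adelaide", "newcastle"),
    "smoking": ("never", "previous", "current"),
    "sleep_quality": ("good", "bad"),
    "tv": ("low", "medium", "high"),
    "recpa": ("over30", "none", "upto30"),
}

COMPOSITION_COLUMNS = ("sleep_min", "sb_min", "lpa_min", "mvpa_min")


# ---------------------------------------------------------------------------
# moderator categorisation


def assign_moderators(
    tv_minutes: pd.Series, recpa_minutes: pd.Series, sleep_rating: pd.Series
) -> pd.DataFrame:
    """Categorise the self-report moderators.

    TV minutes are split at the empirical 1/3 and 2/3 quantiles of the
    sample (linear interpolation; ties at a cut go to the lower category).
    Recreational PA: 0 min -> "none", (0, 30] -> "upto30", > 30 -> "over30".
    Sleep-quality rating (0 = very good .. 3 = very bad): 0-1 -> "good",
    2-3 -> "bad".
    """
    tv = pd.Series(tv_minutes, dtype=float)
    rec = pd.Series(recpa_minutes, dtype=float)
    rating = pd.Series(sleep_rating)
    if tv.lt(0).any() or rec.lt(0).any():
        raise ValueError("activity minutes must be nonnegative")
    if not rating.dropna().isin([0, 1, 2, 3]).all():
        raise ValueError("sleep-quality rating must be in {0, 1, 2, 3}")

    q1, q2 = np.quantile(tv.dropna(), [1.0 / 3.0, 2.0 / 3.0])
    tv_cat = pd.Series(
        np.where(tv <= q1, "low", np.where(tv <= q2, "medium", "high")), index=tv.index
    ).where(tv.notna())
    rec_cat = pd.Series(
        np.where(rec == 0, "none", np.where(rec <= 30, "upto30", "over30")), index=rec.index
    ).where(rec.notna())
    sleep_cat = pd.Series(
        np.where(rating <= 1, "good", "bad"), index=rating.index
    ).where(rating.notna())
    return pd.DataFrame({"tv": tv_cat, "recpa": rec_cat, "sleep_quality": sleep_cat})


# ---------------------------------------------------------------------------
# pairwise correlations


def pairwise_correlations(df: pd.DataFrame, columns: Sequence[str] | None = None):
    """Pearson r with two-sided p on pairwise-complete observations.

    Returns ``(r, p, n)`` DataFrames.  Cells with fewer than 3 complete
    pairs are left NaN (flagged by the ``n`` table).
    """
    cols = list(columns) if columns is not None else list(df.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        n.loc[a, a] = int(df[a].notna().sum())
        r.loc[a, a] = 1.0
        for b in cols[i + 1 :]:
            pair = df[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                continue
            res = scipy.stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p, n


# ---------------------------------------------------------------------------
# model specification and design


@dataclass(frozen=True)
class ModelSpec:
    """Terms of one outcome's linear model.

    ``interactions`` lists moderators whose composition x moderator block is
    included; marginality requires the composition block and that
    moderator's main effect to be present alongside any interaction.
    """

    outcome: str
    covariates: tuple[str, ...] = COVARIATES
    moderators: tuple[str, ...] = MODERATORS
    composition: bool = True
    interactions: tuple[str, ...] = MODERATORS

    def __post_init__(self) -> None:
        unknown = set(self.interactions) - set(self.moderators)
        if unknown:
            raise ValueError(f"interaction with absent moderator main effect: {sorted(unknown)}")
        if self.interactions and not self.composition:
            raise ValueError("interaction blocks require the composition block (marginality)")

    @property
    def terms(self) -> tuple[str, ...]:
        t = list(self.covariates) + list(self.moderators)
        if self.composition:
            t.append(COMPOSITION_TERM)
        t += [f"{COMPOSITION_TERM}:{m}" for m in self.interactions]
        return tuple(t)


@dataclass
class Design:
    y: np.ndarray
    X: pd.DataFrame
    groups: dict[str, list[str]]  # term -> design column names
    index: pd.Index  # complete-case row index into the source table


def _dummy_columns(df: pd.DataFrame, var: str) -> pd.DataFrame:
    levels = CATEGORY_LEVELS[var]
    observed = set(df[var].dropna().unique()) - set(levels)
    if observed:
        raise ValueError(f"unknown level(s) {sorted(observed)} for {var!r}")
    out = {}
    for level in levels[1:]:
        out[f"{var}_{level}"] = (df[var] == level).astype(float)
    return pd.DataFrame(out, index=df.index)


def ilr_columns(df: pd.DataFrame, order: Sequence[str] = PARTS) -> pd.DataFrame:
    """z1..z3 ilr coordinates of the behaviour-minute columns under ``order``."""
    comp = df[list(COMPOSITION_COLUMNS)].to_numpy(dtype=float)
    z = ilr_transform(comp, order=order)
    return pd.DataFrame(z, columns=["z1", "z2", "z3"], index=df.index)


def build_design(
    df: pd.DataFrame, spec: ModelSpec, order: Sequence[str] = PARTS
) -> Design:
    """Assemble the design matrix on complete cases (listwise deletion).

    Categorical terms are dummy-coded against the reference levels of
    :data:`CATEGORY_LEVELS`; the composition enters as the three ilr
    coordinates under ``order``; an interaction block is the elementwise
    product of each ilr coordinate with each non-reference moderator dummy.
    """
    needed = [spec.outcome]
    for t in spec.covariates + spec.moderators:
        needed.append(t)
    if spec.composition:
        needed += list(COMPOSITION_COLUMNS)
    data = df[needed].dropna()

    blocks: list[pd.DataFrame] = [pd.DataFrame({"const": 1.0}, index=data.index)]
    groups: dict[str, list[str]] = {}
    for var in spec.covariates + spec.moderators:
        if var in CATEGORY_LEVELS:
            block = _dummy_columns(data, var)
        else:
            block = data[[var]].astype(float)
        groups[var] = list(block.columns)
        blocks.append(block)
    if spec.composition:
        zblock = ilr_columns(data, order=order)
        groups[COMPOSITION_TERM] = list(zblock.columns)
        blocks.append(zblock)
        for mod in spec.interactions:
            inter = {}
            for dummy in groups[mod]:
                for zcol in zblock.columns:
                    inter[f"{zcol}:{dummy}"] = zblock[zcol] * blocks_col(blocks, dummy)
            iblock = pd.DataFrame(inter, index=data.index)
            groups[f"{COMPOSITION_TERM}:{mod}"] = list(iblock.columns)
            blocks.append(iblock)
    X = pd.concat(blocks, axis=1)
    return Design(y=data[spec.outcome].to_numpy(dtype=float), X=X, groups=groups,
                  index=data.index)


def blocks_col(blocks: list[pd.DataFrame], name: str) -> pd.Series:
    for b in blocks:
        if name in b.columns:
            return b[name]
    raise KeyError(name)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, _, pivots = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        aliased = [X.columns[i] for i in pivots[rank:]]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


@dataclass
class FittedModel:
    spec: ModelSpec
    design: Design
    result: "sm.regression.linear_model.RegressionResultsWrapper"

    @property
    def n(self) -> int:
        return len(self.design.y)


def fit_model(df: pd.DataFrame, spec: ModelSpec, order: Sequence[str] = PARTS) -> FittedModel:
    """OLS fit of ``spec`` on complete cases; errors on rank-deficient designs."""
    design = build_design(df, spec, order=order)
    _check_full_rank(design.X)
    result = sm.OLS(design.y, design.X).fit()
    return FittedModel(spec=spec, design=design, result=result)


# ---------------------------------------------------------------------------
# type II ANOVA


def _containing_terms(term: str, spec: ModelSpec) -> list[str]:
    """Terms that include ``term`` (and must be absent from both nested models)."""
    if term == COMPOSITION_TERM:
        return [f"{COMPOSITION_TERM}:{m}" for m in spec.interactions]
    if term in spec.moderators and term in spec.interactions:
        return [f"{COMPOSITION_TERM}:{term}"]
    return []


def type2_anova(
    df: pd.DataFrame,
    spec: ModelSpec,
    order: Sequence[str] = PARTS,
    design: Design | None = None,
) -> pd.DataFrame:
    """Marginality-respecting type II F-test for every term group.

    For group g the sum of squares is RSS(model with every term except g
    and except any term containing g) minus RSS(that model plus g); the F
    denominator is the full model's MSE.  Composition and interaction
    blocks are multi-df groups.  Returns a TermTable with columns
    ``term, F, df_num, df_den, p``.
    """
    if design is None:
        design = build_design(df, spec, order=order)
    _check_full_rank(design.X)
    X = design.X.to_numpy(dtype=float)
    y = design.y
    cols = list(design.X.columns)
    col_idx = {c: i for i, c in enumerate(cols)}
    rss_full = _rss(X, y)
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse_full = rss_full / df_resid

    rows = []
    for term in spec.terms:
        g_cols = design.groups[term]
        excluded = set(g_cols)
        for other in _containing_terms(term, spec):
            excluded.update(design.groups[other])
        base = [col_idx[c] for c in cols if c not in excluded]
        with_g = base + [col_idx[c] for c in g_cols]
        ss = _rss(X[:, base], y) - _rss(X[:, with_g], y)
        df_num = len(g_cols)
        f = (ss / df_num) / mse_full
        p = scipy.stats.f.sf(f, df_num, df_resid)
        rows.append({"term": term, "F": f, "df_num": df_num, "df_den": df_resid, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward selection


@dataclass
class SelectionStep:
    step: int
    action: str  # "remove" | "keep" | "test"
    term: str
    p: float


#: fixed tie-break order for equal largest p-values at interaction removal
_INTERACTION_ORDER = ("tv", "recpa", "sleep_quality")


def backward_select(
    df: pd.DataFrame,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    drop_covariates: bool = False,
    outcome: str | None = None,
    order: Sequence[str] = PARTS,
) -> tuple[ModelSpec, list[SelectionStep]]:
    """The staged backward-selection procedure.

    (i) while any composition x moderator block has type II p >= alpha,
    remove the one with the largest p (ties broken in the fixed order TV,
    recreational PA, sleep quality) and refit; (ii) once no interaction
    remains removable, test the composition block — it may be removed only
    when no interaction block is left — and drop it if p >= alpha;
    (iii) test the remaining covariates and moderator main effects with one
    collective F.  By default the collective block is retained regardless of
    its p (set ``drop_covariates=True`` for strict removal).  Marginality is
    never violated; every decision is recorded in the trace.
    """
    if spec is None:
        if outcome is None:
            raise ValueError("supply a ModelSpec or an outcome name")
        spec = ModelSpec(outcome=outcome)
    trace: list[SelectionStep] = []
    step = 0

    # (i) interaction blocks, largest p first
    while spec.interactions:
        tt = type2_anova(df, spec, order=order).set_index("term")
        pvals = {m: tt.loc[f"{COMPOSITION_TERM}:{m}", "p"] for m in spec.interactions}
        worst = max(
            spec.interactions,
            key=lambda m: (pvals[m], -_INTERACTION_ORDER.index(m)),
        )
        step += 1
        if pvals[worst] >= alpha:
            trace.append(SelectionStep(step, "remove", f"{COMPOSITION_TERM}:{worst}", pvals[worst]))
            spec = replace(spec, interactions=tuple(m for m in spec.interactions if m != worst))
        else:
            trace.append(SelectionStep(step, "keep", f"{COMPOSITION_TERM}:{worst}", pvals[worst]))
            break

    # (ii) the composition block (only removable with no interactions left)
    if spec.composition and not spec.interactions:
        tt = type2_anova(df, spec, order=order).set_index("term")
        p_comp = float(tt.loc[COMPOSITION_TERM, "p"])
        step += 1
        if p_comp >= alpha:
            trace.append(SelectionStep(step, "remove", COMPOSITION_TERM, p_comp))
            spec = replace(spec, composition=False, interactions=())
        else:
            trace.append(SelectionStep(step, "keep", COMPOSITION_TERM, p_comp))

    # (iii) covariates + moderator main effects, collectively
    locked = set(spec.interactions)  # marginality: mains of retained interactions stay
    block_terms = [t for t in spec.covariates + spec.moderators if t not in locked]
    if block_terms:
        design = build_design(df, spec, order=order)
        X = design.X.to_numpy(dtype=float)
        y = design.y
        cols = list(design.X.columns)
        col_idx = {c: i for i, c in enumerate(cols)}
        g_cols = [c for t in block_terms for c in design.groups[t]]
        base = [col_idx[c] for c in cols if c not in set(g_cols)]
        rss_full = _rss(X, y)
        df_resid = len(y) - X.shape[1]
        ss = _rss(X[:, base], y) - rss_full
        f = (ss / len(g_cols)) / (rss_full / df_resid)
        p_cov = float(scipy.stats.f.sf(f, len(g_cols), df_resid))
        step += 1
        if drop_covariates and p_cov >= alpha:
            trace.append(SelectionStep(step, "remove", "covariates", p_cov))
            spec = replace(
                spec,
                covariates=(),
                moderators=tuple(m for m in spec.moderators if m in locked),
            )
        else:
            trace.append(SelectionStep(step, "keep", "covariates", p_cov))
    return spec, trace


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``adj_(k) = min(1, min_{j>=k} p_(j) * m / j)`` over the ascending sort;
    monotone and idempotent.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    asc = np.argsort(p, kind="stable")
    scaled = p[asc] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[asc] = adj
    return out


# ---------------------------------------------------------------------------
# pivot coefficients


def extract_pivot_coefficients(
    df: pd.DataFrame, spec: ModelSpec
) -> dict[str, float]:
    """Behaviour-vs-remaining slopes via the four pivot SBP rotations.

    The final model is refit once per behaviour with a part order placing
    that behaviour first; the first ilr coordinate's coefficient is the
    behaviour's pivot beta.  Fitted values and R^2 are identical across
    rotations (the four bases span the same column space).
    """
    if not spec.composition:
        raise ValueError("pivot coefficients require the composition block in the model")
    out = {}
    for part in PARTS:
        fm = fit_model(df, spec, order=sbp_order(part))
        out[part] = float(fm.result.params["z1"])
    return out


# ---------------------------------------------------------------------------
# the full study


@dataclass
class OutcomeResult:
    outcome: str
    n: int
    spec: ModelSpec
    term_table: pd.DataFrame  # term, F, df_num, df_den, p, p_adj
    trace: list[SelectionStep]
    pivot_betas: dict[str, float] | None


def run_study(
    df: pd.DataFrame,
    outcomes: Sequence[str],
    alpha: float = 0.05,
    drop_covariates: bool = False,
) -> dict[str, OutcomeResult]:
    """Backward selection + type II ANOVA + within-model FDR, per outcome.

    Missingness is handled by listwise deletion per outcome, so each model
    reports its own complete-case n.  The FDR family is the set of term
    p-values inside one outcome's final model.
    """
    results: dict[str, OutcomeResult] = {}
    for outcome in outcomes:
        final, trace = backward_select(
            df, outcome=outcome, alpha=alpha, drop_covariates=drop_covariates
        )
        design = build_design(df, final)
        tt = type2_anova(df, final, design=design)
        tt["p_adj"] = bh_adjust(tt["p"])
        pivot = extract_pivot_coefficients(df, final) if final.composition else None
        results[outcome] = OutcomeResult(
            outcome=outcome, n=len(design.y), spec=final, term_table=tt,
            trace=trace, pivot_betas=pivot,
        )
    return results


def format_study_table(results: dict[str, OutcomeResult]) -> pd.DataFrame:
    """Wide per-term summary across outcomes; removed terms are printed "–"."""
    all_terms: list[str] = []
    for res in results.values():
        for t in res.term_table["term"]:
            if t not in all_terms:
                all_terms.append(t)
    table = {}
    for name, res in results.items():
        tt = res.term_table.set_index("term")
        col = {}
        for t in all_terms:
            if t in tt.index:
                r = tt.loc[t]
                col[t] = (
                    f"F({int(r.df_num)},{int(r.df_den)})={r.F:.2f}, "
                    f"p={r.p:.2f}, adj.p={r.p_adj:.2f}"
                )
            else:
                col[t] = "–"
        table[name] = col
    return pd.DataFrame(table).loc[all_terms]
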