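"""Cohort-level statistics: memory scores, mixed-effects models, effect sizes.

The primary analysis asks whether the mean cosine of the spindle-coupling
phase differs between slow and fast switcher SWs and is differentially
associated with medial-prefrontal amyloid burden (Centiloid), controlling for
age, sex, total sleep time and SW-type duration, with a random intercept per
subject. Fixed-effect F tests carry Satterthwaite denominator degrees of
freedom, and effect sizes are reported as the semi-partial R²β*
(q·F/ν) / (1 + q·F/ν).

Secondary models (event densities, band powers, memory change) reuse the same
design-building and fitting machinery through ``fit_model``; they are
configuration, not separate code paths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import ContrastTest, LMMResult, fit_random_intercept

logger = logging.getLogger(__name__)

#: reference levels for two-level factors (first level absorbed in intercept)
FACTOR_REFERENCES = {"sex": "female", "switcher": "slow"}

PRIMARY_FIXED = [
    "switcher", "centiloid", "switcher:centiloid", "age", "sex", "tst",
    "sw_duration",
]


@dataclass
class EffectTest:
    F: float
    df_num: int
    df_den: float
    p: float
    r2_beta_star: float


@dataclass
class MixedModelFit:
    """Fixed-effect F table and fit metadata for one mixed model."""

    dependent: str
    effects: dict[str, EffectTest]
    coefficients: dict[str, float]
    random_intercept_var: float
    residual_var: float
    meta: dict = field(default_factory=dict)
    design_columns: list[str] = field(default_factory=list)
    result: LMMResult | None = None
    subjects: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# scalar formulas


def recognition_memory_score(p_old_given_target: float, p_old_given_foil: float) -> float:
    """RM score: P('old' | target) - P('old' | foil)."""
    for name, r in (("p_old_given_target", p_old_given_target),
                    ("p_old_given_foil", p_old_given_foil)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0, 1]")
    return p_old_given_target - p_old_given_foil


def memory_decline(rm_baseline: float, rm_followup: float) -> float:
    """Relative memory change: (baseline - follow-up) / baseline.

    Higher values indicate greater decline; negative values, improvement.
    """
    if rm_baseline == 0:
        raise ValueError("memory decline undefined at zero baseline score")
    return (rm_baseline - rm_followup) / rm_baseline


def semipartial_r2(F: float, df_num: float, df_den: float) -> float:
    """Semi-partial effect size R²β* of a fixed effect from its F statistic.

    R²β* = (q F / ν) / (1 + q F / ν) with numerator df q and denominator df ν;
    strictly increasing in F, mapping [0, inf) onto [0, 1).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    ratio = df_num * F / df_den
    return ratio / (1.0 + ratio)


# ---------------------------------------------------------------------------
# design building


def _encode_term(table: pd.DataFrame, term: str) -> tuple[str, np.ndarray]:
    col = table[term]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"factor {term!r} must have two levels, has {levels}")
        ref = FACTOR_REFERENCES.get(term, levels[0])
        other = [lv for lv in levels if lv != ref][0]
        return f"{term}[{other}]", (col == other).to_numpy(float)
    return term, col.to_numpy(float)


def build_design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept for main-effect and ':' interaction terms.

    Two-level factors are dummy-coded against the reference level
    (female for sex, slow for switcher, else the first sorted level).
    """
    cols = [np.ones(len(table))]
    names = ["intercept"]
    encoded: dict[str, tuple[str, np.ndarray]] = {}
    for term in terms:
        parts = term.split(":")
        for part in parts:
            if part not in encoded:
                encoded[part] = _encode_term(table, part)
        name = ":".join(encoded[p][0] for p in parts)
        vec = np.prod([encoded[p][1] for p in parts], axis=0)
        names.append(name)
        cols.append(vec)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# model fitting


def fit_model(
    table: pd.DataFrame,
    dependent: str,
    fixed: list[str],
    group: str = "subject_id",
) -> MixedModelFit:
    """Fit a random-intercept LMM and test each fixed-effect term.

    Rows with missing values in any used column are dropped. Each term gets a
    1-df Wald F test with Satterthwaite denominator df and its R²β*.
    """
    used = [dependent, group] + sorted({p for t in fixed for p in t.split(":")})
    data = table.dropna(subset=[c for c in used if c in table.columns])
    if data.empty:
        raise ValueError("no complete rows to fit")
    missing = [c for c in used if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks required columns {missing}")

    X, names = build_design(data, fixed)
    y = data[dependent].to_numpy(float)
    fit = fit_random_intercept(y, X, data[group].to_numpy())
    if fit.singular:
        logger.warning("%s model: singular random intercept; equivalent to a "
                       "fixed-effects fit", dependent)

    effects: dict[str, EffectTest] = {}
    for term, name in zip(fixed, names[1:]):
        l = np.zeros(X.shape[1])
        l[names.index(name)] = 1.0
        test = fit.contrast_f(l[None, :])
        effects[term] = EffectTest(
            F=test.stat, df_num=test.df_num, df_den=test.df_den, p=test.p,
            r2_beta_star=semipartial_r2(test.stat, test.df_num, test.df_den),
        )
    return MixedModelFit(
        dependent=dependent,
        effects=effects,
        coefficients=dict(zip(names, fit.beta)),
        random_intercept_var=fit.tau2,
        residual_var=fit.sigma2,
        meta={"df_method": fit.df_method, "converged": fit.converged,
              "singular": fit.singular, "reml": True},
        design_columns=names,
        result=fit,
        subjects=list(pd.unique(data[group])),
    )


def fit_primary_model(table: pd.DataFrame) -> MixedModelFit:
    """The primary coupling-phase model on the subject-by-SW-type long table.

    Dependent: per-subject mean cos coupling phase per switcher type.
    Fixed: SW type, Centiloid, their interaction, age, sex, TST, and SW-type
    mean duration. Random intercept per subject.
    """
    n_subjects = table["subject_id"].nunique()
    if n_subjects < 20:
        raise ValueError(f"primary model needs >= 20 subjects, got {n_subjects}")
    return fit_model(table, dependent="cos_phase", fixed=list(PRIMARY_FIXED))


def posthoc_slopes(fit: MixedModelFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SW-type amyloid slopes from the fitted primary model.

    The slow-switcher slope is the Centiloid coefficient; the fast-switcher
    slope adds the interaction. p-values are Tukey-adjusted across the two
    contrasts via the studentized range with k = 2.
    """
    if fit.result is None or "switcher[fast]:centiloid" not in fit.design_columns:
        raise ValueError("post-hoc slopes need the fitted model with the "
                         "SW-type-by-amyloid interaction")
    names = fit.design_columns
    p = len(names)
    l_slow = np.zeros(p)
    l_slow[names.index("centiloid")] = 1.0
    l_fast = l_slow.copy()
    l_fast[names.index("switcher[fast]:centiloid")] = 1.0

    rows = []
    for sw_type, l in (("slow", l_slow), ("fast", l_fast)):
        test: ContrastTest = fit.result.contrast_t(l)
        p_adj = float(stats.studentized_range.sf(
            abs(test.stat) * np.sqrt(2.0), 2, test.df_den))
        rows.append({
            "switcher": sw_type,
            "slope": test.estimate,
            "se": test.se,
            "t": test.stat,
            "df": test.df_den,
            "p_tukey": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


def cooks_check(fit: MixedModelFit, flag_threshold: float = 1.0) -> pd.DataFrame:
    """Leave-one-subject-out Cook's distances on the fixed effects.

    Distances above 1 conventionally flag influential subjects.
    """
    if fit.result is None:
        raise ValueError("need a fitted model")
    if fit.result.n_groups < 10:
        warnings.warn("Cook's distances on under 10 subjects are unstable",
                      stacklevel=2)
    d = fit.result.cooks_distances()
    return pd.DataFrame({
        "subject_id": fit.subjects,
        "cooks_distance": d,
        "flagged": d > flag_threshold,
    })


def paired_change_test(baseline: np.ndarray, followup: np.ndarray):
    """Paired two-sided t test on baseline minus follow-up scores.

    Returns (t, df, p). A positive t indicates an overall decline.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape:
        raise ValueError("baseline and follow-up must be paired (equal length)")
    if baseline.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = baseline - followup
    if np.all(diff == diff[0]):  # zero-variance differences: t degenerate
        if diff[0] == 0:
            return 0.0, int(baseline.size - 1), 1.0
        return float(np.inf * np.sign(diff[0])), int(baseline.size - 1), 0.0
    res = stats.ttest_rel(baseline, followup)
    return float(res.statistic), int(baseline.size - 1), float(res.pvalue)
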