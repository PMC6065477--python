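"""Correlations, paired contrasts, and the hierarchical 8-model BIC table.

The morphology analysis asks how much variance in a cortical measure
(thickness, fractal dimensionality, or gyrification) is explained by age,
BMI, and head motion.  Eight nested/alternative linear models are fit per
outcome and compared by the Bayesian information criterion in its
least-squares form,

    BIC = n ln(RSS / n) + p ln(n),

where p counts the intercept and slope terms (the error variance, shared
by all compared models, is omitted).  Delta-BIC is taken relative to the
best (smallest-BIC) model of a comparison set, and models within 2 of the
best are flagged as statistically equivalent.

Because BIC values are only comparable across models fit to the same
rows, models that require BMI (fit on the BMI-complete subset) form
their own comparison set by default; ``paper_compat=True`` forces the
single all-eight table layout with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

from .io import CohortRecord, cohort_to_frame

#: ΔBIC below which two models are treated as equivalent fits.
BIC_EQUIVALENCE = 2.0

#: Term name -> cohort column.
TERM_COLUMNS = {
    "age": "age_years",
    "bmi": "bmi_kg_m2",
    "motion_rest": "motion_rest_mm_min",
    "motion_movie": "motion_movie_mm_min",
    "aes_axial": "aes_axial",
}

OUTCOME_COLUMNS = {
    "thickness": "thickness_mm",
    "fd": "fd_cortical",
    "gyrification": "gyrification",
}

#: The eight hierarchical models, in table order.  Interaction terms are
#: written ``a*b`` and built from mean-centered main effects.
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("age",),
    2: ("bmi",),
    3: ("age", "bmi"),
    4: ("age", "motion_rest"),
    5: ("age", "motion_movie"),
    6: ("age", "motion_movie", "age*motion_movie"),
    7: ("age", "aes_axial"),
    8: ("age", "aes_axial", "age*aes_axial"),
}

#: Models needing BMI run on the BMI-complete subset.
BMI_MODELS = frozenset({2, 3})


@dataclass
class ModelSpec:
    model_id: int
    outcome: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.model_id in MODEL_TERMS and tuple(self.terms) != MODEL_TERMS[self.model_id]:
            raise ValueError(
                f"model {self.model_id} must have terms {MODEL_TERMS[self.model_id]}, "
                f"got {self.terms}"
            )
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class ModelFit:
    """One least-squares fit with its information-criterion bookkeeping."""

    model_id: int
    outcome: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    r2: float
    rss: float
    n: int
    p: int                      # intercept + slope terms
    bic: float
    delta_bic: float = math.nan
    equivalent_to_best: bool = False


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sp_stats.pearsonr(x, y).statistic)


def partial_corr(x: Sequence[float], y: Sequence[float],
                 control: Sequence[float]) -> float:
    """Partial correlation of x and y controlling one covariate.

    Computed as the correlation of the residuals of x and y after each is
    regressed (with intercept) on the control variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.size < 4:
        raise ValueError("need equal-length samples of size >= 4")
    design = np.column_stack([np.ones_like(c), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return pearson(rx, ry)


def paired_contrast(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Paired t statistic, mean difference, and Cohen's d for a - b.

    Cohen's d divides the mean difference by the SD of the paired
    differences.  Identical samples return (0, 0, 0); nonzero constant
    differences (an infinite t) are degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples of size >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 0.0, 0.0
        raise ValueError("paired differences have zero variance")
    mean_diff = float(diff.mean())
    t = float(mean_diff / (sd / math.sqrt(diff.size)))
    return t, mean_diff, float(mean_diff / sd)


def _design_matrix(frame: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Build the design with intercept; interactions from centered mains."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        if "*" in term:
            a, b = term.split("*")
            va = frame[TERM_COLUMNS[a]].to_numpy(float)
            vb = frame[TERM_COLUMNS[b]].to_numpy(float)
            cols.append((va - va.mean()) * (vb - vb.mean()))
        else:
            cols.append(frame[TERM_COLUMNS[term]].to_numpy(float))
        names.append(term)
    X = np.column_stack([np.ones(len(frame))] + cols)
    return X, ["intercept"] + names


def fit_linear(frame: pd.DataFrame, outcome: str, terms: Sequence[str],
               model_id: int = 0) -> ModelFit:
    """Ordinary least squares of an outcome on the named terms.

    Rows with a missing value in the outcome or any term are dropped
    before fitting; the design must be full rank and have more rows than
    parameters.
    """
    spec_terms = tuple(terms)
    needed = [OUTCOME_COLUMNS[outcome]]
    for t in spec_terms:
        for part in t.split("*"):
            col = TERM_COLUMNS[part]
            if col not in needed:
                needed.append(col)
    sub = frame.dropna(subset=needed)
    y = sub[OUTCOME_COLUMNS[outcome]].to_numpy(float)
    X, names = _design_matrix(sub, spec_terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design (rank {rank} < {p}) for columns {names}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    coeffs = dict(zip(names, (float(c) for c in res.params)))
    fit = ModelFit(model_id=model_id, outcome=outcome, terms=spec_terms,
                   coefficients=coeffs, r2=float(res.rsquared), rss=rss,
                   n=n, p=p, bic=math.nan)
    fit.bic = bic(fit)
    return fit


def bic(fit: ModelFit) -> float:
    """Least-squares BIC: ``n ln(RSS/n) + p ln(n)`` with p = intercept + slopes."""
    if fit.rss <= 0:
        raise ValueError("BIC undefined for non-positive RSS")
    return fit.n * math.log(fit.rss / fit.n) + fit.p * math.log(fit.n)


def compare_models(fits: Sequence[ModelFit], allow_mixed_n: bool = False) -> list[ModelFit]:
    """Attach delta-BIC (relative to the set's best model) to each fit.

    All fits must share the same outcome and — unless ``allow_mixed_n``
    — the same row count, since BIC is not comparable across data sets.
    Exactly one fit gets delta_bic == 0.
    """
    if not fits:
        raise ValueError("no fits to compare")
    outcomes = {f.outcome for f in fits}
    if len(outcomes) > 1:
        raise ValueError(f"fits mix outcomes {sorted(outcomes)}")
    ns = {f.n for f in fits}
    if len(ns) > 1 and not allow_mixed_n:
        raise ValueError(
            f"fits use differing row counts {sorted(ns)}; BIC values are not "
            "comparable across data sets (pass allow_mixed_n=True to override)"
        )
    best = min(f.bic for f in fits)
    out = []
    for f in fits:
        g = ModelFit(**{**f.__dict__})
        g.delta_bic = f.bic - best
        g.equivalent_to_best = g.delta_bic < BIC_EQUIVALENCE
        out.append(g)
    # float ties: force a unique zero at the smallest BIC
    zero_idx = int(np.argmin([f.bic for f in fits]))
    out[zero_idx].delta_bic = 0.0
    out[zero_idx].equivalent_to_best = True
    return out


def model_table(cohort: pd.DataFrame | Sequence[CohortRecord], outcome: str,
                paper_compat: bool = False, min_bmi_rows: int = 10) -> list[ModelFit]:
    """Fit the eight hierarchical models for one outcome.

    Models 1 and 4-8 use every record; models 2-3 use the BMI-complete
    subset.  By default delta-BIC is computed within each same-n set
    (full-data set, BMI-subset set).  ``paper_compat=True`` instead ranks
    all eight together — the classic single-table layout — and warns,
    since cross-n BIC comparison is not statistically meaningful.
    Results come back ordered by model id.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    n_bmi = int(frame["bmi_kg_m2"].notna().sum())
    if n_bmi < min_bmi_rows:
        raise ValueError(f"only {n_bmi} BMI-complete records; need >= {min_bmi_rows}")
    fits = {mid: fit_linear(frame, outcome, MODEL_TERMS[mid], model_id=mid)
            for mid in MODEL_TERMS}
    full_ids = sorted(set(MODEL_TERMS) - BMI_MODELS)
    subset_ids = sorted(BMI_MODELS)
    if paper_compat and len({fits[m].n for m in MODEL_TERMS}) > 1:
        warnings.warn(
            "paper_compat: ranking models fit on different row counts in one "
            "delta-BIC set; BIC is not strictly comparable across data sets",
            stacklevel=2,
        )
        ranked = compare_models([fits[m] for m in sorted(MODEL_TERMS)], allow_mixed_n=True)
        return ranked
    groups = [[fits[m] for m in full_ids]]
    if {fits[m].n for m in subset_ids} == {fits[full_ids[0]].n}:
        # no missing BMI: a single comparison set covers all eight
        groups = [[fits[m] for m in sorted(MODEL_TERMS)]]
    else:
        groups.append([fits[m] for m in subset_ids])
    ranked_all: list[ModelFit] = []
    for grp in groups:
        ranked_all.extend(compare_models(grp))
    return sorted(ranked_all, key=lambda f: f.model_id)


def model_table_frame(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Long-format table (model_id, terms, n, r2, bic, delta_bic)."""
    return pd.DataFrame([
        {"model_id": f.model_id, "terms": " + ".join(f.terms), "n": f.n,
         "r2": f.r2, "bic": f.bic, "delta_bic": f.delta_bic,
         "equivalent_to_best": f.equivalent_to_best}
        for f in fits
    ])


def cohort_correlations(frame: pd.DataFrame) -> pd.DataFrame:
    """The study's headline correlation block on a cohort table.

    Age vs motion (both scans), inter-scan motion, age vs BMI, BMI vs
    motion with and without an age control, computed on the rows where
    both variables are observed.
    """
    rows = []

    def add(name, xcol, ycol, control=None):
        sub = frame.dropna(subset=[xcol, ycol] + ([control] if control else []))
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        if control:
            r = partial_corr(x, y, sub[control].to_numpy(float))
        else:
            r = pearson(x, y)
        rows.append({"pair": name, "r": r, "n": len(sub),
                     "partial_on": control or ""})

    add("age~motion_rest", "age_years", "motion_rest_mm_min")
    add("age~motion_movie", "age_years", "motion_movie_mm_min")
    add("motion_rest~motion_movie", "motion_rest_mm_min", "motion_movie_mm_min")
    add("age~bmi", "age_years", "bmi_kg_m2")
    add("bmi~motion_rest", "bmi_kg_m2", "motion_rest_mm_min")
    add("bmi~motion_movie", "bmi_kg_m2", "motion_movie_mm_min")
    add("bmi~motion_rest|age", "bmi_kg_m2", "motion_rest_mm_min", control="age_years")
    add("bmi~motion_movie|age", "bmi_kg_m2", "motion_movie_mm_min", control="age_years")
    add("age~aes_axial", "age_years", "aes_axial")
    add("age~aes_sagittal", "age_years", "aes_sagittal")
    add("age~aes_coronal", "age_years", "aes_coronal")
    return pd.DataFrame(rows)
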