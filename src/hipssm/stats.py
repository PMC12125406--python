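"""Outcome derivation, quintile categorization, logistic-regression
association analysis, and variance-weighted reliability.

Four adverse outcomes are derived per patient:

1. open reduction;
2. any surgery (open reduction or pelvic osteotomy within five years);
3. pelvic osteotomy or residual dysplasia at age five, with
   open-reduction patients excluded (not applicable for them);
4. the composite "unfavorable outcome" (open reduction, osteotomy, or
   residual dysplasia).

Residual dysplasia means an acetabular index strictly greater than 21
degrees on the age-five radiograph. Initial closed reduction is not an
adverse outcome.

Associations between mode Z-scores (continuous and quintile-categorized)
and the outcomes are estimated by binary logistic regression with odds
ratios, Wald 95 % confidence intervals and p-values, and a
likelihood-ratio omnibus test per model. Complete or quasi-complete
separation is reported, not corrected.

Reliability uses the single-measures two-way absolute-agreement ICC per
mode, combined into one overall coefficient by weighting each retained
mode by its share of the explained shape variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "OutcomeSet",
    "AssociationResult",
    "ICCResult",
    "StatsError",
    "derive_outcomes",
    "outcomes_table",
    "quintile_assign",
    "logistic_fit",
    "run_association_suite",
    "icc_absolute_agreement",
    "overall_weighted_icc",
    "reliability_from_sessions",
]

#: Coefficient magnitude beyond which a logistic fit is flagged as separated.
SEPARATION_COEF_LIMIT = 15.0


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeSet:
    """The four derived adverse outcomes for one patient.

    ``o3`` is None (not applicable) for open-reduction patients, who are
    excluded from the osteotomy-or-residual analysis.
    """

    o1_open_reduction: bool
    o2_surgery: bool
    o3_osteotomy_or_residual: Optional[bool]
    o4_unfavorable: bool


def derive_outcomes(record, ai_threshold: float = 21.0) -> OutcomeSet:
    """Derive the four outcomes from a patient's treatment history and
    age-five acetabular index (AI).

    Residual dysplasia is AI > ``ai_threshold`` (strict). A non-surgical
    record with no AI raises :class:`StatsError`; surgical records may
    lack an AI (residual then contributes nothing beyond the surgery
    itself).
    """
    o1 = bool(record.open_reduction)
    o2 = o1 or bool(record.pelvic_osteotomy)
    ai = record.acetabular_index_5y
    if ai is None:
        if not o2:
            raise StatsError(
                f"record {record.hip_id!r}: missing acetabular index for non-surgical patient"
            )
        residual = False
    else:
        residual = float(ai) > ai_threshold
    o3 = None if o1 else (bool(record.pelvic_osteotomy) or residual)
    o4 = o2 or residual
    return OutcomeSet(o1, o2, o3, o4)


def outcomes_table(records: Sequence, ai_threshold: float = 21.0) -> pd.DataFrame:
    """Outcomes for a cohort as a DataFrame indexed by hip_id (o3 nullable)."""
    rows = {}
    for r in records:
        o = derive_outcomes(r, ai_threshold)
        rows[r.hip_id] = {
            "o1": o.o1_open_reduction,
            "o2": o.o2_surgery,
            "o3": o.o3_osteotomy_or_residual,
            "o4": o.o4_unfavorable,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "hip_id"
    return df


# ---------------------------------------------------------------------------
# Quintiles
# ---------------------------------------------------------------------------


def quintile_assign(values):
    """Rank-based quintile labels (0 lowest ... 4 highest) and cutpoints.

    Values are ranked ascending with ties broken by stable input order.
    Group boundaries sit at ranks round(k*n/5), k = 1..4, with
    round-half-even, which yields groups whose sizes differ by at most
    one (e.g. 18/19/18/19/18 for n = 92). Cutpoints are the boundary
    values (the largest value of each lower group).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise StatsError(f"need at least 5 values for quintiles, got {n}")
    order = np.argsort(x, kind="stable")
    boundaries = [int(round(k * n / 5)) for k in range(1, 5)]
    labels = np.empty(n, dtype=int)
    edges = [0] + boundaries + [n]
    for g in range(5):
        labels[order[edges[g] : edges[g + 1]]] = g
    cutpoints = [float(x[order[b - 1]]) for b in boundaries]
    return labels, cutpoints


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    """One covariate's estimate from one logistic model."""

    outcome_id: int
    model_form: str  # univariable | multivariable | categorized
    covariate: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float
    omnibus_p: float
    separation: bool
    n: int

    def as_dict(self) -> dict:
        return {
            "outcome_id": self.outcome_id,
            "model_form": self.model_form,
            "covariate": self.covariate,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_wald": self.p_wald,
            "omnibus_p": self.omnibus_p,
            "separation": self.separation,
            "n": self.n,
        }


def logistic_fit(design: pd.DataFrame, y, outcome_id: int = 0, model_form: str = "univariable"):
    """Maximum-likelihood binary logistic regression.

    Fits ``y ~ intercept + design`` by Newton scoring (IRLS). Returns one
    :class:`AssociationResult` per design column with OR = exp(beta),
    Wald 95 % CI from the observed information, two-sided Wald p, and
    the likelihood-ratio omnibus p against the intercept-only model.

    Complete or quasi-complete separation (non-finite information or a
    coefficient with |beta| > 15) is flagged per covariate rather than
    corrected, mirroring how such cells are reported in small cohorts.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
        design.columns = [f"x{j}" for j in range(design.shape[1])]
    if len(np.unique(y)) < 2:
        raise StatsError("outcome has a single class; logistic fit undefined")
    for c in design.columns:
        if design[c].nunique() < 2:
            raise StatsError(f"covariate {c!r} is constant")
    X = sm.add_constant(design.astype(float), has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
            fit = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
        params = np.asarray(fit.params)
        bse = np.asarray(fit.bse)
        pvals = np.asarray(fit.pvalues)
        try:
            omnibus = float(fit.llr_pvalue)
        except Exception:
            omnibus = float("nan")
    zcrit = 1.959964
    results = []
    ncases = len(y)
    for j, name in enumerate(design.columns, start=1):
        beta = float(params[j])
        se = float(bse[j])
        flag = separated or not np.isfinite(se) or abs(beta) > SEPARATION_COEF_LIMIT
        results.append(
            AssociationResult(
                outcome_id=outcome_id,
                model_form=model_form,
                covariate=str(name),
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - zcrit * se)),
                ci_high=float(np.exp(beta + zcrit * se)),
                p_wald=float(pvals[j]),
                omnibus_p=omnibus,
                separation=bool(flag),
                n=ncases,
            )
        )
    return results


def run_association_suite(
    zs: pd.DataFrame, fhc_categories: pd.Series, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """All mode/outcome logistic models for one cohort.

    For each of the four outcomes: per-mode univariable fits on the
    continuous Z-score; one multivariable fit entering all retained
    modes plus the Morin FHC category (keeping the covariate count at
    five for the four-mode model); and per-mode categorized fits with
    quintile indicator variables (lowest quintile Q0 as reference).
    Outcome-3 models drop the open-reduction rows. A cell that cannot be
    fit (single-class outcome, separation failure) is recorded with NaN
    estimates instead of aborting the suite.

    Inputs are indexed by hip_id and must cover the same hips.
    """
    zs = zs.sort_index()
    fhc_categories = fhc_categories.reindex(zs.index)
    outcomes = outcomes.reindex(zs.index)
    rows = []

    def _safe_fit(design, y, outcome_id, model_form):
        try:
            return [r.as_dict() for r in logistic_fit(design, y, outcome_id, model_form)]
        except StatsError as exc:
            return [
                {
                    "outcome_id": outcome_id,
                    "model_form": model_form,
                    "covariate": str(c),
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_wald": np.nan,
                    "omnibus_p": np.nan,
                    "separation": True,
                    "n": len(y),
                    "error": str(exc),
                }
                for c in design.columns
            ]

    for oid, col in ((1, "o1"), (2, "o2"), (3, "o3"), (4, "o4")):
        mask = outcomes[col].notna()
        y = outcomes.loc[mask, col].astype(bool).to_numpy()
        z_o = zs.loc[mask]
        fhc_o = fhc_categories.loc[mask].astype(float)
        for mode in zs.columns:
            rows += _safe_fit(z_o[[mode]], y, oid, "univariable")
        multi = z_o.copy()
        multi["fhc_category"] = fhc_o
        rows += _safe_fit(multi, y, oid, "multivariable")
        for mode in zs.columns:
            labels, _ = quintile_assign(z_o[mode].to_numpy())
            dummies = pd.DataFrame(
                {f"{mode}_Q{q}": (labels == q).astype(float) for q in range(1, 5)},
                index=z_o.index,
            )
            rows += _safe_fit(dummies, y, oid, "categorized")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    """Per-mode ICCs with their variance weights and the weighted overall ICC."""

    per_mode_icc: np.ndarray
    weights: np.ndarray
    overall_icc: float


def icc_absolute_agreement(measurements) -> float:
    """Single-measures two-way absolute-agreement ICC (ICC(A,1)).

    ``measurements`` is an (n_images, k_sessions) matrix with no missing
    cells. From the two-way ANOVA decomposition (rows = images, columns
    = annotation sessions):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Absolute agreement penalizes systematic between-session offsets as
    well as inconsistency.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise StatsError("need an (n >= 2) x (k >= 2) measurement matrix")
    if not np.all(np.isfinite(m)):
        raise StatsError("measurement matrix has missing or non-finite cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise StatsError("zero denominator in ICC (no variance anywhere)")
    return float((msr - mse) / denom)


def overall_weighted_icc(per_mode_icc, variance_proportions) -> float:
    """Weighted mean of per-mode ICCs, each mode weighted by its share of
    the total shape variance (weights renormalized to sum to one)."""
    icc = np.asarray(per_mode_icc, dtype=float)
    w = np.asarray(variance_proportions, dtype=float)
    if len(icc) != len(w):
        raise StatsError("per-mode ICCs and weights differ in length")
    if np.any(w <= 0):
        raise StatsError("weights must be positive")
    return float(np.sum(w * icc) / np.sum(w))


def reliability_from_sessions(session_zscores: Sequence[np.ndarray], variance_proportions) -> ICCResult:
    """Combined inter/intra-rater reliability from repeated Z-scores.

    ``session_zscores`` is a list of (n_images, n_modes) arrays, one per
    annotation series (e.g. rater 1 session 1, rater 1 session 2,
    rater 2), stacked as the k columns of one two-way table per mode.
    Returns per-mode ICC(A,1) values and the variance-weighted overall
    coefficient.
    """
    arrays = [np.asarray(a, dtype=float) for a in session_zscores]
    if len(arrays) < 2:
        raise StatsError("need at least two annotation sessions")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise StatsError("session Z-score tables differ in shape")
    n_modes = shape[1]
    per_mode = np.array(
        [
            icc_absolute_agreement(np.column_stack([a[:, m] for a in arrays]))
            for m in range(n_modes)
        ]
    )
    w = np.asarray(variance_proportions, dtype=float)[:n_modes]
    w = w / w.sum()
    return ICCResult(
        per_mode_icc=per_mode,
        weights=w,
        overall_icc=overall_weighted_icc(per_mode, w),
    )
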