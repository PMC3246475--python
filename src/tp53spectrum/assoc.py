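"""Mutation-record association analysis: crude and adjusted odds ratios.

The analysis unit is the *mutation record*: a participant with m >= 1
mutations contributes m records (one per mutation) and a wild-type
participant contributes exactly one record with outcome class
``WILD_TYPE``.  This denominator convention is what reconciles the
published stratum percentages and crude odds ratios with the cohort
margins, and it is verified by the record-conservation invariant
(records = mutations + wild-type participants).

Crude odds ratios come from 2x2 contingency tables with Woolf
(log-OR +/- z*SE) confidence intervals; zero-cell tables are reported
undefined rather than corrected (a Haldane-Anscombe +0.5 correction is
available behind a flag).  Adjusted odds ratios come from a multivariate
logistic regression fitted by iteratively reweighted least squares with
explicit separation / non-convergence reporting per covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import MutationRecord
from .io_core import Participant

WILD_TYPE = "WILD_TYPE"

#: covariate -> (levels in order, reference level); age_years is continuous.
COVARIATE_LEVELS: dict[str, tuple[tuple[str, ...], str]] = {
    "age_group": (("<66", ">=66"), "<66"),
    "sex": (("female", "male"), "female"),
    "ethnicity": (("non_turkmen", "turkmen"), "non_turkmen"),
    "residence": (("rural", "urban"), "rural"),
    "tobacco_opium": (("neither", "tobacco", "opium", "both"), "neither"),
    "tea_interval": (("4plus", "2-3", "0-1"), "4plus"),
}
AGE_CUTOFF = 66.0  # cohort median age; categorical split >= 66 vs < 66


@dataclass(frozen=True)
class RecordUnit:
    """One analysis row: a mutation (its category) or a wild-type participant."""

    sample_id: str
    outcome_class: str  # a mutation category, or WILD_TYPE
    covariates: Mapping[str, object]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Four cells with fixed orientation: a=exposed&event, b=exposed&no-event,
    c=unexposed&event, d=unexposed&no-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    """An odds ratio with its 95% CI, or an explicit reason it is undefined."""

    or_point: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    undefined_reason: str | None = None  # zero_cell | not_converged
    adjusted: bool = False
    covariate_set: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return self.or_point is not None


def build_record_units(
    participants: Sequence[Participant], mutations: Sequence[MutationRecord]
) -> list[RecordUnit]:
    """Expand a cohort into mutation records plus wild-type records.

    Every mutation's sample must exist in the participant table; orphan
    sample ids raise.  ``len(result) == len(mutations) + #wild-type``.
    """
    by_id = {p.sample_id: p for p in participants}
    orphans = sorted({m.sample_id for m in mutations} - set(by_id))
    if orphans:
        raise ValueError(f"mutations reference unknown sample ids: {orphans}")

    def _covariates(p: Participant) -> dict:
        age_group = None
        if p.age_years is not None:
            age_group = ">=66" if p.age_years >= AGE_CUTOFF else "<66"
        return {
            "age_years": p.age_years,
            "age_group": age_group,
            "sex": p.sex,
            "ethnicity": p.ethnicity,
            "residence": p.residence,
            "tobacco_opium": p.tobacco_opium,
            "tea_interval": p.tea_interval,
        }

    records = [
        RecordUnit(m.sample_id, m.category, _covariates(by_id[m.sample_id]))
        for m in mutations
    ]
    mutated = {m.sample_id for m in mutations}
    for p in participants:
        if p.sample_id not in mutated:
            records.append(RecordUnit(p.sample_id, WILD_TYPE, _covariates(p)))
    return records


def crude_or(table: ContingencyTable2x2, haldane: bool = False) -> AssociationResult:
    """Crude odds ratio (a*d)/(b*c) with a Woolf 95% CI.

    Zero-cell tables are undefined with reason ``zero_cell`` unless
    ``haldane=True`` adds 0.5 to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.has_zero_cell:
        if not haldane:
            return AssociationResult(None, undefined_reason="zero_cell")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    low, high = _woolf(a, b, c, d)
    return AssociationResult(point, low, high)


def woolf_ci(table: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Woolf CI for the odds ratio: exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d))."""
    if table.has_zero_cell:
        raise ValueError("Woolf CI undefined with a zero cell")
    return _woolf(table.a, table.b, table.c, table.d, level)


def _woolf(a, b, c, d, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf((1 + level) / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


# -- logistic regression by IRLS ---------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with convergence diagnostics."""

    params: np.ndarray
    cov: np.ndarray | None
    converged: bool
    separation: bool
    n_iter: int
    loglik: float
    columns: tuple[str, ...]


SEPARATION_NORM = 15.0  # |log-odds| beyond this flags (quasi-)separation


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit logit P(y=1) = X beta by iteratively reweighted least squares.

    Convergence is declared on the change in log-likelihood; separation
    is detected by a diverging coefficient norm (any |beta_j| above 15 on
    the log-odds scale at termination, or numerically singular weights).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, None, False, True, it, ll, ())
        beta = beta + step
    eta = np.clip(X @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    separation = bool(np.max(np.abs(beta)) > SEPARATION_NORM)
    cov = None
    if converged:
        w = mu * (1 - mu)
        try:
            cov = np.linalg.inv((X.T * w) @ X)
        except np.linalg.LinAlgError:
            separation = True
    return LogisticFit(beta, cov, converged, separation, it, ll, ())


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous columns + reference-coded dummies."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "age_years":
            cols.append(df["age_years"].to_numpy(dtype=float))
            names.append("age_years")
            continue
        levels, ref = COVARIATE_LEVELS[cov]
        for lev in levels:
            if lev == ref:
                continue
            cols.append((df[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    # collinearity check on the complete-case design
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix over columns {names}")
    return X, names


def fit_logistic(
    records: Sequence[RecordUnit],
    outcome: Callable[[str], bool],
    covariates: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict[str, AssociationResult]:
    """Adjusted odds ratios per non-reference covariate level.

    Records are complete-case filtered on the requested covariates.  The
    outcome is a predicate on the record's outcome class.  Levels whose
    coefficient cannot be estimated (separation / iteration cap) are
    reported undefined with reason ``not_converged``.
    """
    df = pd.DataFrame(
        [
            {**r.covariates, "_y": 1.0 if outcome(r.outcome_class) else 0.0}
            for r in records
        ]
    )
    df = df.dropna(subset=[c for c in covariates])
    y = df["_y"].to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome is constant after complete-case filtering")
    X, names = _design_matrix(df, covariates)
    fit = irls_logistic(X, y, max_iter=max_iter, tol=tol)
    cov_tuple = tuple(covariates)
    out: dict[str, AssociationResult] = {}
    z = stats.norm.ppf(0.975)
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        # separation invalidates only the diverging coefficient(s); the
        # remaining levels stay estimable and are reported
        se2 = fit.cov[j, j] if fit.cov is not None else float("nan")
        bad = (not fit.converged) or fit.cov is None \
            or abs(fit.params[j]) > SEPARATION_NORM \
            or not math.isfinite(se2) or se2 <= 0
        if bad:
            out[name] = AssociationResult(
                None, undefined_reason="not_converged", adjusted=True,
                covariate_set=cov_tuple,
            )
            continue
        se = math.sqrt(fit.cov[j, j])
        out[name] = AssociationResult(
            math.exp(fit.params[j]),
            math.exp(fit.params[j] - z * se),
            math.exp(fit.params[j] + z * se),
            adjusted=True,
            covariate_set=cov_tuple,
        )
    return out


# -- the published-table layout ---------------------------------------------

ADJUSTMENT_COVARIATES = (
    "age_years", "sex", "ethnicity", "residence", "tobacco_opium", "tea_interval",
)


def stratum_table(
    records: Sequence[RecordUnit], category: str, covariate: str, level: str, ref: str
) -> ContingencyTable2x2:
    """2x2 table (level vs reference stratum, category vs all other records)."""
    a = b = c = d = 0
    for r in records:
        val = r.covariates.get(covariate)
        if val is None:
            continue
        is_event = r.outcome_class == category
        if val == level:
            a, b = a + is_event, b + (not is_event)
        elif val == ref:
            c, d = c + is_event, d + (not is_event)
    return ContingencyTable2x2(a, b, c, d)


def category_strata_counts(
    records: Sequence[RecordUnit], category: str, covariate: str
) -> dict[str, tuple[int, int, float]]:
    """Per-stratum (event count, records, percent) for one category."""
    out = {}
    levels, _ = COVARIATE_LEVELS[covariate]
    for lev in levels:
        in_stratum = [r for r in records if r.covariates.get(covariate) == lev]
        n = len(in_stratum)
        k = sum(r.outcome_class == category for r in in_stratum)
        out[lev] = (k, n, 100.0 * k / n if n else float("nan"))
    return out


def association_table(
    participants: Sequence[Participant],
    mutations: Sequence[MutationRecord],
    target_categories: Sequence[str] = ("GC>AT", "GC>AT_CpG", "GC>TA"),
    adjusted: bool = True,
) -> dict:
    """Counts, crude and adjusted ORs per target category and characteristic.

    Each target category (or ``WILD_TYPE``) is contrasted against all
    other records.  Crude ORs are per-level 2x2 tables vs the reference
    level; adjusted ORs come from one multivariate model per category
    with age continuous — except for the categorical age-group rows,
    whose model swaps in the age-group variable (they are not adjusted
    for continuous age).  Complete-case per analysis.
    """
    records = build_record_units(participants, mutations)
    report: dict = {"n_records": len(records), "categories": {}}
    for cat in target_categories:
        cat_report: dict = {}
        # continuous age: adjusted model only (a crude per-unit OR is also given)
        if adjusted:
            adj_main = _safe_fit(records, cat, ADJUSTMENT_COVARIATES)
            adj_agegrp = _safe_fit(
                records, cat, ("age_group",) + ADJUSTMENT_COVARIATES[1:]
            )
            cat_report["age_years"] = {
                "adjusted": adj_main.get("age_years",
                                         AssociationResult(None, undefined_reason="not_converged")),
            }
        for cov in COVARIATE_LEVELS:
            levels, ref = COVARIATE_LEVELS[cov]
            counts = category_strata_counts(records, cat, cov)
            rows = {}
            for lev in levels:
                k, n, pct = counts[lev]
                row: dict = {"count": k, "records": n, "percent": pct}
                if lev == ref:
                    row["crude"] = "ref"
                else:
                    row["crude"] = crude_or(stratum_table(records, cat, cov, lev, ref))
                    if adjusted:
                        source = adj_agegrp if cov == "age_group" else adj_main
                        row["adjusted"] = source.get(
                            f"{cov}[{lev}]",
                            AssociationResult(None, undefined_reason="not_converged",
                                              adjusted=True),
                        )
                rows[lev] = row
            cat_report[cov] = rows
        report["categories"][cat] = cat_report
    return report


def _safe_fit(records, category: str, covariates) -> dict[str, AssociationResult]:
    try:
        return fit_logistic(records, lambda oc: oc == category, covariates)
    except (ValueError, np.linalg.LinAlgError):
        return {}
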