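"""Cohort statistics: group comparison, residualized and partial
correlation, covariate-adjusted logistic regression, two-rater ICC, and
the cohort exclusion filter.

Conventions (each an explicit, auditable default):

* "rank-sum" comparison = two-sample Mann-Whitney U, two-sided; exact
  permutation null for small tie-free samples, otherwise the normal
  approximation with tie and continuity corrections.
* Logistic pseudo-R2: Nagelkerke reported as headline, Cox-Snell emitted
  alongside.
* ICC form: ICC(2,1) — two-way random effects, absolute agreement,
  single measures — with the F-based 95% confidence interval.
* mTICI enters regressions as ordinal 0..4 (grades 0,1,2a,2b,3) by
  default; a binary success flag (>= 2b) is available. Sex is coded
  F=0, M=1. Covariates are never standardized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import MTICI_ORDINAL

__all__ = [
    "StatsConfig", "StatsReport", "SchemaError", "DegenerateDataError",
    "filter_cohort", "mann_whitney", "ols_residuals", "spearman_corr",
    "logistic_fit", "partial_corr", "icc_two_way", "analyze_cohort",
]


class SchemaError(ValueError):
    """Missing or malformed input columns/fields."""


class DegenerateDataError(ValueError):
    """Data admit no meaningful estimate (constant input, separation...)."""


# ---------------------------------------------------------------------------
# cohort filter

#: Occlusion sites measurable for perviousness (M1 or proximal M2).
ELIGIBLE_SITES = {"m1", "m2-proximal", "m2_proximal", "proximal-m2", "proximal_m2"}

EXCLUSION_CRITERIA = ("distal_occlusion", "residual_flow", "slice_thickness")


def filter_cohort(records):
    """Apply the exclusion criteria in their stated order.

    Exclusions, first matching criterion wins: (1) occlusion beyond the
    proximal M2 segment, (2) residual blood flow through the occlusion,
    (3) slice thickness strictly greater than 3 mm.

    Returns ``(kept_records, tally)`` where tally maps criterion name to
    the number of records it removed.
    """
    kept, tally = [], {c: 0 for c in EXCLUSION_CRITERIA}
    for i, rec in enumerate(records):
        for fld in ("occlusion_site", "residual_flow", "slice_thickness_mm"):
            if getattr(rec, fld, None) is None:
                raise SchemaError(f"record {getattr(rec, 'id', i)!r} missing field {fld!r}")
        if str(rec.occlusion_site).lower() not in ELIGIBLE_SITES:
            tally["distal_occlusion"] += 1
        elif bool(rec.residual_flow):
            tally["residual_flow"] += 1
        elif float(rec.slice_thickness_mm) > 3.0:
            tally["slice_thickness"] += 1
        else:
            kept.append(rec)
    return kept, tally


# ---------------------------------------------------------------------------
# elementary tests

def mann_whitney(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U with method reporting.

    Exact permutation null when both groups are small (max n <= 8) and
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction. Returns ``(U, p, method)`` with U counted for
    ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if max(a.size, b.size) <= 8 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "normal-approximation"


def _design_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Intercept-plus-covariates design from a DataFrame/array/None."""
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n and X.shape[1] == n:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != n:
        raise SchemaError("covariate rows do not match response length")
    return np.column_stack([np.ones(n), X]), ["intercept"] + names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise DegenerateDataError(
            f"rank-deficient design; collinear column(s): {bad or names}"
        )


def ols_residuals(y, covariates=None) -> np.ndarray:
    """Least-squares residuals of ``y`` on covariates plus an intercept."""
    y = np.asarray(y, dtype=float)
    X, names = _design_matrix(covariates, len(y))
    if len(y) <= X.shape[1]:
        raise DegenerateDataError(
            f"need n > {X.shape[1]} observations for {X.shape[1] - 1} predictors"
        )
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses exact permutation enumeration for tie-free samples
    with n <= 7, otherwise the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise DegenerateDataError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 7 and not ties:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        null = [
            float(np.corrcoef(rx, perm)[0, 1]) for perm in permutations(ry)
        ]
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(sps.spearmanr(x, y).pvalue)


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticReport:
    coefficients: dict[str, float]
    wald_p: dict[str, float]
    r2_nagelkerke: float
    r2_coxsnell: float
    converged: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "wald_p": self.wald_p,
            "r2_nagelkerke": self.r2_nagelkerke,
            "r2_coxsnell": self.r2_coxsnell,
            "converged": self.converged,
            "n": self.n,
        }


def logistic_fit(outcome, covariates) -> LogisticReport:
    """Maximum-likelihood binary logistic regression with Wald tests.

    Raises :class:`DegenerateDataError` on one-class outcomes, rank
    deficiency, or complete separation (detected rather than silently
    diverging).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise SchemaError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("both outcome classes must be present")
    X, names = _design_matrix(covariates, len(y))
    if len(y) <= X.shape[1]:
        raise DegenerateDataError("need more observations than parameters")
    _check_full_rank(X, names)

    model = sm.Logit(y, X)
    try:
        fit = model.fit(method="newton", tol=1e-8, maxiter=200, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise DegenerateDataError(f"separation: {exc}") from exc
    if np.any(np.abs(fit.params) > 1e3):
        raise DegenerateDataError(
            "separation: unbounded coefficient estimates"
        )

    n = len(y)
    ll1 = float(fit.llf)
    ll0 = float(fit.llnull)
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    r2_max = 1.0 - math.exp(2.0 * ll0 / n)
    return LogisticReport(
        coefficients=dict(zip(names, map(float, fit.params))),
        wald_p=dict(zip(names, map(float, fit.pvalues))),
        r2_nagelkerke=r2_cs / r2_max if r2_max > 0 else float("nan"),
        r2_coxsnell=r2_cs,
        converged=bool(fit.mle_retvals.get("converged", True)),
        n=n,
    )


# ---------------------------------------------------------------------------
# partial correlation and ICC

def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized x and y.

    p-value from the t distribution with ``n - k - 2`` degrees of
    freedom (k = number of covariates). With no covariates this is the
    ordinary Pearson correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = 0 if covariates is None else _design_matrix(covariates, n)[0].shape[1] - 1
    if n <= k + 2:
        raise DegenerateDataError("need n > number of covariates + 2")
    rx = ols_residuals(x, covariates)
    ry = ols_residuals(y, covariates)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateDataError("residualized variable is constant")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), dof))
    return r, p


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    label: str = "ICC(2,1) two-way random, absolute agreement, single measures"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "label": self.label,
        }


def icc_two_way(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based confidence interval.

    ``ratings`` is an (n, 2) table (subjects x raters) with no missing
    cells; the estimate comes from the two-way ANOVA mean squares and
    the CI follows the standard single-measure absolute-agreement
    formulas.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[1] != 2:
        raise SchemaError("ratings must be an n x 2 table")
    n, k = R.shape
    if n < 5:
        raise DegenerateDataError("need at least 5 subjects")
    if np.any(~np.isfinite(R)):
        raise SchemaError("ratings contain missing cells")

    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    if np.ptp(row_means) == 0:
        raise DegenerateDataError("zero between-subject variance")

    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((R - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI with Satterthwaite degrees of freedom
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    denom = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = (a * msc + b * mse) ** 2 / denom if denom > 0 else (n - 1) * (k - 1)
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return ICCResult(estimate=float(icc), ci_low=float(lower), ci_high=float(upper))


# ---------------------------------------------------------------------------
# full cohort analysis

COVARIATE_COLUMNS = ("age", "sex", "slice_thickness_mm", "mtici", "procedure_time_min")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    mtici_coding: str = "ordinal"    # "ordinal" | "binary"
    pseudo_r2: str = "nagelkerke"


@dataclass
class StatsReport:
    group_summaries: dict
    wilcoxon: dict | None = None
    logistic: dict | None = None
    spearman_residual: dict | None = None
    partial_corr: dict | None = None
    icc: dict | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_summaries": self.group_summaries,
            "wilcoxon": self.wilcoxon,
            "logistic": self.logistic,
            "spearman_residual": self.spearman_residual,
            "partial_corr": self.partial_corr,
            "icc": self.icc,
            "skipped": self.skipped,
            "config": self.config,
        }

    def summary_text(self) -> str:
        lines = ["Cohort analysis", "=" * 15]
        for name, g in self.group_summaries.items():
            lines.append(
                f"{name}: n={g['n']}, index mean={g['mean']:.3f}, SD={g['sd']:.3f}"
            )
        if self.wilcoxon:
            w = self.wilcoxon
            lines.append(
                f"Rank-sum comparison: U={w['statistic']:.1f}, p={w['p']:.4g} "
                f"({w['method']})"
            )
        if self.logistic:
            lo = self.logistic
            lines.append(
                "Logistic (favorable outcome): "
                f"index coef={lo['coefficients']['cta_index']:.3f} "
                f"(p={lo['wald_p']['cta_index']:.4g}), "
                f"Nagelkerke R2={lo['r2_nagelkerke']:.3f}"
            )
        if self.spearman_residual:
            s = self.spearman_residual
            lines.append(
                f"Residualized index vs discharge NIHSS: Spearman r={s['r']:.3f}, "
                f"p={s['p']:.4g}"
            )
        if self.partial_corr:
            pc = self.partial_corr
            lines.append(
                f"Index vs mTICI (partial, age+thickness): r={pc['r']:.3f}, "
                f"p={pc['p']:.4g}"
            )
        if self.icc:
            ic = self.icc
            lines.append(
                f"Interrater {ic['label']}: {ic['estimate']:.3f} "
                f"[{ic['ci_low']:.3f}, {ic['ci_high']:.3f}]"
            )
        for name, reason in self.skipped.items():
            lines.append(f"skipped {name}: {reason}")
        return "\n".join(lines)


def _covariate_frame(records, config: StatsConfig) -> pd.DataFrame:
    rows = []
    for r in records:
        if config.mtici_coding == "binary":
            mtici_val = 1.0 if MTICI_ORDINAL[r.mtici] >= 3 else 0.0  # >= 2b
        else:
            mtici_val = float(MTICI_ORDINAL[r.mtici])
        rows.append(
            {
                "age": float(r.age),
                "sex": 0.0 if r.sex == "F" else 1.0,
                "slice_thickness_mm": float(r.slice_thickness_mm),
                "mtici": mtici_val,
                "procedure_time_min": float(r.procedure_time_min),
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(records, rater_pairs: pd.DataFrame | None = None,
                   config: StatsConfig | None = None) -> StatsReport:
    """Run the full statistical battery on a measured cohort.

    Analyses whose preconditions fail are skipped with a recorded
    reason; schema violations raise before anything runs. Deterministic
    and invariant to record order.
    """
    config = config or StatsConfig()
    records = list(records)
    if not records:
        raise SchemaError("empty cohort")
    for i, r in enumerate(records):
        for fld in ("cta_index",) + tuple(c for c in COVARIATE_COLUMNS):
            if getattr(r, fld, None) is None:
                raise SchemaError(f"record {getattr(r, 'id', i)!r} missing field {fld!r}")

    # order-invariance: analyses run on an id-sorted copy
    records = sorted(records, key=lambda r: str(r.id))
    index = np.array([r.cta_index for r in records])
    cov = _covariate_frame(records, config)
    report = StatsReport(group_summaries={}, config={
        "alpha": config.alpha,
        "mtici_coding": config.mtici_coding,
        "pseudo_r2": config.pseudo_r2,
    })

    with_outcome = [r for r in records if r.mrs90 is not None]
    fav = np.array([r.cta_index for r in with_outcome if r.favorable])
    nonfav = np.array([r.cta_index for r in with_outcome if not r.favorable])
    report.group_summaries = {
        "favorable": _summary(fav),
        "non_favorable": _summary(nonfav),
        "all": _summary(index),
    }

    if len(fav) >= 5 and len(nonfav) >= 5:
        u, p, method = mann_whitney(fav, nonfav)
        report.wilcoxon = {"statistic": u, "p": p, "method": method}

        out_idx = [i for i, r in enumerate(records) if r.mrs90 is not None]
        y = np.array([1.0 if records[i].favorable else 0.0 for i in out_idx])
        X = pd.concat(
            [pd.Series(index[out_idx], name="cta_index"), cov.iloc[out_idx].reset_index(drop=True)],
            axis=1,
        )
        try:
            report.logistic = logistic_fit(y, X).to_dict()
        except DegenerateDataError as exc:
            report.skipped["logistic"] = str(exc)
    else:
        reason = (
            "fewer than 5 records per outcome group"
            if with_outcome
            else "no mrs90 outcomes present"
        )
        report.skipped["wilcoxon"] = reason
        report.skipped["logistic"] = reason

    try:
        resid = ols_residuals(index, cov)
        nihss_post = np.array([r.nihss_post for r in records], dtype=float)
        r, p = spearman_corr(resid, nihss_post)
        report.spearman_residual = {"r": r, "p": p}
    except DegenerateDataError as exc:
        report.skipped["spearman_residual"] = str(exc)

    try:
        r, p = partial_corr(
            index, cov["mtici"].to_numpy(), cov[["age", "slice_thickness_mm"]]
        )
        report.partial_corr = {
            "r": r, "p": p, "covariates": ["age", "slice_thickness_mm"],
        }
    except DegenerateDataError as exc:
        report.skipped["partial_corr"] = str(exc)

    if rater_pairs is not None:
        try:
            rp = rater_pairs.sort_values("id") if "id" in rater_pairs else rater_pairs
            icc = icc_two_way(rp[["rater1", "rater2"]].to_numpy(), alpha=config.alpha)
            report.icc = icc.to_dict()
        except DegenerateDataError as exc:
            report.skipped["icc"] = str(exc)
    else:
        report.skipped["icc"] = "no rater-pair table supplied"

    return report


def _summary(x: np.ndarray) -> dict:
    if len(x) == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
    }
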