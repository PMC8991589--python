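"""Evaluation of case-control risk scores.

Metrics follow the conventions of small-panel PRS validation studies:

* IQ-OR — odds ratio per control-distribution interquartile-range increase
  of the score (logistic slope on score/IQR, Wald 95% CI);
* Q4-vs-Q1 OR — cross-product odds ratio of the extreme control-defined
  score quartiles (Woolf log-scale CI, Haldane-Anscombe +0.5 when needed);
* AUC — Mann-Whitney statistic with the Hanley-McNeil closed-form standard
  error;
* decile calibration — observed vs expected log odds ratios per
  control-defined score decile against a pooled middle-decile reference,
  summarized by a through-origin least-squares slope (the O/E OR; 1 means
  well calibrated);
* residual adjustment — replacing scores by their OLS residuals against
  non-genetic risk factors (or an external absolute-risk column) before
  re-computing all metrics;
* interaction scan — per-pair product-term Wald tests with a Bonferroni
  threshold of alpha / C(n_snps, 2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .containers import GenotypeMatrix, status_to_binary

__all__ = [
    "EvaluationReport",
    "InteractionScanResult",
    "CalibrationResult",
    "iq_or",
    "quartile_or",
    "auc_ci",
    "calibration",
    "oe_slope",
    "residual_adjust",
    "interaction_scan",
    "bonferroni_alpha",
    "evaluate_prs",
]

CLASSICAL_RISK_FACTORS = [
    "age",
    "age_menarche",
    "live_births",
    "family_history",
    "bmi",
    "menopausal",
]


@dataclass
class CalibrationResult:
    table: pd.DataFrame  # per-bin: counts, mean score, expected/observed log-OR
    slope: float
    ci: tuple[float, float]
    reference_bins: tuple[int, ...]
    haldane_used: bool


@dataclass
class EvaluationReport:
    iq_or: float
    iq_or_ci: tuple[float, float]
    q4_vs_q1_or: float
    q4_vs_q1_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    calibration: CalibrationResult
    adjustment: str = "none"
    case_set: str = "overall"

    def as_row(self) -> dict:
        return {
            "case_set": self.case_set,
            "adjustment": self.adjustment,
            "q4_vs_q1_or": self.q4_vs_q1_or,
            "q4_vs_q1_lo": self.q4_vs_q1_ci[0],
            "q4_vs_q1_hi": self.q4_vs_q1_ci[1],
            "iq_or": self.iq_or,
            "iq_or_lo": self.iq_or_ci[0],
            "iq_or_hi": self.iq_or_ci[1],
            "oe_or": self.calibration.slope,
            "oe_or_lo": self.calibration.ci[0],
            "oe_or_hi": self.calibration.ci[1],
            "auc": self.auc,
            "auc_lo": self.auc_ci[0],
            "auc_hi": self.auc_ci[1],
        }


@dataclass
class InteractionScanResult:
    pairs: pd.DataFrame  # snp_i, snp_j, delta, p, flagged
    bonferroni_alpha: float
    n_nominal: int
    n_significant: int


def _split(scores: np.ndarray, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=float)
    if set(np.unique(status)) - {0.0, 1.0}:
        raise ValueError("status must be 0/1")
    cases = scores[status == 1]
    controls = scores[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def iq_or(scores: np.ndarray, status: np.ndarray) -> tuple[float, tuple[float, float]]:
    """OR per control-IQR increase: logistic slope of status on score/IQR."""
    cases, controls = _split(scores, status)
    iqr = float(np.percentile(controls, 75) - np.percentile(controls, 25))
    if iqr <= 0:
        raise ValueError("control IQR is zero")
    x = np.asarray(scores, dtype=float) / iqr
    fit = sm.Logit(np.asarray(status, float), sm.add_constant(x)).fit(disp=0)
    b, se = fit.params[1], fit.bse[1]
    return float(np.exp(b)), (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))


def _woolf_ci(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float]]:
    """OR = (a*d)/(b*c) with Woolf log-scale 95% CI from table
    [[a, b], [c, d]] = [[cases_top, controls_top], [cases_bottom, controls_bottom]]."""
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, (orr * math.exp(-1.96 * se), orr * math.exp(1.96 * se))


def quartile_or(
    scores: np.ndarray, status: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Extreme-quartile OR with quartile cut points from controls only."""
    cases, controls = _split(scores, status)
    cuts = np.percentile(controls, [25, 50, 75])
    if len(np.unique(cuts)) < 3:
        raise ValueError("control quartile cut points are not distinct")
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=float)
    q = np.searchsorted(cuts, scores, side="right")  # 0..3
    cells = {}
    for quart in (0, 3):
        in_q = q == quart
        cells[quart] = (float(np.sum(in_q & (status == 1))), float(np.sum(in_q & (status == 0))))
        if sum(cells[quart]) == 0:
            raise ValueError(f"quartile {quart + 1} contains no samples")
    a, b = cells[3]  # cases/controls in Q4
    c, d = cells[0]  # cases/controls in Q1
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return _woolf_ci(a, b, c, d)


def auc_ci(scores: np.ndarray, status: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (ties count 1/2) with Hanley-McNeil 95% CI."""
    cases, controls = _split(scores, status)
    nc, nn = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    a = (ranks[:nc].sum() - nc * (nc + 1) / 2) / (nc * nn)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (nc - 1) * (q1 - a * a) + (nn - 1) * (q2 - a * a)) / (nc * nn)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return float(a), (float(lo), float(hi))


def calibration(
    scores: np.ndarray,
    status: np.ndarray,
    n_bins: int = 10,
    reference: str = "middle",
) -> CalibrationResult:
    """Decile calibration with an O/E-OR slope.

    Bins are control-score quantile bins.  The reference is the pooled pair
    of middle bins (``"middle"``, so expected log-ORs straddle zero) or the
    bottom bin (``"first"``).  For each non-reference bin the expected
    log-OR is the bin-mean score minus the reference-mean score (the score
    is already on the log-OR scale) and the observed log-OR comes from the
    2x2 case-control table of the bin against the reference (+0.5 Haldane
    correction when a cell is empty, flagged).  The O/E OR is the
    through-origin least-squares slope of observed on expected log-ORs, with
    a t-based 95% CI from the regression standard error.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cases, controls = _split(scores, status)
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=float)
    cuts = np.percentile(controls, np.linspace(0, 100, n_bins + 1)[1:-1])
    bins = np.searchsorted(cuts, scores, side="right")
    if reference == "middle":
        ref_bins = (n_bins // 2 - 1, n_bins // 2) if n_bins % 2 == 0 else (n_bins // 2,)
    elif reference == "first":
        ref_bins = (0,)
    else:
        raise ValueError("reference must be 'middle' or 'first'")
    in_ref = np.isin(bins, ref_bins)
    ref_cases = float(np.sum(in_ref & (status == 1)))
    ref_controls = float(np.sum(in_ref & (status == 0)))
    ref_mean = float(scores[in_ref].mean())

    rows = []
    haldane = False
    for d in range(n_bins):
        in_d = bins == d
        n_case = float(np.sum(in_d & (status == 1)))
        n_ctrl = float(np.sum(in_d & (status == 0)))
        if n_case + n_ctrl == 0:
            raise ValueError(f"calibration bin {d + 1} is empty")
        mean_score = float(scores[in_d].mean())
        if d in ref_bins:
            rows.append((d + 1, n_case, n_ctrl, mean_score, 0.0, 0.0, True))
            continue
        expected = mean_score - ref_mean
        a, b, c, dd = n_case, n_ctrl, ref_cases, ref_controls
        if min(a, b, c, dd) == 0:
            a, b, c, dd = a + 0.5, b + 0.5, c + 0.5, dd + 0.5
            haldane = True
        observed = math.log((a * dd) / (b * c))
        rows.append((d + 1, n_case, n_ctrl, mean_score, expected, observed, False))
    table = pd.DataFrame(
        rows,
        columns=["bin", "n_cases", "n_controls", "mean_score",
                 "expected_log_or", "observed_log_or", "is_reference"],
    )
    nr = table[~table["is_reference"]]
    slope, ci = oe_slope(
        nr["expected_log_or"].to_numpy(), nr["observed_log_or"].to_numpy()
    )
    return CalibrationResult(table=table, slope=slope, ci=ci,
                             reference_bins=tuple(b + 1 for b in ref_bins),
                             haldane_used=haldane)


def oe_slope(
    expected: np.ndarray, observed: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Through-origin least-squares slope of observed on expected log-ORs
    (sum(xy)/sum(x^2)) with a t-based 95% CI from the regression SE."""
    x = np.asarray(expected, dtype=float)
    yv = np.asarray(observed, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("expected log-ORs are all zero; slope undefined")
    slope = float(np.sum(x * yv) / sxx)
    m = len(x)
    resid = yv - slope * x
    if m > 1:
        se = math.sqrt(float(np.sum(resid**2)) / ((m - 1) * sxx))
        tq = float(stats.t.ppf(0.975, m - 1))
        ci = (slope - tq * se, slope + tq * se)
    else:
        ci = (float("-inf"), float("inf"))
    return slope, ci


def residual_adjust(
    scores: np.ndarray, covariate_table: pd.DataFrame, mode: str = "classical"
) -> np.ndarray:
    """OLS residuals of the score on non-genetic risk factors.

    ``classical`` regresses on age, age at menarche, live births, family
    history, BMI and menopausal status (booleans as 0/1 indicators);
    ``gail`` regresses on the externally computed 5-year absolute risk
    column only.  The residuals feed every downstream metric unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if mode == "classical":
        cols = CLASSICAL_RISK_FACTORS
    elif mode == "gail":
        cols = ["external_5yr_risk"]
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")
    X = covariate_table[cols].copy()
    for c in cols:
        if X[c].dtype == bool or X[c].dtype == object:
            X[c] = X[c].astype(float) if X[c].dtype == bool else (
                X[c].map({"yes": 1.0, "no": 0.0, "pre": 0.0, "post": 1.0})
            )
    Xv = X.to_numpy(dtype=float)
    bad = np.isnan(Xv).any(axis=1)
    if bad.any():
        ids = covariate_table.loc[bad, "sample_id"].tolist() if "sample_id" in covariate_table else list(np.flatnonzero(bad))
        raise ValueError(f"missing covariate values for samples {ids[:10]}")
    design = np.hstack([np.ones((len(scores), 1)), Xv])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    return scores - design @ coef


def bonferroni_alpha(n_snps: int, alpha: float = 0.05) -> float:
    """Corrected per-pair threshold alpha / C(n_snps, 2)."""
    n_pairs = n_snps * (n_snps - 1) // 2
    if n_pairs == 0:
        raise ValueError("need at least 2 SNPs")
    return alpha / n_pairs


def interaction_scan(
    g: GenotypeMatrix, t: pd.DataFrame, alpha: float = 0.05
) -> InteractionScanResult:
    """Pairwise SNP x SNP interaction screen.

    For every unordered pair, logistic regression of status on the two
    dosages and their product; the product term's Wald P is reported, with a
    likelihood-ratio fallback (flagged) under separation.  A 24-SNP panel
    yields 276 pairs and a Bonferroni threshold of 0.05/276 ~ 1.8e-4.
    """
    if g.n_snps < 2:
        raise ValueError("interaction scan needs at least 2 SNPs")
    y = status_to_binary(t)
    if np.isnan(g.dosages).any():
        raise ValueError("interaction_scan requires an imputed matrix")
    rows = []
    for i, j in itertools.combinations(range(g.n_snps), 2):
        xi, xj = g.dosages[:, i], g.dosages[:, j]
        X = sm.add_constant(np.column_stack([xi, xj, xi * xj]))
        flagged = False
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not np.isfinite(fit.bse[3]):
                raise RuntimeError("separation")
            delta, p = float(fit.params[3]), float(fit.pvalues[3])
        except Exception:
            flagged = True
            lr = LogisticRegression(C=1e6, max_iter=2000)
            lr.fit(X[:, 1:], y)
            delta = float(lr.coef_[0, 2])
            lr0 = LogisticRegression(C=1e6, max_iter=2000)
            lr0.fit(X[:, 1:3], y)
            def _ll(model, Z):
                pr = np.clip(model.predict_proba(Z)[:, 1], 1e-12, 1 - 1e-12)
                return float(np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
            stat = max(0.0, 2 * (_ll(lr, X[:, 1:]) - _ll(lr0, X[:, 1:3])))
            p = float(stats.chi2.sf(stat, 1))
        rows.append((g.snp_ids[i], g.snp_ids[j], delta, p, flagged))
    pairs = pd.DataFrame(rows, columns=["snp_i", "snp_j", "delta", "p", "flagged"])
    corr = bonferroni_alpha(g.n_snps, alpha)
    return InteractionScanResult(
        pairs=pairs,
        bonferroni_alpha=corr,
        n_nominal=int((pairs["p"] < alpha).sum()),
        n_significant=int((pairs["p"] < corr).sum()),
    )


def evaluate_prs(
    scores: np.ndarray,
    status: np.ndarray,
    covariate_table: pd.DataFrame | None = None,
    adjustments: tuple[str, ...] = ("none",),
    case_set: str = "overall",
    n_bins: int = 10,
) -> list[EvaluationReport]:
    """One report per requested adjustment (``none`` / ``gail`` /
    ``classical``), each holding IQ-OR, extreme-quartile OR, AUC and the
    decile calibration summary."""
    reports = []
    for adj in adjustments:
        if adj == "none":
            s = np.asarray(scores, dtype=float)
        else:
            if covariate_table is None:
                raise ValueError("covariate_table required for adjustment")
            s = residual_adjust(scores, covariate_table, mode=adj)
        iq, iq_ci = iq_or(s, status)
        q4, q4_ci = quartile_or(s, status)
        a, a_ci = auc_ci(s, status)
        cal = calibration(s, status, n_bins=n_bins)
        reports.append(
            EvaluationReport(
                iq_or=iq, iq_or_ci=iq_ci,
                q4_vs_q1_or=q4, q4_vs_q1_ci=q4_ci,
                auc=a, auc_ci=a_ci,
                calibration=cal,
                adjustment=adj, case_set=case_set,
            )
        )
    return reports
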