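"""Cross-sectional association and discrimination statistics.

Enrichment and subphenotype odds ratios (logistic and
proportional-odds ordinal regression, Wald inference), extreme-quartile
and score-bin contrasts, ROC/AUC via the Mann-Whitney identity with the
DeLong paired comparison test, onset-age-stratified AUC, and screening
predictive values at an assumed population prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationWarning)

from .genotypes import GenotypeMatrix
from .scores import ScoreSet

_Z95 = stats.norm.ppf(0.975)
_COEF_DIVERGED = 25.0  # |log OR| beyond this is numerically separated


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges, no estimate is reported."""


@dataclass
class AssocResult:
    outcome: str
    exposure: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    covariates: list[str] = field(default_factory=list)
    model: str = "logistic"
    flag: str | None = None

    def row(self) -> dict:
        return {"outcome": self.outcome, "exposure": self.exposure,
                "or": self.odds_ratio, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p_value,
                "n": self.n_used, "model": self.model,
                "covariates": "+".join(self.covariates) or "none",
                "flag": self.flag or ""}


@dataclass
class RocResult:
    auc: float
    n_cases: int
    n_controls: int
    comparison_p: float | None = None
    label: str | None = None


@dataclass
class PredictiveValues:
    cutoff: float | None
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positive_rate: float
    assumed_prevalence: float

    def __post_init__(self) -> None:
        pi, s, sp = self.assumed_prevalence, self.sensitivity, self.specificity
        expected = pi * s + (1 - pi) * (1 - sp)
        if abs(self.positive_rate - expected) > 1e-12:
            raise ValueError("positive_rate inconsistent with sens/spec/prev")


def _design(exposure, covariates) -> tuple[np.ndarray, list[str]]:
    exposure = np.asarray(exposure, float)
    cols = [exposure]
    names = ["exposure"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(float))
            names.append(str(c))
    X = np.column_stack(cols)
    return X, names


def fit_logistic(
    outcome,
    exposure,
    covariates=None,
    outcome_name: str = "outcome",
    exposure_name: str = "grs_continuous",
) -> AssocResult:
    """Maximum-likelihood logistic fit; OR = exp(exposure coefficient).

    Newton-Raphson with Wald 95% CI and p.  Perfect separation and rank
    deficiency raise rather than returning a silent estimate.
    """
    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X, names = _design(exposure, covariates)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, Xc).fit(method="newton", maxiter=100,
                                      tol=1e-10, disp=0)
        except (PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"perfect separation detected: {exc}")
    beta, se = res.params[1], res.bse[1]
    if abs(beta) > _COEF_DIVERGED or not np.isfinite(se):
        raise SeparationError("diverging coefficient; data are separated")
    return AssocResult(outcome_name, exposure_name,
                       float(np.exp(beta)),
                       float(np.exp(beta - _Z95 * se)),
                       float(np.exp(beta + _Z95 * se)),
                       float(res.pvalues[1]), int(len(y)),
                       names[1:], "logistic")


def fit_ordinal(
    outcome,
    exposure,
    covariates=None,
    outcome_name: str = "outcome",
    exposure_name: str = "grs_continuous",
) -> AssocResult:
    """Proportional-odds (cumulative logit) fit, one common OR.

    The reported OR is for being in a *higher* outcome category per unit
    of exposure, matching the logistic convention; with two categories
    the fit coincides with :func:`fit_logistic`.
    """
    y = pd.Series(outcome).astype(int)
    if y.nunique() < 2:
        raise ValueError("ordinal outcome collapses to a single category")
    X, names = _design(exposure, covariates)
    endog = pd.Series(pd.Categorical(y.to_numpy(), ordered=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, X, distr="logit")
        res = model.fit(method="bfgs", gtol=1e-12, maxiter=1000, disp=0)
    k = X.shape[1]
    beta = float(np.asarray(res.params)[0])
    se = float(np.asarray(res.bse)[0])
    if abs(beta) > _COEF_DIVERGED or not np.isfinite(se):
        raise SeparationError("diverging ordinal coefficient")
    z = beta / se
    return AssocResult(outcome_name, exposure_name,
                       float(np.exp(beta)),
                       float(np.exp(beta - _Z95 * se)),
                       float(np.exp(beta + _Z95 * se)),
                       float(2 * stats.norm.sf(abs(z))), int(len(y)),
                       names[1:k], "ordinal")


def quartile_or(
    outcome,
    scores: ScoreSet,
    covariates=None,
    outcome_name: str = "outcome",
) -> AssocResult:
    """High-vs-low extreme-quartile OR for a binary outcome.

    Restricts to quartiles 1 and 4 of the score set and fits a logistic
    model on the high-quartile indicator plus any covariates.
    """
    if scores.quartile is None:
        raise ValueError("quartiles not assigned")
    q = np.asarray(scores.quartile, float)
    keep = np.isin(q, (1, 4))
    y = np.asarray(outcome)[keep]
    high = (q[keep] == 4).astype(float)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates).loc[keep].reset_index(drop=True)
    res = fit_logistic(y, high, cov, outcome_name, "quartile_high_vs_low")
    return res


def or_by_score_bins(
    outcome,
    scores: ScoreSet,
    bin_edges=(7, 8, 9, 10, 11),
    covariates=None,
    outcome_name: str = "outcome",
) -> list[AssocResult]:
    """Per-bin ORs against the lowest score bin.

    Bins are left-closed right-open between consecutive edges, with
    open-ended extremes (< first edge = reference, > last edge = top).
    An empty bin yields a result flagged ``undefined`` rather than being
    dropped.
    """
    edges = np.asarray(bin_edges, float)
    grs = np.asarray(scores.grs, float)
    y = np.asarray(outcome)
    bin_idx = np.digitize(grs, edges)  # 0 = reference bin
    if (bin_idx == 0).sum() == 0:
        raise ValueError("reference bin is empty")
    labels = [f"<{edges[0]:g}"] + [
        f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])
    ] + [f">{edges[-1]:g}"]
    results = []
    for b in range(1, len(edges) + 1):
        label = labels[b]
        keep = np.isin(bin_idx, (0, b))
        if (bin_idx == b).sum() == 0:
            results.append(AssocResult(outcome_name, f"score_bin {label}",
                                       np.nan, np.nan, np.nan, np.nan, 0,
                                       [], "logistic", flag="undefined"))
            continue
        cov = None
        if covariates is not None:
            cov = pd.DataFrame(covariates).loc[keep].reset_index(drop=True)
        try:
            res = fit_logistic(y[keep], (bin_idx[keep] == b).astype(float),
                               cov, outcome_name, f"score_bin {label}")
        except (SeparationError, ValueError) as exc:
            res = AssocResult(outcome_name, f"score_bin {label}",
                              np.nan, np.nan, np.nan, np.nan,
                              int(keep.sum()), [], "logistic",
                              flag=str(exc))
        results.append(res)
    return results


def roc_auc(score, status) -> RocResult:
    """AUC by the Mann-Whitney identity; tied pairs count one half."""
    score = np.asarray(score, float)
    status = np.asarray(status, bool)
    m, n = int(status.sum()), int((~status).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    auc = (ranks[status].sum() - m * (m + 1) / 2) / (m * n)
    return RocResult(float(auc), m, n)


def _delong_components(score, status):
    """Structural components V10 (cases) and V01 (controls)."""
    x = np.asarray(score, float)[np.asarray(status, bool)]
    y = np.asarray(score, float)[~np.asarray(status, bool)]
    # psi(x, y) = 1 if x > y, 1/2 if tie
    v10 = np.array([np.mean((xi > y) + 0.5 * (xi == y)) for xi in x])
    v01 = np.array([np.mean((x > yj) + 0.5 * (x == yj)) for yj in y])
    return v10, v01


def compare_auc_paired(score_a, score_b, status) -> tuple[float, float, RocResult, RocResult]:
    """DeLong test for the paired AUC difference of two scores.

    Returns (auc_difference, two-sided p, roc_a, roc_b).  Identical
    rankings give zero variance; by convention p = 1 (flagged in the
    RocResult comparison_p fields).
    """
    status = np.asarray(status, bool)
    ra, rb = roc_auc(score_a, status), roc_auc(score_b, status)
    v10a, v01a = _delong_components(score_a, status)
    v10b, v01b = _delong_components(score_b, status)
    m, n = ra.n_cases, ra.n_controls
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = ra.auc - rb.auc
    if var <= 0 or not np.isfinite(var):
        p = 1.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / np.sqrt(var)))
    ra.comparison_p = rb.comparison_p = p
    return float(diff), p, ra, rb


def auc_by_onset_strata(
    score,
    status,
    age_at_diagnosis,
    bin_edges=(20.0, 40.0),
) -> list[RocResult]:
    """AUC of stratum cases (by age at diagnosis) against all controls.

    Strata are left-closed right-open ([0, e1), [e1, e2), ..., [ek, inf));
    controls are shared across strata.  An empty stratum yields an
    undefined (NaN) result rather than an error.
    """
    score = np.asarray(score, float)
    status = np.asarray(status, bool)
    age = np.asarray(age_at_diagnosis, float)
    edges = np.asarray(bin_edges, float)
    labels = [f"<{edges[0]:g}"] + [
        f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])
    ] + [f">{edges[-1]:g}"]
    strata = np.digitize(age, edges)  # left-closed: age == edge -> upper bin
    out = []
    for s in range(len(edges) + 1):
        sel = (~status) | (status & (strata == s) & np.isfinite(age))
        if not (status & (strata == s) & np.isfinite(age)).any():
            out.append(RocResult(np.nan, 0, int((~status).sum()),
                                 label=labels[s]))
            continue
        r = roc_auc(score[sel], status[sel])
        r.label = labels[s]
        out.append(r)
    return out


def predictive_values(
    score,
    outcome,
    cutoff: float,
    assumed_prevalence: float,
) -> PredictiveValues:
    """Screening PPV/NPV at a score cut-off and assumed prevalence.

    Sensitivity and specificity come from the empirical 2x2 at the
    cut-off (score >= cutoff counts as test-positive); predictive values
    are prevalence-adjusted by Bayes' rule:
    PPV = pi*s / (pi*s + (1-pi)(1-sp)),
    NPV = (1-pi)*sp / ((1-pi)*sp + pi*(1-s)).
    """
    if not 0 < assumed_prevalence < 1:
        raise ValueError("assumed_prevalence must be in (0,1)")
    score = np.asarray(score, float)
    y = np.asarray(outcome, bool)
    if y.all() or not y.any():
        raise ValueError("outcome must contain both classes")
    pos = score >= cutoff
    if pos.all() or not pos.any():
        raise ValueError("cutoff produces no positives or no negatives")
    sens = float(pos[y].mean())
    spec = float((~pos)[~y].mean())
    return _from_sens_spec(sens, spec, assumed_prevalence, cutoff)


def predictive_values_inverse(
    specificity: float,
    assumed_prevalence: float,
    positive_rate: float,
) -> PredictiveValues:
    """Solve for sensitivity given specificity, prevalence and the
    overall positive-test rate, then derive PPV/NPV.

    From positive_rate = pi*s + (1-pi)(1-sp):
    s = (positive_rate - (1-pi)(1-sp)) / pi.
    """
    pi, sp, r = assumed_prevalence, specificity, positive_rate
    sens = (r - (1 - pi) * (1 - sp)) / pi
    if not 0 <= sens <= 1:
        raise ValueError(f"implied sensitivity {sens:.4f} outside [0,1]")
    return _from_sens_spec(sens, sp, pi, cutoff=None)


def _from_sens_spec(sens, spec, prevalence, cutoff) -> PredictiveValues:
    pi = prevalence
    ppv = pi * sens / (pi * sens + (1 - pi) * (1 - spec))
    npv = (1 - pi) * spec / ((1 - pi) * spec + pi * (1 - sens))
    rate = pi * sens + (1 - pi) * (1 - spec)
    return PredictiveValues(cutoff, float(sens), float(spec),
                            float(ppv), float(npv), float(rate), float(pi))


def per_snp_outcome_scan(
    genotypes: GenotypeMatrix,
    outcome,
    covariates=None,
    model: str = "ordinal",
) -> list[AssocResult]:
    """Association scan of every panel SNP dosage against one outcome.

    One proportional-odds (or logistic) fit per SNP; p-values are
    reported unadjusted.  Constant-dosage or separated SNPs are flagged
    and the scan continues.
    """
    fit = fit_ordinal if model == "ordinal" else fit_logistic
    results = []
    for j, sid in enumerate(genotypes.snp_ids):
        dose = genotypes.dosage[:, j]
        if np.ptp(dose) == 0:
            results.append(AssocResult("outcome", sid, np.nan, np.nan,
                                       np.nan, np.nan, len(dose), [],
                                       model, flag="constant dosage"))
            continue
        try:
            res = fit(outcome, dose, covariates, "outcome", sid)
            res.model = model
            results.append(res)
        except (SeparationError, np.linalg.LinAlgError) as exc:
            results.append(AssocResult("outcome", sid, np.nan, np.nan,
                                       np.nan, np.nan, len(dose), [],
                                       model, flag=str(exc)))
    return results


def assoc_table(results: list[AssocResult]) -> pd.DataFrame:
    """Tidy one-row-per-fit results table (machine-readable Table 1 twin)."""
    return pd.DataFrame([r.row() for r in results])
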