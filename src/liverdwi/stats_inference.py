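"""Group comparisons and diagnostic-accuracy statistics.

This module implements the statistical stage of the diagnostic analysis:

* exact Mann-Whitney U and Fisher's exact test for clinical/lab group
  comparisons;
* linear mixed model (random intercept per patient) for parameters measured
  twice per patient, with per-group estimated means and 95% CIs;
* empirical ROC analysis with the Youden-optimal cutoff and exact
  (Clopper-Pearson) sensitivity/specificity intervals;
* DeLong placement-value variance for AUC confidence intervals and paired
  AUC comparisons;
* logistic combination of two markers scored by the AUC of the fitted
  probabilities.

Conventions: two-sided tests throughout; the positive class is "BA";
sensitivity/specificity are reported in percent, AUC on [0, 1].
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "GroupComparisonResult",
    "DiagnosticResult",
    "mann_whitney_u_exact",
    "fisher_exact_2x2",
    "lmm_group_comparison",
    "clopper_pearson_interval",
    "roc_with_youden",
    "delong_ci",
    "delong_paired_test",
    "logistic_combined_auc",
]


# ---------------------------------------------------------------------------
# rank tests

@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table, rows = groups, columns = outcome levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def mann_whitney_u_exact(x, y, exact_limit: int = 20) -> tuple[float, float]:
    """Mann-Whitney U test; exact permutation null for small samples.

    Returns ``(U, p)`` where U is the statistic of the first sample.  When
    the combined sample size is at most ``exact_limit`` the two-sided p is
    computed by exhaustive enumeration of all C(n, n1) group labelings of
    the observed (mid-ranked) values, counting labelings whose U is at least
    as far from the null mean n1*n2/2 as the observed one — valid with ties.
    Larger samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_limit:
        mean_u = n1 * n2 / 2
        obs_dev = abs(u1 - mean_u)
        count = total = 0
        rank_sum_offset = n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - rank_sum_offset
            # tolerance guards float midrank arithmetic in the comparison
            if abs(u - mean_u) >= obs_dev - 1e-9:
                count += 1
            total += 1
        return u1, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p (sum of hypergeometric probabilities of
    same-margin tables no more probable than the observed one)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# linear mixed model

@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-group estimated means with 95% CIs and the group-effect p."""

    parameter: str
    estimates: dict[str, tuple[float, float, float]]  # group -> (est, lo, hi)
    p_value: float
    method: str  # "lmm-wald-z" | "patient-mean-ols"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for g, (est, lo, hi) in self.estimates.items():
            if not (lo <= est <= hi):
                raise ValueError(f"CI for {g} does not contain the estimate")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _patient_mean_ols(df: pd.DataFrame, parameter: str,
                      flags: tuple[str, ...]) -> GroupComparisonResult:
    """Fallback: two-sample t on patient means (equal-variance)."""
    pm = df.groupby(["patient_id", "group"], sort=False)["value"].mean().reset_index()
    groups = list(dict.fromkeys(pm["group"]))
    a = pm.loc[pm["group"] == groups[0], "value"].to_numpy()
    b = pm.loc[pm["group"] == groups[1], "value"].to_numpy()
    t_res = stats.ttest_ind(a, b, equal_var=True)
    # pooled-variance SEs for per-group means, t-based CIs
    dof = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / dof
    tcrit = stats.t.ppf(0.975, dof)
    est = {}
    for g, v in ((groups[0], a), (groups[1], b)):
        half = tcrit * math.sqrt(sp2 / v.size)
        est[g] = (float(v.mean()), float(v.mean() - half), float(v.mean() + half))
    return GroupComparisonResult(parameter, est, float(t_res.pvalue),
                                 "patient-mean-ols", flags + ("lmm_fallback",))


def lmm_group_comparison(measurements: pd.DataFrame, parameter: str,
                         group_col: str = "group",
                         patient_col: str = "patient_id") -> GroupComparisonResult:
    """Mixed model for repeated ROI measurements: fixed group effect,
    random intercept per patient.

    ``measurements`` needs columns ``patient_col``, ``group_col`` and the
    parameter column; each patient contributes its repeated slice-level
    rows.  Inference on the group effect is a Wald z test (no small-sample
    degree-of-freedom correction is available in the fitting backend; the
    method string records this).  Singular or non-converging fits fall back
    to an equal-variance t test on patient means, flagged ``lmm_fallback``.
    """
    import statsmodels.api as sm

    df = measurements[[patient_col, group_col, parameter]].rename(
        columns={patient_col: "patient_id", group_col: "group",
                 parameter: "value"}).dropna()
    groups = list(dict.fromkeys(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    counts = df.groupby("group")["patient_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least two patients per group")

    indicator = (df["group"] == groups[1]).astype(float)
    exog = np.column_stack([np.ones(len(df)), indicator])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["value"].to_numpy(), exog,
                               groups=df["patient_id"].to_numpy())
            fit = model.fit(reml=True)
        beta = fit.fe_params
        cov = np.asarray(fit.cov_params())[:2, :2]
        p = float(fit.pvalues[1])
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))
                and np.isfinite(p)):
            raise ValueError("non-finite mixed-model estimates")
    except Exception:
        return _patient_mean_ols(df, parameter, ())

    z = stats.norm.ppf(0.975)
    est = {}
    for i, g in enumerate(groups):
        contrast = np.array([1.0, float(i)])
        mu = float(contrast @ beta)
        se = math.sqrt(float(contrast @ cov @ contrast))
        est[g] = (mu, mu - z * se, mu + z * se)
    return GroupComparisonResult(parameter, est, p, "lmm-wald-z")


# ---------------------------------------------------------------------------
# diagnostic accuracy

def clopper_pearson_interval(successes: int, n: int,
                             level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI endpoints in percent (beta-quantile inversion)."""
    if int(successes) != successes or int(n) != n:
        raise ValueError("counts must be integers")
    successes, n = int(successes), int(n)
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return 100.0 * lo, 100.0 * hi


def _placement_values(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components: V10 (one per positive, the fraction of
    negatives it outranks) and V01; ties count one half."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_mann_whitney(scores, labels) -> float:
    """Empirical AUC = P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    v10, _ = _placement_values(pos, neg)
    return float(v10.mean())


@dataclass(frozen=True)
class DiagnosticResult:
    """Cutoff-level operating point plus AUC for one marker."""

    marker: str
    orientation: str            # "lower" | "higher"  (which side indicates BA)
    cutoff: float
    criterion: str              # e.g. "<= 1.165" or "> 188"
    sensitivity: float          # percent
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for v, (lo, hi) in ((self.sensitivity, self.sensitivity_ci),
                            (self.specificity, self.specificity_ci)):
            if not (0 <= lo <= v + 1e-9 and v - 1e-9 <= hi <= 100):
                raise ValueError("sens/spec CI must contain the point estimate")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")


def roc_with_youden(scores, labels, orientation: str = "higher",
                    marker: str = "") -> DiagnosticResult:
    """Empirical ROC with the Youden-optimal cutoff.

    ``labels`` are truthy for the positive (BA) class.  ``orientation``
    states which side of the cutoff indicates the positive class: with
    ``"higher"`` the test is positive when score > cutoff, with ``"lower"``
    when score <= cutoff.  Candidate cutoffs are the observed score values;
    ties in the Youden index are broken toward higher specificity.  AUC is
    the Mann-Whitney probability (ties half-weighted) with a DeLong CI;
    sensitivity/specificity get exact Clopper-Pearson intervals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher' or 'lower'")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    oriented = scores if orientation == "higher" else -scores

    best = None  # ((youden, specificity), cutoff, tp, tn)
    for c in np.unique(scores):
        if orientation == "higher":
            tp = int((pos > c).sum())
            tn = int((neg <= c).sum())
        else:
            tp = int((pos <= c).sum())
            tn = int((neg > c).sum())
        spec = tn / neg.size
        youden = tp / pos.size + spec - 1.0
        key = (youden, spec)
        if best is None or key > best[0]:
            best = (key, float(c), tp, tn)
    _, cutoff, tp, tn = best
    criterion = (f"> {cutoff:g}" if orientation == "higher"
                 else f"<= {cutoff:g}")
    sens = 100.0 * tp / pos.size
    spec = 100.0 * tn / neg.size
    auc, auc_lo, auc_hi, auc_flags = _auc_with_delong_ci(oriented, labels)
    return DiagnosticResult(
        marker=marker, orientation=orientation, cutoff=cutoff,
        criterion=criterion,
        sensitivity=sens,
        sensitivity_ci=clopper_pearson_interval(tp, pos.size),
        specificity=spec,
        specificity_ci=clopper_pearson_interval(tn, neg.size),
        auc=auc, auc_ci=(auc_lo, auc_hi),
        n_pos=int(pos.size), n_neg=int(neg.size), flags=auc_flags,
    )


def _delong_variance(scores, labels) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    v10, v01 = _placement_values(pos, neg)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if pos.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if neg.size > 1 else 0.0
    return auc, s10 / pos.size + s01 / neg.size


def _auc_with_delong_ci(scores, labels, level: float = 0.95):
    auc, var = _delong_variance(scores, labels)
    flags: tuple[str, ...] = ()
    if var <= 0:
        flags = ("degenerate_variance",)
        return auc, auc, auc, flags
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half), flags


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC and its DeLong normal-approximation CI: ``(auc, lo, hi)``."""
    auc, lo, hi, _ = _auc_with_delong_ci(scores, labels, level)
    return auc, lo, hi


def delong_paired_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong comparison of two markers on the same observations.

    Returns a dict with ``auc_a``, ``auc_b``, ``delta`` (a - b), ``se``,
    ``z``, ``p`` (two-sided normal) and ``flags``.  A degenerate variance
    (e.g. identical scores) yields p = 1 with a flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("paired comparison requires equally shaped inputs")
    pos_a, neg_a = a[labels], a[~labels]
    pos_b, neg_b = b[labels], b[~labels]
    m, n = pos_a.size, neg_a.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10a, v01a = _placement_values(pos_a, neg_a)
    v10b, v01b = _placement_values(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_a - auc_b

    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var_delta <= 0:
        return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "se": 0.0,
                "z": 0.0, "p": 1.0, "flags": ("degenerate_variance",)}
    se = math.sqrt(var_delta)
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "se": se,
            "z": z, "p": p, "flags": ()}


# ---------------------------------------------------------------------------
# logistic combination

def logistic_combined_auc(marker_a, marker_b, labels,
                          marker: str = "combined") -> DiagnosticResult:
    """Diagnostic performance of the logistic combination of two markers.

    Fits a maximum-likelihood logistic model of the (standardized) two
    predictors on the class label, then scores each subject by the fitted
    linear predictor and evaluates it like any other marker (higher score
    indicates the positive class).  Complete separation is detected and
    flagged; the separating direction is then recovered with a lightly
    ridge-penalized fit, which leaves the AUC of the separating score
    intact.
    """
    import statsmodels.api as sm

    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("inputs must be equally shaped, one row per patient")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least two patients per class")

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    X = sm.add_constant(np.column_stack([standardize(a), standardize(b)]),
                        has_constant="add")
    flags: tuple[str, ...] = ()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels.astype(float), X).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params)
        if not fit.mle_retvals.get("converged", False) or \
                not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise ValueError("separation suspected")
    except Exception:
        flags = ("complete_separation",)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels.astype(float), X).fit_regularized(
                alpha=1e-3, disp=0, maxiter=500)
        params = np.asarray(fit.params)

    score = X @ params
    res = roc_with_youden(score, labels, orientation="higher", marker=marker)
    return DiagnosticResult(**{**res.__dict__, "flags": res.flags + flags})
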