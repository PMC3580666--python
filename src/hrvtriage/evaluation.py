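"""Paired diagnostic-accuracy statistics for comparing two risk scores.

Implements the battery used to compare a continuous risk score with an
ordinal comparator on the same patients:

* ROC curves and AUROC via the rank (Mann–Whitney) formulation with tie
  correction;
* paired AUROC difference with a z-test using DeLong's placement-value
  covariance (Hanley–McNeil available as an option);
* threshold metrics (sensitivity, specificity, PPV, NPV, LR+) with Wilson
  score CIs for proportions and a log-method CI for LR+;
* McNemar tests for paired sensitivity (within events) and specificity
  (within non-events), with a Tango-type score CI for the difference of
  paired proportions;
* a generalized score test (cluster-robust GEE score, chi-square 1 df) for
  paired positive/negative predictive values;
* risk-strata event-rate tables with exact (Clopper–Pearson) binomial CIs.

Percentages are on the 0–100 scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_Z95 = stats.norm.ppf(0.975)


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given inputs."""


# ----------------------------------------------------------------------
# confidence intervals for proportions
# ----------------------------------------------------------------------

def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as percentages."""
    if n == 0:
        return (math.nan, math.nan)
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (100 * max(0.0, centre - half), 100 * min(1.0, centre + half))


def exact_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval, as percentages."""
    if n == 0:
        return (math.nan, math.nan)
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return (100 * lo, 100 * hi)


# ----------------------------------------------------------------------
# 2x2 diagnostic table
# ----------------------------------------------------------------------

@dataclass
class DiagnosticTable:
    """2x2 confusion counts with the derived diagnostic metrics.

    Metrics are percentages with 95% CIs (Wilson by default); LR+ carries a
    log-method CI. Undefined metrics (zero denominator) are ``nan``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    ci_method: str = "wilson"
    metrics: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.metrics = self._derive()

    def _prop(self, k: int, n: int) -> tuple[float, float, float]:
        if n == 0:
            return (math.nan, math.nan, math.nan)
        ci = wilson_ci(k, n) if self.ci_method == "wilson" else exact_ci(k, n)
        return (100 * k / n, *ci)

    def _derive(self) -> dict[str, tuple[float, float, float]]:
        m = {
            "sensitivity": self._prop(self.tp, self.tp + self.fn),
            "specificity": self._prop(self.tn, self.fp + self.tn),
            # predictive values are degenerate without both outcome classes
            "ppv": (self._prop(self.tp, self.tp + self.fp)
                    if self.tp + self.fn > 0 else (math.nan,) * 3),
            "npv": (self._prop(self.tn, self.tn + self.fn)
                    if self.fp + self.tn > 0 else (math.nan,) * 3),
        }
        m["lr_pos"] = self._lr_pos()
        return m

    def _lr_pos(self) -> tuple[float, float, float]:
        """LR+ = sens / (1 - spec) with the standard log-method CI."""
        pos, neg = self.tp + self.fn, self.fp + self.tn
        if pos == 0 or neg == 0 or self.fp == 0 or self.tp == 0:
            if pos and neg and self.tp and self.fp == 0:
                return (math.inf, math.nan, math.nan)
            return (math.nan, math.nan, math.nan)
        sens = self.tp / pos
        fpr = self.fp / neg
        lr = sens / fpr
        se_log = math.sqrt((1 - sens) / self.tp + (1 - fpr) / self.fp)
        return (lr, lr * math.exp(-_Z95 * se_log), lr * math.exp(_Z95 * se_log))

    @property
    def sensitivity(self) -> float:
        return self.metrics["sensitivity"][0]

    @property
    def specificity(self) -> float:
        return self.metrics["specificity"][0]

    @property
    def ppv(self) -> float:
        return self.metrics["ppv"][0]

    @property
    def npv(self) -> float:
        return self.metrics["npv"][0]

    @property
    def lr_pos(self) -> float:
        return self.metrics["lr_pos"][0]


def threshold_metrics(scores: np.ndarray, labels: np.ndarray, cutoff: float,
                      ci_method: str = "wilson") -> DiagnosticTable:
    """Dichotomize at ``score >= cutoff`` and tabulate the 2x2 metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return DiagnosticTable(tp, fp, fn, tn, ci_method=ci_method)


def reconstruct_2x2(n: int, n_pos: int, sens_pct: float, spec_pct: float,
                    ci_method: str = "wilson") -> DiagnosticTable:
    """Rebuild integer 2x2 counts from a cohort size, event count and the
    reported sensitivity/specificity percentages.

    ``tp = round(sens * n_pos / 100)`` and ``tn = round(spec * (n - n_pos)
    / 100)`` (half away from zero, the usual reporting convention); fn/fp
    by complement. All derived metrics (PPV, NPV, LR+) are then recomputed
    from the integer cells, which makes published tables arithmetically
    checkable.
    """
    if not 0 <= n_pos <= n:
        raise ValueError("need 0 <= n_pos <= n")
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    n_neg = n - n_pos
    tp = int(math.floor(sens_pct * n_pos / 100 + 0.5))
    tn = int(math.floor(spec_pct * n_neg / 100 + 0.5))
    if tp > n_pos or tn > n_neg:
        raise ValueError("rounded cells exceed the class totals")
    return DiagnosticTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn,
                           ci_method=ci_method)


# ----------------------------------------------------------------------
# ROC / AUROC
# ----------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # fraction, descending threshold order
    specificity: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUROC.

    The AUC is the tie-corrected Mann–Whitney concordance
    ``P(s_pos > s_neg) + 0.5 P(s_pos = s_neg)`` computed from midranks; the
    curve is a sweep over the distinct observed score values (appropriate
    for both continuous and ordinal scores).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUROC undefined with a single class")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(scores)[::-1]
    sens = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).mean() for t in thresholds])
    return RocResult(thresholds, sens, spec, float(auc))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-positive and per-negative empirical
    exceedance probabilities (with ties counted half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v_pos = np.array([np.mean((s > neg) + 0.5 * (s == neg)) for s in pos])
    v_neg = np.array([np.mean((pos > s) + 0.5 * (pos == s)) for s in neg])
    return v_pos, v_neg


@dataclass
class PairedComparison:
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str


def compare_auc_paired(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray, method: str = "delong") -> PairedComparison:
    """Paired AUROC difference test on the same patients.

    ``delong`` (default) uses the placement-value covariance of the two
    AUCs; ``hanley-mcneil`` uses the correlated-AUC approximation with the
    placement correlation plugged in. Both report the difference A−B, a
    Wald 95% CI and the two-sided z-test p-value. With identical inputs the
    difference is 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(scores_a).size < 2 or np.unique(scores_b).size < 2:
        raise DegenerateInputError("constant scores: AUROC comparison undefined")
    ra, rb = roc_auc(scores_a, labels), roc_auc(scores_b, labels)
    delta = ra.auc - rb.auc

    va_p, va_n = _placements(scores_a, labels)
    vb_p, vb_n = _placements(scores_b, labels)
    m, n = va_p.size, va_n.size
    # 2x2 covariance of (auc_a, auc_b) from placement values
    s_p = np.cov(np.vstack([va_p, vb_p]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_n = np.cov(np.vstack([va_n, vb_n]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s_p / m + s_n / n
    if method == "delong":
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    elif method == "hanley-mcneil":
        se_a = math.sqrt(cov[0, 0])
        se_b = math.sqrt(cov[1, 1])
        denom = se_a * se_b
        r = cov[0, 1] / denom if denom > 0 else 0.0
        var = se_a**2 + se_b**2 - 2 * r * se_a * se_b
    else:
        raise ValueError(f"unknown method {method!r}")
    if delta == 0 and var <= 0:
        return PairedComparison(0.0, 0.0, 0.0, 1.0, method)
    se = math.sqrt(max(var, 0.0))
    if se == 0:
        p = 0.0 if delta != 0 else 1.0
        return PairedComparison(delta, delta, delta, p, method)
    z = delta / se
    p = 2 * stats.norm.sf(abs(z))
    return PairedComparison(delta, delta - _Z95 * se, delta + _Z95 * se, p, method)


# ----------------------------------------------------------------------
# paired proportion comparisons (McNemar, Tango CI)
# ----------------------------------------------------------------------

def _tango_ci(b: int, c: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Score CI for the difference of paired proportions.

    Inverts the score statistic ``z(d) = (b - c - n d) / sqrt(n (pb + pc -
    d^2))`` with ``(pb, pc)`` the multinomial MLE of the discordant-cell
    probabilities constrained to ``pb - pc = d`` (profiled numerically).
    """
    if n == 0:
        return (math.nan, math.nan)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    n11 = n - b - c  # concordant pairs (pooled)

    def neg_loglik(pc: float, d: float) -> float:
        pb = pc + d
        p0 = 1.0 - pb - pc
        eps = 1e-12
        return -(b * math.log(max(pb, eps)) + c * math.log(max(pc, eps))
                 + n11 * math.log(max(p0, eps)))

    def z_of(d: float) -> float:
        lo = max(0.0, -d) + 1e-9
        hi = (1.0 - d) / 2.0 - 1e-9
        if hi <= lo:
            pc = max(0.0, -d)
        else:
            res = optimize.minimize_scalar(neg_loglik, bounds=(lo, hi),
                                           args=(d,), method="bounded")
            pc = float(res.x)
        pb = pc + d
        var = n * (pb + pc - d * d)
        if var <= 0:
            var = 1e-12
        return (b - c - n * d) / math.sqrt(var)

    d_hat = (b - c) / n

    def lower_eq(d: float) -> float:
        return z_of(d) - z_crit

    def upper_eq(d: float) -> float:
        return z_of(d) + z_crit

    lo_bound = -1.0 + 1e-9
    hi_bound = 1.0 - 1e-9
    try:
        ci_lo = optimize.brentq(lower_eq, lo_bound, d_hat) if lower_eq(lo_bound) * lower_eq(d_hat) < 0 else lo_bound
    except ValueError:
        ci_lo = lo_bound
    try:
        ci_hi = optimize.brentq(upper_eq, d_hat, hi_bound) if upper_eq(d_hat) * upper_eq(hi_bound) < 0 else hi_bound
    except ValueError:
        ci_hi = hi_bound
    return (ci_lo, ci_hi)


def mcnemar_paired(metric: str, flags_a: np.ndarray, flags_b: np.ndarray,
                   labels: np.ndarray) -> PairedComparison:
    """McNemar comparison of paired sensitivities or specificities.

    ``metric`` selects the stratum: ``"sensitivity"`` compares the two
    screen-positive rates among events; ``"specificity"`` compares the
    screen-negative rates among non-events. The chi-square statistic (1 df,
    no continuity correction) uses only the discordant pairs; with no
    discordant pairs p = 1. The difference (A − B, percentage points)
    carries a score-type CI for paired proportions.
    """
    flags_a = np.asarray(flags_a).astype(bool)
    flags_b = np.asarray(flags_b).astype(bool)
    labels = np.asarray(labels).astype(int)
    if metric == "sensitivity":
        sel = labels == 1
        ok_a, ok_b = flags_a[sel], flags_b[sel]
    elif metric == "specificity":
        sel = labels == 0
        ok_a, ok_b = ~flags_a[sel], ~flags_b[sel]
    else:
        raise ValueError("metric must be 'sensitivity' or 'specificity'")
    n = int(sel.sum())
    if n == 0:
        raise DegenerateInputError(f"no patients in the {metric} stratum")
    b = int(np.sum(ok_a & ~ok_b))   # A correct, B wrong
    c = int(np.sum(~ok_a & ok_b))   # B correct, A wrong
    delta = 100.0 * (b - c) / n
    if b + c == 0:
        ci = _tango_ci(b, c, n)
        return PairedComparison(delta, 100 * ci[0], 100 * ci[1], 1.0, "mcnemar")
    chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    ci = _tango_ci(b, c, n)
    return PairedComparison(delta, 100 * ci[0], 100 * ci[1], p, "mcnemar")


# ----------------------------------------------------------------------
# paired predictive values (generalized score test)
# ----------------------------------------------------------------------

def compare_predictive_values(flags_a: np.ndarray, flags_b: np.ndarray,
                              labels: np.ndarray, which: str = "ppv") -> PairedComparison:
    """Generalized score test for paired predictive values (chi-square 1 df).

    Each patient contributes one record per test that calls them positive
    (for PPV; negative for NPV), with the disease state as the response and
    the test identity as the covariate. The statistic is the GEE score test
    for the test-identity effect under working independence with a
    cluster-robust (per-patient) variance — identical predictions give
    p = 1, and the statistic is chi-square with 1 df under the null of
    equal predictive values.
    """
    flags_a = np.asarray(flags_a).astype(bool)
    flags_b = np.asarray(flags_b).astype(bool)
    d = np.asarray(labels).astype(float)
    if which == "ppv":
        in_a, in_b = flags_a, flags_b
        resp = d
    elif which == "npv":
        in_a, in_b = ~flags_a, ~flags_b
        resp = 1.0 - d
    else:
        raise ValueError("which must be 'ppv' or 'npv'")
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 or nb == 0:
        raise DegenerateInputError(f"one score yields no records for {which}")
    pv_a = float(resp[in_a].mean())
    pv_b = float(resp[in_b].mean())
    delta = 100.0 * (pv_a - pv_b)
    if np.array_equal(in_a, in_b):
        return PairedComparison(delta, math.nan, math.nan, 1.0, "generalized-score")

    n_rec = na + nb
    p_bar = (resp[in_a].sum() + resp[in_b].sum()) / n_rec
    z_bar = nb / n_rec  # mean of the test-identity covariate over records
    # per-patient score contributions for the identity-link GEE score test
    e = (in_a * (0.0 - z_bar) + in_b * (1.0 - z_bar)) * (resp - p_bar)
    u = float(e.sum())
    v = float(np.sum(e * e))
    if v <= 0:
        return PairedComparison(delta, math.nan, math.nan, 1.0, "generalized-score")
    chi2 = u * u / v
    p = float(stats.chi2.sf(chi2, df=1))
    return PairedComparison(delta, math.nan, math.nan, p, "generalized-score")


# ----------------------------------------------------------------------
# risk strata
# ----------------------------------------------------------------------

def strata_rates(scores: np.ndarray, labels: np.ndarray,
                 bounds: tuple[float, float] = (40.0, 60.0)) -> list[dict]:
    """Event rates by risk stratum with exact binomial 95% CIs.

    Strata on the 0–100 score: low ``<= bounds[0]``, intermediate
    ``(bounds[0], bounds[1]]``, high ``> bounds[1]``. Empty strata report a
    missing rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    lo, hi = bounds
    masks = {
        "low": scores <= lo,
        "intermediate": (scores > lo) & (scores <= hi),
        "high": scores > hi,
    }
    out = []
    for name, m in masks.items():
        n = int(m.sum())
        k = int(labels[m].sum())
        if n == 0:
            out.append({"stratum": name, "n": 0, "events": 0,
                        "rate_pct": math.nan, "ci_low": math.nan, "ci_high": math.nan})
            continue
        ci = exact_ci(k, n)
        out.append({"stratum": name, "n": n, "events": k,
                    "rate_pct": 100.0 * k / n, "ci_low": ci[0], "ci_high": ci[1]})
    return out
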