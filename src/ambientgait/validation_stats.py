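"""Test-retest reliability and clinical validation statistics.

Covers the statistics layer of the gait study design: intraclass
correlation coefficients (ICC) with label-shuffling permutation tests for
test-retest reliability; outlier-screened Pearson agreement between
device- and stopwatch-derived gait speed; leave-one-out logistic models
for predicting age group and sex from single gait features; standard
two-sample tests; the Fried frailty grouping; binarization of the
Quality of Recovery-15 questionnaire; and the speed x cadence interaction
logistic model for postoperative recovery.

ICC is computed from the ANOVA variance components.  With an n-subject by
k-trial table, the one-way random-effects single-measure form (the
default) is

    ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW)

with MSB/MSW the between/within-subject mean squares; two-way forms
(absolute agreement ICC(2,1) and consistency ICC(3,1)) are selectable.
No multiple-testing adjustment is applied anywhere: p-values and
permutation Q are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "StatsError",
    "IccResult",
    "PermutationResult",
    "ExclusionResult",
    "LoocvResult",
    "InteractionModelResult",
    "icc",
    "icc_permutation",
    "exclude_speed_outliers",
    "loocv_logistic",
    "group_tests",
    "frailty_groups",
    "qor_binarize",
    "qor_interaction_model",
]


class StatsError(ValueError):
    """Raised for degenerate inputs to a statistical routine."""


@dataclass
class IccResult:
    icc: float
    p: float
    form: str       # icc1 | icc2 | icc3
    n: int
    k: int
    msb: float
    msw: float

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise StatsError("ICC cannot exceed 1")


@dataclass
class PermutationResult:
    q: float               # (b + 1) / (n_perm + 1)
    observed: float
    n_perm: int
    null_mean: float
    null_sd: float
    null_quantiles: dict = field(default_factory=dict)


@dataclass
class ExclusionResult:
    kept: np.ndarray       # bool mask over input pairs
    r: float
    p: float
    exclusions: list       # (index, reason) tuples


@dataclass
class LoocvResult:
    accuracy: float
    auc: float
    probabilities: np.ndarray   # held-out predicted P(class 1)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_skipped_folds: int


@dataclass
class InteractionModelResult:
    coefficients: dict          # term -> beta
    interaction_or: float
    ci_low: float
    ci_high: float
    p_interaction: float
    penalized: bool = False     # separation fallback used


def _as_table(pairs) -> np.ndarray:
    """Coerce paired/repeated-trial input into an (n, k) float table."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim == 1:
        raise StatsError("need an (n, k) table of repeated trials")
    if x.ndim == 2 and x.shape[1] > x.shape[0] and x.shape[0] <= 2:
        x = x.T  # accept (k, n) with k of 2
    if np.any(~np.isfinite(x)):
        raise StatsError("repeated-trial table must be complete")
    return x


def _anova_components(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssb = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    ssw = sst - ssb
    sse = sst - ssb - ssc
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    msc = ssc / (k - 1) if k > 1 else 0.0
    mse = sse / ((n - 1) * (k - 1))
    return n, k, msb, msw, msc, mse


def icc(pairs, form: str = "icc1") -> IccResult:
    """Intraclass correlation of an (n subjects x k trials) table.

    ``form``: ``"icc1"`` one-way random effects, single measure (default,
    matching the common R reliability-package default); ``"icc2"`` two-way
    random, absolute agreement, single measure; ``"icc3"`` two-way mixed,
    consistency, single measure.  The analytic p-value tests ICC = 0 via
    the corresponding F ratio.
    """
    x = _as_table(pairs)
    n, k, msb, msw, msc, mse = _anova_components(x)
    if n < 3:
        raise StatsError("need >= 3 subjects")
    if msb + msw == 0:
        raise StatsError("zero between+within variance")
    if form == "icc1":
        val = (msb - msw) / (msb + (k - 1) * msw)
        f = msb / msw if msw > 0 else np.inf
        p = float(stats.f.sf(f, n - 1, n * (k - 1)))
        return IccResult(val, p, form, n, k, msb, msw)
    if form in ("icc2", "icc3"):
        if form == "icc2":
            val = (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
        else:
            val = (msb - mse) / (msb + (k - 1) * mse)
        f = msb / mse if mse > 0 else np.inf
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
        return IccResult(val, p, form, n, k, msb, mse)
    raise StatsError(f"unknown ICC form {form!r}")


def _icc1_pairs_vectorized(x1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """ICC(1) for k=2 tables, vectorized over permutations of trial 2.

    ``X2`` is (B, n): B candidate second-trial vectors against the fixed
    first-trial vector ``x1``.  With k = 2, SSW = sum (x1 - x2)^2 / 2 and
    SSB = 2 * sum (m_i - m)^2 with m_i the pair means.
    """
    n = x1.size
    m = 0.5 * (x1[None, :] + X2)
    g = m.mean(axis=1, keepdims=True)
    msb = 2.0 * np.sum((m - g) ** 2, axis=1) / (n - 1)
    msw = 0.5 * np.sum((x1[None, :] - X2) ** 2, axis=1) / n
    return (msb - msw) / (msb + msw)


def icc_permutation(pairs, n_perm: int = 10000,
                    seed: int | np.random.Generator | None = None,
                    form: str = "icc1") -> PermutationResult:
    """Label-shuffling permutation test for a paired-trials ICC.

    The second-trial vector is shuffled across subjects ``n_perm`` times
    (breaking the pairing while preserving both marginals) and the ICC
    recomputed each time; Q is the fraction of permuted ICCs at least as
    large as the observed one, with the (b + 1) / (n_perm + 1) correction
    so Q is never exactly zero.
    """
    x = _as_table(pairs)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    observed = icc(x, form=form).icc
    x1, x2 = x[:, 0], x[:, 1]
    if x.shape[1] == 2 and form == "icc1":
        perms = np.array([rng.permutation(x2) for _ in range(n_perm)])
        null = _icc1_pairs_vectorized(x1, perms)
    else:
        null = np.empty(n_perm)
        for b in range(n_perm):
            xp = x.copy()
            xp[:, 1] = rng.permutation(x[:, 1])
            null[b] = icc(xp, form=form).icc
    b = int(np.sum(null >= observed))
    qs = np.quantile(null, [0.025, 0.5, 0.975])
    return PermutationResult(
        q=(b + 1) / (n_perm + 1), observed=observed, n_perm=n_perm,
        null_mean=float(null.mean()), null_sd=float(null.std()),
        null_quantiles={"2.5%": qs[0], "50%": qs[1], "97.5%": qs[2]},
    )


def exclude_speed_outliers(device, stopwatch, abs_limit: float = 2.5,
                           sd_limit: float = 2.5) -> ExclusionResult:
    """Screen device-vs-stopwatch speed pairs, then correlate.

    Pairs with stopwatch speed above ``abs_limit`` m/s (physiologically
    implausible: stopwatch user error) are dropped first; then pairs whose
    device-minus-stopwatch difference lies beyond mean +/- ``sd_limit``
    SDs of the differences (device malfunction or reading error) are
    dropped; Pearson r is computed on the remainder.
    """
    d = np.asarray(device, dtype=float)
    s = np.asarray(stopwatch, dtype=float)
    if d.shape != s.shape:
        raise StatsError("device and stopwatch lists must have equal length")
    kept = np.ones(d.size, dtype=bool)
    exclusions = []
    for i in np.flatnonzero(s > abs_limit):
        kept[i] = False
        exclusions.append((int(i), f"stopwatch speed > {abs_limit} m/s"))
    diff = d[kept] - s[kept]
    mu, sd = float(diff.mean()), float(diff.std(ddof=1))
    if sd > 0:
        idx = np.flatnonzero(kept)
        for i in idx[np.abs(diff - mu) > sd_limit * sd]:
            kept[i] = False
            exclusions.append((int(i), f"difference beyond {sd_limit} SD"))
    if kept.sum() < 3:
        raise StatsError("fewer than 3 pairs remain after exclusion")
    r, p = stats.pearsonr(d[kept], s[kept])
    return ExclusionResult(kept=kept, r=float(r), p=float(p),
                           exclusions=exclusions)


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic, ties averaged."""
    ranks = stats.rankdata(scores)
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise StatsError("AUC needs both classes")
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _roc_points(scores: np.ndarray, y: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr, tpr


def loocv_logistic(x, y) -> LoocvResult:
    """Leave-one-out cross-validated single-feature logistic model.

    Each subject is held out in turn; an (unpenalized) logistic regression
    of the binary outcome on the single feature is fit to the rest and the
    held-out subject's class probability predicted.  Accuracy thresholds
    the held-out probabilities at 0.5; AUC is the rank statistic over
    held-out probabilities.  Folds whose training data lack a class are
    skipped and counted.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 10:
        raise StatsError("need n >= 10 for leave-one-out validation")
    if len(np.unique(y)) != 2:
        raise StatsError("both classes must be present")
    probs = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            skipped += 1
            continue
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10,
                                 max_iter=10000)
        clf.fit(x[mask], y[mask])
        probs[i] = clf.predict_proba(x[i:i + 1])[0, 1]
    ok = np.isfinite(probs)
    preds = (probs[ok] >= 0.5).astype(int)
    acc = float(np.mean(preds == y[ok]))
    auc = _rank_auc(probs[ok], y[ok])
    fpr, tpr = _roc_points(probs[ok], y[ok])
    return LoocvResult(accuracy=acc, auc=auc, probabilities=probs,
                       roc_fpr=fpr, roc_tpr=tpr, n_skipped_folds=skipped)


def group_tests(values, groups, test: str = "mann_whitney"):
    """Two-sided two-sample test or correlation; returns (statistic, p).

    ``test``: ``mann_whitney``, ``ks``, ``t`` split ``values`` by the two
    labels in ``groups``; ``pearson`` treats ``groups`` as a second
    continuous variable.
    """
    values = np.asarray(values, dtype=float)
    if test == "pearson":
        other = np.asarray(groups, dtype=float)
        r, p = stats.pearsonr(values, other)
        return float(r), float(p)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise StatsError("two-sample tests need exactly 2 groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need >= 2 observations per group")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ks":
        res = stats.ks_2samp(a, b)
    elif test == "t":
        res = stats.ttest_ind(a, b)
    else:
        raise StatsError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


_FRAILTY_LABELS = ("robust", "prefrail", "frail")


def frailty_groups(fried) -> np.ndarray:
    """Fried frailty phenotype grouping: 0 robust, 1-2 prefrail, >2 frail."""
    f = np.asarray(fried, dtype=int)
    if np.any((f < 0) | (f > 5)):
        raise StatsError("Fried scores must lie in [0, 5]")
    out = np.where(f == 0, "robust", np.where(f <= 2, "prefrail", "frail"))
    return out


def qor_binarize(qor15, cutoff: int = 121) -> np.ndarray:
    """Quality of Recovery-15 binarization: > cutoff good, <= cutoff poor."""
    q = np.asarray(qor15, dtype=float)
    if np.any((q < 0) | (q > 150)):
        raise StatsError("QoR-15 scores must lie in [0, 150]")
    return np.where(q > cutoff, "good", "poor")


def qor_interaction_model(speed, cadence, outcome) -> InteractionModelResult:
    """Logistic model: outcome ~ speed + cadence + speed * cadence.

    Reports the interaction-term odds ratio with its Wald 95% confidence
    interval.  Runnable for any device combination supplying the speed and
    cadence columns.  On separation (non-finite standard errors) a weakly
    L2-penalized fit provides the point estimate, flagged ``penalized``
    with no confidence interval.
    """
    s = np.asarray(speed, dtype=float)
    c = np.asarray(cadence, dtype=float)
    y = np.asarray(outcome).astype(int)
    if len(y) < 20:
        raise StatsError("need n >= 20")
    if len(np.unique(y)) != 2:
        raise StatsError("both outcomes must be present")
    X = np.column_stack([np.ones_like(s), s, c, s * c])
    names = ("const", "speed", "cadence", "speed:cadence")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = fit.params
        se = fit.bse
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
        orr = float(np.exp(beta[3]))
        half = 1.959963984540054 * se[3]
        return InteractionModelResult(
            coefficients=dict(zip(names, map(float, beta))),
            interaction_or=orr,
            ci_low=float(np.exp(beta[3] - half)),
            ci_high=float(np.exp(beta[3] + half)),
            p_interaction=float(fit.pvalues[3]),
            penalized=False,
        )
    except (np.linalg.LinAlgError, PerfectSeparationError):
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=10000)
        clf.fit(X[:, 1:], y)
        beta = np.concatenate([clf.intercept_, clf.coef_[0]])
        return InteractionModelResult(
            coefficients=dict(zip(names, map(float, beta))),
            interaction_or=float(np.exp(beta[3])),
            ci_low=np.nan, ci_high=np.nan, p_interaction=np.nan,
            penalized=True,
        )
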