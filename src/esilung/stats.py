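"""Statistical battery: dependent-correlation tests, heteroscedastic ANOVA,
Games-Howell post-hocs, chi-squared, and cross-validated logistic/ROC.

These are the procedures used to validate a univariate severity score
against CT ground truth: Pearson correlations compared across overlapping
pairs (Steiger's Z), Welch's heteroscedastic one-way ANOVA with
Games-Howell pairwise post-hocs for the three-group comparisons,
chi-squared independence for cluster-versus-stage tables, and a
stratified ten-fold cross-validated univariate logistic classifier
summarised by ROC curves, AUC and a Youden operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import DomainError


# ---------------------------------------------------------------------------
# correlations

def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p: float
    r_jk: float
    r_jh: float
    r_kh: float
    n: int


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Steiger's Z for two dependent overlapping correlations sharing j.

    Tests H0: rho_jk == rho_jh given the correlation r_kh between the two
    non-shared variables, via Fisher z-transforms with the asymptotic
    covariance evaluated at the back-transformed mean correlation.
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 < r < 1.0:
            raise DomainError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise DomainError("need n > 3")
    corr = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(corr)[0] < -1e-10:
        raise DomainError("correlation matrix is not positive semidefinite")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    r_bar = float(np.tanh(0.5 * (z_jk + z_jh)))
    psi = r_kh * (1.0 - 2.0 * r_bar**2) - 0.5 * r_bar**2 * (1.0 - 2.0 * r_bar**2 - r_kh**2)
    c_bar = psi / (1.0 - r_bar**2) ** 2
    z = float((z_jk - z_jh) * np.sqrt((n - 3) / (2.0 - 2.0 * c_bar)))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return SteigerResult(z=z, p=p, r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n)


def steiger_z_bootstrap(xj, xk, xh, n_boot: int = 2000, seed: int = 0) -> SteigerResult:
    """Bootstrap counterpart on raw data: resamples subjects and tests the
    observed difference r_jk - r_jh against its bootstrap spread.

    Offered as the robust reading of the dependent-correlation comparison:
    no normality assumption enters beyond the bootstrap itself.
    """
    xj = np.asarray(xj, float)
    xk = np.asarray(xk, float)
    xh = np.asarray(xh, float)
    n = xj.size
    if not (xk.size == n and xh.size == n) or n <= 3:
        raise DomainError("need three equal-length samples with n > 3")
    r_jk = pearson_r(xj, xk)
    r_jh = pearson_r(xj, xh)
    r_kh = pearson_r(xk, xh)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        j, k, h = xj[idx], xk[idx], xh[idx]
        with np.errstate(invalid="ignore"):
            d = np.corrcoef(j, k)[0, 1] - np.corrcoef(j, h)[0, 1]
        diffs[b] = d
    diffs = diffs[np.isfinite(diffs)]
    se = diffs.std(ddof=1)
    z = float((r_jk - r_jh) / se) if se > 0 else np.inf
    p = float(2.0 * sps.norm.sf(abs(z)))
    return SteigerResult(z=z, p=p, r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass(frozen=True)
class WelchAnovaResult:
    f_star: float
    df1: float
    df2: float
    p: float


def _as_summaries(groups):
    """Normalise raw value sets or (mean, sd, n) triples to summary arrays."""
    means, sds, ns = [], [], []
    for g in groups:
        g = np.asarray(g, dtype=float) if not isinstance(g, tuple) else g
        if isinstance(g, tuple):
            m, s, n = g
        else:
            if g.ndim != 1 or g.size < 2:
                raise DomainError("each group needs n >= 2 raw values")
            m, s, n = g.mean(), g.std(ddof=1), g.size
        if n < 2 or s <= 0:
            raise DomainError("each group needs n >= 2 and sd > 0")
        means.append(float(m))
        sds.append(float(s))
        ns.append(int(n))
    return np.array(means), np.array(sds), np.array(ns)


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way F* test.

    ``groups`` is a list of raw value arrays or of (mean, sd, n) summary
    triples — the statistic depends on the data only through those
    summaries, so printed tables can be tested directly.
    """
    means, sds, ns = _as_summaries(groups)
    k = means.size
    if k < 2:
        raise DomainError("need at least 2 groups")
    w = ns / sds**2
    w_sum = w.sum()
    grand = float((w * means).sum() / w_sum)
    a = float((w * (means - grand) ** 2).sum() / (k - 1))
    lam = float((((1.0 - w / w_sum) ** 2) / (ns - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    f_star = a / b
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * lam) if lam > 0 else np.inf
    p = float(sps.f.sf(f_star, df1, df2)) if f_star > 0 else 1.0
    return WelchAnovaResult(f_star=float(f_star), df1=df1, df2=float(df2), p=p)


def games_howell(groups) -> pd.DataFrame:
    """Games-Howell pairwise post-hoc comparisons on raw value groups.

    Per pair: Welch degrees of freedom and a studentized-range p-value with
    the number of groups as the range parameter.  Returns one row per pair
    with mean difference, standard error, q, df and p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    means, sds, ns = _as_summaries(arrays)
    k = means.size
    if k < 2:
        raise DomainError("need at least 2 groups")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = sds[i] ** 2 / ns[i], sds[j] ** 2 / ns[j]
            diff = means[i] - means[j]
            se = np.sqrt(0.5 * (vi + vj))
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
            rows.append({"group1": i, "group2": j, "mean_diff": float(diff),
                         "se": float(se), "q": float(q), "df": float(df),
                         "p": p})
    return pd.DataFrame(rows)


def chi_squared(table) -> tuple[float, float, float]:
    """Pearson chi-squared independence test (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise DomainError("contingency table must be 2-D and non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DomainError("zero marginal: expected counts vanish")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# logistic classifier + cross-validated ROC

@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    converged: bool
    n_iter: int
    separation: bool = False


def fit_logistic(x, y, max_iter: int = 100, tol: float = 1e-10) -> LogisticFit:
    """Univariate logistic regression by Newton-Raphson maximum likelihood.

    Perfect separation is detected (disjoint class score ranges, or runaway
    coefficients) and flagged; the returned coefficients still rank
    subjects monotonically so downstream ROC analysis remains valid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("labels must be binary 0/1")
    if y.min() == y.max():
        raise DomainError("both classes must be present")
    separated = float(x[y == 1].min()) > float(x[y == 0].max()) or \
        float(x[y == 1].max()) < float(x[y == 0].min())
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        wdiag = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p)
        hess = (X * wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:  # runaway: (quasi-)separation
            separated = True
            break
    return LogisticFit(intercept=float(beta[0]), slope=float(beta[1]),
                       converged=converged, n_iter=it, separation=separated)


def predict_proba(fit: LogisticFit, x) -> np.ndarray:
    return expit(fit.intercept + fit.slope * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ROCResult:
    """Pooled held-out ROC plus per-fold and fold-averaged summaries."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    fold_aucs: np.ndarray
    mean_fpr_grid: np.ndarray = field(repr=False, default=None)
    mean_tpr: np.ndarray = field(repr=False, default=None)

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def _roc_points(y, scores):
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr, thr


def _trapezoid_auc(fpr, tpr) -> float:
    return float(np.trapezoid(tpr, fpr))


def cv_roc(x, y, k_folds: int = 10, seed: int = 0) -> ROCResult:
    """Stratified k-fold cross-validated ROC of a univariate logistic model.

    Per fold the model is fitted on the training split and held-out
    probabilities are scored; the pooled held-out probabilities give the
    reported ROC/AUC (a rank statistic identical to Mann-Whitney U /
    (n1*n2)), while per-fold AUCs and a vertically averaged ROC over a
    common false-positive grid summarise fold variability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if min(n_pos, n_neg) < k_folds:
        raise DomainError("each class must have at least k_folds members")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pooled = np.empty_like(x)
    fold_aucs = []
    grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for train, test in skf.split(x.reshape(-1, 1), y):
        fit = fit_logistic(x[train], y[train])
        probs = predict_proba(fit, x[test])
        pooled[test] = probs
        fpr, tpr, _ = _roc_points(y[test], probs)
        fold_aucs.append(_trapezoid_auc(fpr, tpr))
        tprs.append(np.interp(grid, fpr, tpr))
    fpr, tpr, thr = _roc_points(y, pooled)
    return ROCResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=_trapezoid_auc(fpr, tpr),
        fold_aucs=np.asarray(fold_aucs),
        mean_fpr_grid=grid,
        mean_tpr=np.mean(tprs, axis=0),
    )


def best_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """Youden operating point: maximises sensitivity + specificity - 1,
    ties broken towards higher specificity."""
    if roc.thresholds.size == 0:
        raise DomainError("empty ROC")
    j = roc.sensitivities + roc.specificities - 1.0
    order = np.lexsort((roc.specificities, j))  # last entry = max J, max spec
    k = order[-1]
    return (float(roc.thresholds[k]), float(roc.sensitivities[k]),
            float(roc.specificities[k]))
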