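"""Statistical kernel: single-sample and preranked gene-set enrichment,
permutation and robust regression tests, ROC/Youden cut-point selection,
2x2 association, and Kaplan-Meier / log-rank survival comparison.

The ssGSEA running sum is the package's own implementation (it is the
quantity every later stage consumes); survival estimation delegates to
lifelines and robust standard errors to statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection, ScoreMatrix, TriaxisError

# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Rank-weighted running-sum enrichment of each set in each sample.

    Per sample, features are ranked by abundance ascending (ties get the
    average rank, so scores are invariant to any strictly monotone
    transform of a sample's values).  Walking the features from highest
    to lowest rank, the score is the summed gap between the weighted
    in-set cumulative distribution (rank^alpha weights) and the uniform
    out-of-set cumulative distribution.  With ``normalize`` the whole
    score matrix is divided by its global (max - min), the convention
    used for cross-sample comparability.

    Sets with fewer than 2 genes in the matrix (or no complement) are
    skipped with a warning; an error is raised if nothing survives.
    """
    X = m.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    feat_pos = {f: i for i, f in enumerate(m.feature_ids)}

    usable: list[tuple[str, np.ndarray]] = []
    for s in sets:
        idx = np.array([feat_pos[g] for g in s.genes if g in feat_pos], dtype=int)
        if len(idx) < 2 or len(idx) >= n_feat:
            warnings.warn(f"gene set {s.name!r}: {len(idx)} usable genes; skipped")
            continue
        mask = np.zeros(n_feat, dtype=bool)
        mask[idx] = True
        usable.append((s.name, mask))
    if not usable:
        raise TriaxisError("no gene set has >=2 genes in the matrix")

    ranks = np.apply_along_axis(stats.rankdata, 0, X)  # ascending, average ties
    out = np.empty((len(usable), n_samp))
    for j in range(n_samp):
        r = ranks[:, j]
        order = np.argsort(-r, kind="stable")
        r_sorted = r[order]
        for i, (_, mask) in enumerate(usable):
            ms = mask[order]
            w = np.where(ms, r_sorted**alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~ms) / (n_feat - ms.sum())
            out[i, j] = float(np.sum(p_in - p_out))

    scores = pd.DataFrame(out, index=[n for n, _ in usable], columns=m.sample_ids)
    if normalize:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            scores = scores / rng_
    return ScoreMatrix(scores, alpha=alpha, normalized=normalize, sample_meta=m.sample_meta.copy())


# ---------------------------------------------------------------------------
# Preranked GSEA


def _running_es(stat_sorted: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Classic weighted Kolmogorov-Smirnov enrichment score (max deviation)."""
    w = np.abs(stat_sorted) ** weight
    nr = w[hit].sum()
    n_miss = len(stat_sorted) - hit.sum()
    if nr == 0 or n_miss == 0:
        return 0.0
    steps = np.where(hit, w / nr, -1.0 / n_miss)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def gsea_preranked(
    stat: pd.Series,
    genes,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Preranked GSEA of one gene set against a per-feature statistic.

    The null is gene-label permutation: random sets of equal size.  NES is
    the observed ES divided by the mean |null ES| of matching sign; the
    permutation p-value has a floor of 1/(n_perm+1).
    """
    if stat.isna().any():
        raise TriaxisError("ranking statistic contains NaN")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null")
    gene_set = set(genes)
    hit_full = np.array([g in gene_set for g in stat.index])
    nh = int(hit_full.sum())
    if nh < 2:
        raise TriaxisError("set has <2 genes in the ranking")
    order = np.argsort(-stat.to_numpy(), kind="stable")
    s_sorted = stat.to_numpy()[order]
    hit = hit_full[order]
    es = _running_es(s_sorted, hit, weight)

    rng = np.random.default_rng(seed)
    n = len(s_sorted)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=nh, replace=False)
        h = np.zeros(n, dtype=bool)
        h[idx] = True
        null[b] = _running_es(s_sorted, h, weight)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        raise TriaxisError("no same-sign permutation; NES undefined")
    nes = es / np.mean(np.abs(same_sign))
    # two-sided permutation p against the full null on |ES|: keeps the
    # 1/(n_perm+1) floor and a uniform null distribution
    p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (n_perm + 1)
    return {"es": es, "nes": float(nes), "p": float(p)}


# ---------------------------------------------------------------------------
# Permutation / robust linear fits


@dataclass
class PermFitResult:
    slope: float
    intercept: float
    p_value: float
    n_perm: int
    n_used: int


def permuted_linear_fit(
    x, y, n_perm: int = 5000, seed: int | None = None
) -> PermFitResult:
    """Least-squares slope with a permutation p-value.

    When n! fits within the permutation budget the null is enumerated
    exhaustively and p is the exact fraction of permutations with
    |slope| at least the observed (the identity permutation makes
    p >= 1/n!); otherwise ``n_perm`` random permutations are drawn and
    the add-one estimator (1+k)/(B+1) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise TriaxisError("need paired vectors of length >= 4")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise TriaxisError("x is constant; slope undefined")
    slope = float(xc @ y) / sxx
    intercept = float(y.mean() - slope * x.mean())
    if np.ptp(y) == 0:
        warnings.warn("constant y; p = 1 by convention")
        return PermFitResult(slope, intercept, 1.0, 0, len(x))

    n = len(x)
    tol = 1e-12 * max(1.0, abs(slope))
    if math.factorial(n) <= n_perm:
        perms = np.array(list(_permutations(range(n))))
        slopes = (perms_y := y[perms]) @ xc / sxx
        k = int(np.sum(np.abs(slopes) >= abs(slope) - tol))
        return PermFitResult(slope, intercept, k / len(perms), len(perms), n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        sp = float(xc @ rng.permutation(y)) / sxx
        if abs(sp) >= abs(slope) - tol:
            count += 1
    return PermFitResult(slope, intercept, (1 + count) / (n_perm + 1), n_perm, n)


def robust_linear_fit_iqr(x, y) -> PermFitResult:
    """Two-stage robust fit: IQR residual-outlier removal, then OLS with
    heteroskedasticity-consistent (HC2) slope standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 6:
        raise TriaxisError("need paired vectors of length >= 6")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    # tolerance keeps float-noise residuals of near-perfect fits inside a
    # degenerate (zero-width) fence
    eps = 1e-9 * max(1.0, float(np.max(np.abs(resid))))
    keep = (resid >= q1 - 1.5 * iqr - eps) & (resid <= q3 + 1.5 * iqr + eps)
    if keep.sum() < 4:
        raise TriaxisError("fewer than 4 points survive outlier removal")
    xk, yk = x[keep], y[keep]
    fit = sm.OLS(yk, sm.add_constant(xk)).fit(cov_type="HC2", use_t=True)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    p = 0.0 if (se == 0 or not np.isfinite(se)) else float(fit.pvalues[1])
    return PermFitResult(slope, float(fit.params[0]), p, 0, int(keep.sum()))


# ---------------------------------------------------------------------------
# ROC / Youden


def roc_youden(score, label) -> dict:
    """AUC by the Mann-Whitney identity (ties half credit) and the observed
    cutoff maximizing Youden's J under 'positive iff score >= cutoff'."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    n1 = int(label.sum())
    n0 = len(label) - n1
    if n1 == 0 or n0 == 0:
        raise TriaxisError("both classes must be present")
    ranks = stats.rankdata(score)
    auc = (ranks[label == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    best = (-np.inf, None, None, None)
    for c in np.unique(score):  # ascending: ties in J -> smallest cutoff kept
        pred = score >= c
        sens = float((pred & (label == 1)).sum()) / n1
        spec = float((~pred & (label == 0)).sum()) / n0
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    j, cutoff, sens, spec = best
    return {"auc": float(auc), "cutoff": cutoff, "J": j, "sens": sens, "spec": spec}


# ---------------------------------------------------------------------------
# chi-square association


def chi2_association(table, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 contingency table (df = 1)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise TriaxisError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise TriaxisError("zero margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    assert dof == 1
    return {"chi2": float(chi2), "p": float(p)}


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class SurvivalSplit:
    labels: pd.Series  # 'high' / 'low' (or two arbitrary group names)
    logrank_stat: float
    p_value: float
    curves: dict  # group -> DataFrame(time, survival)


def km_logrank(survival: pd.DataFrame, groups: pd.Series) -> SurvivalSplit:
    """Two-group log-rank test plus per-group product-limit curves.

    ``survival`` must have columns ``time`` and ``event`` indexed like
    ``groups``.  Each group needs at least one member and the pooled data
    at least one event.
    """
    groups = groups.loc[survival.index]
    names = sorted(groups.unique())
    if len(names) != 2:
        raise TriaxisError(f"need exactly 2 groups, got {names}")
    for g in names:
        if (groups == g).sum() == 0:
            raise TriaxisError(f"group {g!r} is empty")
    if survival["event"].sum() == 0:
        raise TriaxisError("no events in survival table")

    a = survival[groups == names[0]]
    b = survival[groups == names[1]]
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    curves = {}
    for g in names:
        sub = survival[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return SurvivalSplit(
        labels=groups,
        logrank_stat=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
    )
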