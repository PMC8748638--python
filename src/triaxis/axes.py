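"""Region-agnostic cluster discovery on signature scores and the
KRAS/MYC/hypoxia axis characterization: Ward clustering of purified
tumour samples, cluster-driver signatures, per-axis ROC separation and
the axis anti-correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .containers import ScoreMatrix, TriaxisError
from .enrichment import PermFitResult, chi2_association, permuted_linear_fit, roc_youden


@dataclass
class ClusterResult:
    labels: pd.Series  # sample -> cluster id (0..k-1)
    linkage: str
    chi2_vs_niche: dict | None  # {'chi2', 'p'} when labels x niche is 2x2
    driver_table: pd.DataFrame | None = None


def cluster_samples(
    scores: ScoreMatrix, niches=("CT", "PAN"), k: int = 2
) -> ClusterResult:
    """Hierarchical (Ward/Euclidean) clustering of samples in the purified
    tumour niches, on per-signature z-scored rows, cut at ``k``.

    When both the labels and the niche annotation are binary, the
    cluster-vs-niche contingency is tested by Pearson chi-square.
    """
    if k < 2:
        raise TriaxisError("k must be >= 2")
    meta = scores.sample_meta
    if meta is None:
        raise TriaxisError("score matrix carries no sample metadata")
    keep = [s for s in scores.sample_ids if meta.loc[s, "niche"] in set(niches)]
    if len(keep) < 2 * k:
        raise TriaxisError(f"need >= {2 * k} samples after niche subsetting")
    X = scores.scores[keep].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = np.where(sd > 0, (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1), 0.0)
    model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="ward")
    raw = model.fit_predict(Z.T)
    # canonical relabeling by first occurrence: invariant to sample order quirks
    order = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order)
    labels = pd.Series([order[lab] for lab in raw], index=keep, name="cluster")

    chi2 = None
    niche_here = meta.loc[keep, "niche"]
    if k == 2 and niche_here.nunique() == 2:
        tab = pd.crosstab(labels, niche_here).to_numpy()
        if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            chi2 = chi2_association(tab)
    return ClusterResult(labels=labels, linkage="ward", chi2_vs_niche=chi2)


def driver_signatures(
    scores: ScoreMatrix, labels: pd.Series, q_thresh: float = 0.05
) -> pd.DataFrame:
    """Per-signature Welch t-test between the two clusters with
    Benjamini-Hochberg correction; the signatures driving the split.

    A stand-in statistic for cluster-driver discovery: effect is the
    cluster mean difference, ``enriched_in`` the higher-mean cluster.
    Constant rows (zero variance, zero difference) get p = 1.
    """
    ids = list(labels.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise TriaxisError("need exactly 2 clusters")
    a_ids = [s for s in ids if labels[s] == uniq[0]]
    b_ids = [s for s in ids if labels[s] == uniq[1]]
    if min(len(a_ids), len(b_ids)) < 3:
        raise TriaxisError("each cluster needs >= 3 samples")
    A = scores.scores[a_ids].to_numpy(dtype=float)
    B = scores.scores[b_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    effect = A.mean(axis=1) - B.mean(axis=1)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "signature": scores.signatures,
            "effect": effect,
            "p": p,
            "q": q,
            "enriched_in": np.where(effect >= 0, uniq[0], uniq[1]),
            "significant": q < q_thresh,
        }
    ).set_index("signature")


def axis_separation_roc(
    scores: ScoreMatrix, labels: pd.Series, signatures
) -> pd.DataFrame:
    """ROC/Youden separation of the cluster labels by each listed signature;
    AUC is reported orientation-corrected (max(AUC, 1-AUC)) with a flag."""
    rows = []
    for sig in signatures:
        if sig not in scores.signatures:
            raise TriaxisError(f"unknown signature {sig!r}")
        s = scores.row(sig).loc[labels.index].to_numpy(dtype=float)
        y = labels.to_numpy()
        res = roc_youden(s, y == sorted(set(y))[-1])
        flipped = res["auc"] < 0.5
        if flipped:  # re-orient so J and the cutoff describe the usable direction
            res = roc_youden(-s, y == sorted(set(y))[-1])
        rows.append(
            {
                "signature": sig,
                "auc": res["auc"],
                "J": res["J"],
                "cutoff": -res["cutoff"] if flipped else res["cutoff"],
                "flipped": flipped,
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def axis_anticorrelation(
    scores: ScoreMatrix, sig_a: str, sig_b: str, n_perm: int = 5000, seed: int = 0
) -> PermFitResult:
    """Permutation test of the linear relation between two signature rows
    (the KRAS-vs-MYC mutual-exclusion check)."""
    a = scores.row(sig_a).to_numpy(dtype=float)
    b = scores.row(sig_b).to_numpy(dtype=float)
    return permuted_linear_fit(a, b, n_perm=n_perm, seed=seed)
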