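"""Expression preprocessing for label-free proteomics and TPM tables:
replicate merging, group presence filtering, log2 + downshifted-Gaussian
imputation, geometric-mean centering, low-zero feature selection, sample
outlier flagging and the region-marker differential-expression matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import ExpressionMatrix, TISSUE_NICHES, TriaxisError


def _detected(m: ExpressionMatrix) -> pd.DataFrame:
    """Boolean frame of detection events: mask-aware for protein, value>0
    otherwise."""
    if m.missing_mask is not None:
        return ~m.missing_mask
    return m.values > 0


def merge_technical_replicates(m: ExpressionMatrix, pairs) -> ExpressionMatrix:
    """Average technical replicate pairs; when one of a pair is missing the
    non-missing value is taken; both missing stays missing.

    The merged column keeps the first sample id of the pair and its
    metadata.  Unpaired samples pass through unchanged.
    """
    known = set(m.sample_ids)
    for a, b in pairs:
        if a not in known or b not in known:
            raise TriaxisError(f"replicate pair ({a}, {b}) references unknown sample")
        if tuple(m.sample_meta.loc[a, ["patient_id", "niche"]]) != tuple(
            m.sample_meta.loc[b, ["patient_id", "niche"]]
        ):
            raise TriaxisError(f"pair ({a}, {b}) spans different patient/niche")
    det = _detected(m)
    paired = {s for p in pairs for s in p}
    cols, masks, keep_ids = {}, {}, []
    for sid in m.sample_ids:
        if sid in paired:
            continue
        cols[sid] = m.values[sid]
        masks[sid] = ~det[sid]
        keep_ids.append(sid)
    for a, b in pairs:
        va, vb = m.values[a], m.values[b]
        da, db = det[a], det[b]
        merged = pd.Series(0.0, index=m.feature_ids)
        both = da & db
        merged[both] = (va[both] + vb[both]) / 2
        only_a = da & ~db
        only_b = db & ~da
        merged[only_a] = va[only_a]
        merged[only_b] = vb[only_b]
        cols[a] = merged
        masks[a] = ~(da | db)
        keep_ids.append(a)
    values = pd.DataFrame({s: cols[s] for s in keep_ids})
    mask = pd.DataFrame({s: masks[s] for s in keep_ids}) if m.modality == "protein" else None
    return ExpressionMatrix(values, m.sample_meta.loc[keep_ids].copy(), m.modality, missing_mask=mask)


def presence_filter(m: ExpressionMatrix, frac: float = 0.6, rule: str = "any_group") -> ExpressionMatrix:
    """Keep features detected in at least ``frac`` of the samples of at
    least one niche group (or of every group with ``rule='all_groups'``)."""
    if not 0 < frac <= 1:
        raise TriaxisError("frac must be in (0, 1]")
    if m.n_features == 0 or m.n_samples == 0:
        raise TriaxisError("empty matrix")
    det = _detected(m)
    frac_by_group = det.T.groupby(m.niches()).mean().T  # features x groups
    if rule == "any_group":
        keep = (frac_by_group >= frac).any(axis=1)
    elif rule == "all_groups":
        keep = (frac_by_group >= frac).all(axis=1)
    else:
        raise TriaxisError(f"unknown presence rule {rule!r}")
    return m.subset_features(list(m.feature_ids[keep]))


def impute_missing(
    m: ExpressionMatrix, downshift: float = 0.3, width: float = 1.8, seed: int = 0
) -> ExpressionMatrix:
    """Log2 transform and impute missing values from a downshifted Gaussian.

    Per sample column with observed mean mu and SD sigma, each missing
    cell is drawn from Normal(mu - downshift*sigma, (width*sigma)^2) --
    the left-censored fill used for label-free intensities.  Non-positive
    values are treated as missing.  Deterministic under ``seed``.
    """
    if m.modality != "protein":
        raise TriaxisError("imputation applies to the protein modality")
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(dtype=float)
    missing = vals <= 0
    if m.missing_mask is not None:
        missing |= m.missing_mask.to_numpy()
    log2v = np.full_like(vals, np.nan)
    log2v[~missing] = np.log2(vals[~missing])
    out = log2v.copy()
    for j in range(vals.shape[1]):
        obs = log2v[~missing[:, j], j]
        if len(obs) < 3:
            raise TriaxisError(f"column {m.sample_ids[j]!r} has <3 observed values")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        k = int(missing[:, j].sum())
        if k:
            out[missing[:, j], j] = rng.normal(mu - downshift * sigma, width * sigma, size=k)
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return m.with_values(values, log_scale=True, missing_mask=None)


def center_geometric(m: ExpressionMatrix, target: float) -> ExpressionMatrix:
    """Scale each sample so the geometric mean of its positive entries
    equals ``target``; zeros are preserved."""
    if target <= 0:
        raise TriaxisError("target must be positive")
    vals = m.values.to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        pos = vals[:, j] > 0
        if not pos.any():
            raise TriaxisError(f"column {m.sample_ids[j]!r} is all zeros")
        gm = np.exp(np.mean(np.log(vals[pos, j])))
        vals[:, j] *= target / gm
    values = pd.DataFrame(vals, index=m.feature_ids, columns=m.sample_ids)
    mask = m.missing_mask.copy() if m.missing_mask is not None else None
    modality = "rna_tpm" if m.modality == "rna_counts" else m.modality
    return ExpressionMatrix(values, m.sample_meta.copy(), modality, missing_mask=mask)


def select_low_zero_features(m: ExpressionMatrix, n: int = 3000) -> ExpressionMatrix:
    """Keep the ``n`` features with fewest zero/missing entries; ties broken
    by total abundance descending, then feature id."""
    if n <= 0:
        raise TriaxisError("n must be positive")
    if n > m.n_features:
        raise TriaxisError(f"n={n} exceeds feature count {m.n_features}")
    det = _detected(m)
    zeros = (~det).sum(axis=1)
    total = m.values.sum(axis=1)
    order = pd.DataFrame({"zeros": zeros, "neg_total": -total}).sort_values(
        ["zeros", "neg_total"], kind="mergesort"
    )  # stable: index (feature id) breaks remaining ties
    return m.subset_features(list(order.index[:n]))


def flag_outlier_samples(features: pd.DataFrame) -> pd.DataFrame:
    """Flag samples from the (identified-by-MSMS vs total-identified) fit.

    Fits n_msms ~ n_total by OLS and flags Cook's distance > 4/n or
    leverage > 2*p/n (p = 2).  Removal is left to the caller.
    """
    required = {"sample", "n_msms", "n_total"}
    if not required <= set(features.columns):
        raise TriaxisError(f"need columns {sorted(required)}")
    n = len(features)
    if n < 5:
        raise TriaxisError("need >= 5 samples")
    x = features["n_total"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise TriaxisError("constant predictor")
    y = features["n_msms"].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    infl = fit.get_influence()
    leverage = infl.hat_matrix_diag
    if fit.ssr <= 1e-12 * max(np.sum((y - y.mean()) ** 2), 1.0):
        cooks = np.zeros(n)  # exact fit: residuals are float noise
    else:
        cooks = np.nan_to_num(infl.cooks_distance[0], nan=0.0)
    return pd.DataFrame(
        {
            "sample": features["sample"].to_numpy(),
            "cooks_d": cooks,
            "leverage": leverage,
            "flagged": (cooks > 4.0 / n) | (leverage > 2.0 * 2 / n),
        }
    ).set_index("sample")


def region_marker_matrix(m: ExpressionMatrix, alpha: float = 0.01) -> dict:
    """Niche marker table: a feature marks niche N when its mean exceeds
    every other niche's mean with a two-sided Welch t-test p < alpha in
    every comparison.

    Returns ``{"table": DataFrame, "counts": Series}`` where counts are
    the per-niche marker tallies (the heatmap diagonal).
    """
    niches = [n for n in TISSUE_NICHES if (m.niches() == n).any()]
    if set(niches) < set(TISSUE_NICHES):
        raise TriaxisError(f"need samples from all of {TISSUE_NICHES}")
    groups = {}
    for n in TISSUE_NICHES:
        ids = list(m.sample_ids[m.niches() == n])
        if len(ids) < 2:
            raise TriaxisError(f"niche {n} has <2 samples")
        groups[n] = m.values[ids].to_numpy(dtype=float)

    means = {n: g.mean(axis=1) for n, g in groups.items()}
    pvals = {}
    for i, a in enumerate(TISSUE_NICHES):
        for b in TISSUE_NICHES[i + 1 :]:
            p = stats.ttest_ind(groups[a], groups[b], axis=1, equal_var=False).pvalue
            pvals[(a, b)] = pvals[(b, a)] = p

    rows = []
    for n in TISSUE_NICHES:
        others = [o for o in TISSUE_NICHES if o != n]
        higher = np.all([means[n] > means[o] for o in others], axis=0)
        signif = np.all([pvals[(n, o)] < alpha for o in others], axis=0)
        is_marker = higher & signif
        margins = np.min([means[n] - means[o] for o in others], axis=0)
        for idx in np.where(is_marker)[0]:
            rows.append(
                {
                    "feature_id": m.feature_ids[idx],
                    "niche": n,
                    "min_margin": float(margins[idx]),
                    **{f"p_vs_{o}": float(pvals[(n, o)][idx]) for o in others},
                }
            )
    table = pd.DataFrame(rows)
    counts = pd.Series(
        {n: int((table["niche"] == n).sum()) if len(table) else 0 for n in TISSUE_NICHES},
        name="n_markers",
    )
    return {"table": table, "counts": counts}
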