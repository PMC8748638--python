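"""Per-cell axis scoring and three-group assignment.

Cells below the UMI quality bar are discarded, survivors are scored by
ssGSEA per cell, and each cell is assigned to KRAS_high, MYC_high or a
Central group by a z-score threshold-plus-margin rule.  Downstream
phenotype signatures are compared across the three groups with
Kruskal-Wallis and BH-corrected pairwise rank-sum tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection, ScoreMatrix, TriaxisError
from .enrichment import ssgsea_scores

GROUPS = ("KRAS_high", "MYC_high", "Central")


def filter_and_score_cells(
    sc: ExpressionMatrix,
    sets: GeneSetCollection,
    min_umi: int = 10_000,
    alpha: float = 0.25,
) -> tuple[ScoreMatrix, pd.DataFrame]:
    """Drop cells with fewer than ``min_umi`` total UMIs (strict less-than)
    and score the survivors for every set in ``sets``.

    Returns the per-cell score matrix plus an annotation stub with each
    retained cell's UMI total.
    """
    if sc.modality != "sc_counts":
        raise TriaxisError("expected sc_counts modality")
    umi = sc.values.sum(axis=0)
    keep = list(umi.index[umi >= min_umi])
    if not keep:
        raise TriaxisError(f"no cell reaches {min_umi} UMIs")
    filtered = sc.subset_samples(keep)
    scores = ssgsea_scores(filtered, sets, alpha=alpha)
    annot = pd.DataFrame({"umi_total": umi[keep].astype(int)})
    annot.index.name = "cell_id"
    return scores, annot


def assign_axis_groups(
    scores: ScoreMatrix,
    kras_signature: str = "KRAS_targets",
    myc_signature: str = "MYC_targets",
    z_thresh: float = 0.5,
    margin: float = 0.5,
) -> pd.DataFrame:
    """Three-group assignment from z-scored axis signatures.

    A cell is KRAS_high when its KRAS z exceeds ``z_thresh`` and beats
    the MYC z by ``margin``; MYC_high symmetrically; everything else is
    Central (no elevated enrichment in either program).
    """
    k = scores.row(kras_signature)
    m = scores.row(myc_signature)
    if len(k) < 10:
        raise TriaxisError("need >= 10 cells for stable z-scores")
    zk = (k - k.mean()) / k.std(ddof=0)
    zm = (m - m.mean()) / m.std(ddof=0)
    group = np.where(
        (zk > z_thresh) & (zk - zm > margin),
        "KRAS_high",
        np.where((zm > z_thresh) & (zm - zk > margin), "MYC_high", "Central"),
    )
    out = pd.DataFrame(
        {"kras_score": k, "myc_score": m, "kras_z": zk, "myc_z": zm, "group": group}
    )
    out.index.name = "cell_id"
    return out


def compare_group_phenotypes(
    scores: ScoreMatrix,
    annot: pd.DataFrame,
    signatures=None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Kruskal-Wallis across the three groups plus BH-corrected pairwise
    Mann-Whitney tests, per phenotype signature; group medians reported."""
    if signatures is None:
        signatures = list(scores.signatures)
    groups = {g: list(annot.index[annot["group"] == g]) for g in GROUPS}
    small = [g for g, ids in groups.items() if len(ids) < min_cells]
    if small:
        warnings.warn(f"groups below {min_cells} cells skipped: {small}")
        groups = {g: ids for g, ids in groups.items() if g not in small}
    if len(groups) < 2:
        raise TriaxisError("fewer than 2 groups with enough cells")

    rows = []
    for sig in signatures:
        s = scores.row(sig)
        samples = [s.loc[ids].to_numpy() for ids in groups.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(*samples).pvalue)
        pair_ps, pair_names = [], []
        names = list(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = samples[i], samples[j]
                if np.ptp(np.concatenate([a, b])) == 0:
                    pair_ps.append(1.0)
                else:
                    pair_ps.append(float(stats.mannwhitneyu(a, b).pvalue))
                pair_names.append(f"{names[i]}_vs_{names[j]}")
        qs = multipletests(pair_ps, method="fdr_bh")[1]
        rows.append(
            {
                "signature": sig,
                "kruskal_p": kw_p,
                **{f"median_{g}": float(np.median(s.loc[ids])) for g, ids in groups.items()},
                **{f"q_{n}": float(q) for n, q in zip(pair_names, qs)},
            }
        )
    return pd.DataFrame(rows).set_index("signature")
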