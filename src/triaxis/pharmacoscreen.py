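"""Axis-stratified drug-sensitivity screening and the hypoxia/normoxia
plate differential-viability computation.

Cell lines are ranked by model-inferred signature activation, split into
low/high quartile groups, and each drug's DSS1 difference is called
significant only under the four-part rule: both groups have at least 4
members, one-way ANOVA p < 0.05, |mean difference| > 0.1, and at least
one group mean below 0.1 (so a call always involves a sensitive-vs-
resistant contrast, not two intermediate responses).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, TriaxisError
from .signatures import SignatureModel

DEFAULT_CRITERIA = {"min_group": 4, "anova_p": 0.05, "delta": 0.1, "floor": 0.1}


def quartile_groups(activation: pd.Series, high_group: str = "top_quartile") -> dict:
    """Split lines into low/high activation groups by nearest-rank quartile.

    ``high_group='top_quartile'`` contrasts the two extreme quartiles;
    ``'top_75pct'`` contrasts the bottom quartile against everything
    above it.  Ties straddling a boundary are kept together (the group
    expands to include all tied lines).
    """
    activation = activation.dropna()
    n = len(activation)
    if n < 8:
        raise TriaxisError("need >= 8 lines with activation values")
    vals = activation.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise TriaxisError("activation is constant; no ordering")
    k = math.ceil(0.25 * n)  # nearest-rank 25th percentile
    sorted_vals = np.sort(vals)
    low_cut = sorted_vals[k - 1]
    low = list(activation.index[vals <= low_cut])
    if high_group == "top_quartile":
        high_cut = sorted_vals[n - k]
        high = list(activation.index[vals >= high_cut])
    elif high_group == "top_75pct":
        high = list(activation.index[vals > low_cut])
    else:
        raise TriaxisError(f"unknown high_group {high_group!r}")
    if set(low) & set(high):
        raise TriaxisError("ties span the whole range; groups overlap")
    return {"low": low, "high": high}


@dataclass
class DrugScreenResult:
    table: pd.DataFrame  # one row per drug
    criteria: dict

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def differential_sensitivity(
    dss1: pd.DataFrame, groups: dict, criteria: dict | None = None
) -> DrugScreenResult:
    """Apply the four-part significance rule per drug.

    ``dss1`` is the long table (cell_line, drug, dss1); for each drug
    only lines with available values are grouped.  Volcano coordinates
    are (delta, -log10 ANOVA p).  Drugs with fewer than 2 values in a
    group are marked untestable.
    """
    crit = {**DEFAULT_CRITERIA, **(criteria or {})}
    low, high = set(groups["low"]), set(groups["high"])
    rows = []
    for drug, sub in dss1.groupby("drug", sort=True):
        sub = sub.dropna(subset=["dss1"])
        v_low = sub.loc[sub["cell_line"].isin(low), "dss1"].to_numpy(dtype=float)
        v_high = sub.loc[sub["cell_line"].isin(high), "dss1"].to_numpy(dtype=float)
        row = {"drug": drug, "n_low": len(v_low), "n_high": len(v_high)}
        if len(v_low) < 2 or len(v_high) < 2:
            row.update(
                mean_low=np.nan, mean_high=np.nan, delta=np.nan, anova_p=np.nan,
                significant=False, testable=False, direction="untestable",
            )
            rows.append(row)
            continue
        mean_low, mean_high = float(v_low.mean()), float(v_high.mean())
        delta = mean_high - mean_low
        pooled = np.concatenate([v_low, v_high])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            p = float(stats.f_oneway(v_low, v_high).pvalue)
        significant = (
            len(v_low) >= crit["min_group"]
            and len(v_high) >= crit["min_group"]
            and p < crit["anova_p"]
            and abs(delta) > crit["delta"]
            and min(mean_low, mean_high) < crit["floor"]
        )
        row.update(
            mean_low=mean_low,
            mean_high=mean_high,
            delta=delta,
            anova_p=p,
            significant=bool(significant),
            testable=True,
            direction="sensitive_in_high" if delta > 0 else "resistant_in_high",
            neg_log10_p=-np.log10(p) if p > 0 else np.inf,
        )
        rows.append(row)
    return DrugScreenResult(pd.DataFrame(rows).set_index("drug"), crit)


def rank_lines_by_inferred_signature(
    expr: ExpressionMatrix, model: SignatureModel
) -> pd.Series:
    """Per-line activation predicted by the trained signature model (not
    raw ssGSEA); requires >= 50% gene overlap with training features."""
    return model.predict(expr, min_overlap=0.5)


def hypoxia_differential_viability(
    plate: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Plate-screen summary: each well normalized to the mean of its
    condition's reference wells; per compound, overall mean viability and
    the hypoxic-minus-normoxic differential, each condition averaged over
    its replicates.  Compounds missing a condition are skipped."""
    for df, name in ((plate, "plate"), (reference, "reference")):
        required = {"condition", "value"}
        if not required <= set(df.columns):
            raise TriaxisError(f"{name} table needs columns {sorted(required)}")
    ref_means = reference.groupby("condition")["value"].mean()
    if (ref_means <= 0).any():
        raise TriaxisError("reference wells must be positive")
    rows = []
    for compound, sub in plate.groupby("compound", sort=True):
        conds = set(sub["condition"])
        if not {"hypoxic", "normoxic"} <= conds:
            warnings.warn(f"compound {compound!r} missing a condition; skipped")
            continue
        norm = sub.assign(viability=sub["value"] / sub["condition"].map(ref_means).to_numpy())
        per_cond = norm.groupby("condition")["viability"].mean()
        rows.append(
            {
                "compound": compound,
                "mean_viability": float(per_cond.mean()),
                "differential": float(per_cond["hypoxic"] - per_cond["normoxic"]),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["mean_viability", "differential"]).rename_axis("compound")
    return pd.DataFrame(rows).set_index("compound")
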