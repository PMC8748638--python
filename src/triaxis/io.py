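"""Readers and writers for the plain-text formats the pipeline consumes.

GMT gene-set files (MSigDB dialect), expression TSVs with a sample-metadata
sidecar, survival tables, drug-sensitivity tables, and a YAML config that
mirrors every pipeline constant.  All tables are features-as-rows,
samples-as-columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    NICHES,
    TriaxisError,
)

# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file: name, description, genes...

    Duplicate genes within a line are dropped (first occurrence kept);
    duplicate set names are an error.  The description field carries the
    category when it is one of the known categories, else ``curated``.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TriaxisError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            category = desc if desc in ("curated", "hallmark", "oncogenic", "synthetic") else "curated"
            coll.add(GeneSet(name=name, category=category, genes=tuple(genes)))
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.category, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "patient_id", "niche", "modality"}
    missing = required - set(meta.columns)
    if missing:
        raise TriaxisError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["niche"]) - set(NICHES) - {"NA"}
    if bad:
        raise TriaxisError(f"unknown niches in metadata: {sorted(bad)}")
    return meta.set_index("sample_id")


def read_expression_table(path, meta_path, modality: str) -> ExpressionMatrix:
    """Read a feature x sample TSV plus its metadata sidecar.

    Protein-modality zeros are recorded in the missing mask: label-free
    zeros are below-detection events, not observed abundances.  RNA/count
    zeros are kept as true zeros.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = table.columns[[not pd.api.types.is_numeric_dtype(t) for t in table.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = table[col][pd.to_numeric(table[col], errors="coerce").isna()]
            if len(bad):
                raise TriaxisError(
                    f"{path}: non-numeric cell at feature {bad.index[0]!r}, sample {col!r}"
                )
        table = table.astype(float)
    meta = read_sample_meta(meta_path)
    unknown = [s for s in table.columns if s not in meta.index]
    if unknown:
        raise TriaxisError(f"samples absent from metadata: {unknown}")
    mask = None
    if modality == "protein":
        mask = table == 0
    return ExpressionMatrix(table, meta.loc[list(table.columns)], modality, missing_mask=mask)


def write_expression_table(m: ExpressionMatrix, path, meta_path=None) -> None:
    m.values.to_csv(path, sep="\t")
    if meta_path is not None:
        m.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Survival and drug tables


def read_survival(path) -> pd.DataFrame:
    surv = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    if not required <= set(surv.columns):
        raise TriaxisError(f"survival table must have columns {sorted(required)}")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise TriaxisError("event must be 0 (censored) or 1 (event)")
    if (surv["time"] <= 0).any():
        raise TriaxisError("survival times must be positive")
    return surv.set_index("sample_id")


def read_drug_table(path) -> pd.DataFrame:
    drugs = pd.read_csv(path)
    required = {"cell_line", "drug", "dss1"}
    if not required <= set(drugs.columns):
        raise TriaxisError(f"drug table must have columns {sorted(required)}")
    return drugs


# ---------------------------------------------------------------------------
# Config

#: Every pipeline constant in one place; runs resolve and log this mapping.
DEFAULT_CONFIG: dict = {
    "presence_fraction": 0.6,
    "presence_rule": "any_group",  # 'any_group' | 'all_groups'
    "impute_downshift": 0.3,
    "impute_width": 1.8,
    "perseus_convention": False,  # flips to (1.8, 0.3)
    "protein_geomean_target": 1e7,
    "tpm_geomean_target": 2.5,
    "low_zero_features": 3000,
    "marker_alpha": 0.01,
    "ssgsea_alpha": 0.25,
    "coherence_p": 0.01,
    "coherence_min": 0.4,
    "min_genes_both": 20,
    "signature_hyperparams": {"eta": 0.1, "subsample": 0.9, "max_depth": 1, "n_rounds": 200},
    "deconv_hyperparams": {"eta": 0.2, "subsample": 0.8, "max_depth": 1, "n_rounds": 300},
    "n_mixtures": 202,
    "mixture_total_counts": 10_000_000,
    "ct_range": [0.2, 0.8],
    "train_fraction": 0.8,
    "n_permutations": 5000,
    "min_umi": 10000,
    "sc_z_thresh": 0.5,
    "sc_margin": 0.5,
    "drug_min_group": 4,
    "drug_anova_p": 0.05,
    "drug_delta": 0.1,
    "drug_floor": 0.1,
    "drug_high_group": "top_quartile",  # 'top_quartile' | 'top_75pct'
    "chi2_correction": False,
}


def load_config(path=None) -> dict:
    """Resolve the run config: defaults overlaid with a YAML/JSON file."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise TriaxisError(f"unknown config keys: {sorted(unknown)}")
        for k, v in user.items():
            if isinstance(cfg.get(k), dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if cfg["perseus_convention"]:
        cfg["impute_downshift"], cfg["impute_width"] = 1.8, 0.3
    return cfg


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
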