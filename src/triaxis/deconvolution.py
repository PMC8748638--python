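"""CT-niche-specific signature inference via synthetic count mixtures.

Bulk glioblastoma expression mixes the cellular tumour with other niches
and immune infiltrate, so a whole-sample ssGSEA score misreads the CT
compartment.  The engine trains, per signature, a two-level stack on
synthetic mixtures of known composition: 11 level-1 boosted-stump
regressors predict the whole-mixture score, the five compartment
proportions and the five source-sample scores; a level-2 regressor maps
those 11 predictions to the CT-specific activation, defined as the CT
source score divided by the CT content.

Mixtures are drawn by a hierarchical multinomial (compartment totals,
then per-compartment gene counts from the source sample's frequencies),
which is distributionally identical to resampling a concatenated
"expanded count" label vector without materializing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .containers import ExpressionMatrix, GeneSetCollection, TriaxisError
from .enrichment import SurvivalSplit, km_logrank, ssgsea_scores
from .preprocess import center_geometric

COMPARTMENTS = ("CT", "PAN", "LE", "MVP", "LEUKO")

DEFAULT_HYPERPARAMS = {"eta": 0.2, "subsample": 0.8, "max_depth": 1, "n_rounds": 300}

#: The level-2 target is a ratio (CT source score / CT content), which an
#: additive depth-1 ensemble cannot represent; the level-2 model therefore
#: uses modestly deeper trees to capture the interaction.
LEVEL2_HYPERPARAMS = {"eta": 0.2, "subsample": 0.8, "max_depth": 3, "n_rounds": 300}


@dataclass
class MixtureSpec:
    source_samples: dict  # compartment -> source sample id
    proportions: dict  # compartment -> fraction of the mixture
    total_counts: int
    seed: int

    def __post_init__(self) -> None:
        props = np.array([self.proportions[c] for c in COMPARTMENTS])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
            raise TriaxisError("proportions must be >= 0 and sum to 1")
        if not 0.2 <= self.proportions["CT"] <= 0.8:
            raise TriaxisError("CT content must lie in [0.2, 0.8]")


def mix_counts(compendium: ExpressionMatrix, spec: MixtureSpec) -> np.ndarray:
    """Draw one synthetic mixture: compartment totals ~ multinomial over the
    proportions, then gene counts ~ multinomial from each source sample's
    gene frequencies.  The output integer vector sums to total_counts."""
    if compendium.modality != "rna_counts":
        raise TriaxisError("compendium must be rna_counts")
    rng = np.random.default_rng(spec.seed)
    props = np.array([spec.proportions[c] for c in COMPARTMENTS])
    totals = rng.multinomial(spec.total_counts, props)
    out = np.zeros(compendium.n_features, dtype=np.int64)
    for c, n_c in zip(COMPARTMENTS, totals):
        if n_c == 0:
            continue
        sid = spec.source_samples[c]
        if sid not in compendium.sample_ids:
            raise TriaxisError(f"source sample {sid!r} not in compendium")
        counts = compendium.values[sid].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise TriaxisError(f"source sample {sid!r} has zero total counts")
        out += rng.multinomial(int(n_c), counts / total)
    return out


@dataclass
class MixtureTrainingSet:
    signature: str
    mixtures: ExpressionMatrix  # rna_counts, genes x mixtures
    specs: list
    level1_targets: pd.DataFrame  # whole score, 5 proportions, 5 source scores
    level2_target: pd.Series  # CT source score / CT proportion
    train_ids: list
    test_ids: list
    geomean_target: float = 2.5


def build_mixture_training_set(
    compendium: ExpressionMatrix,
    sets: GeneSetCollection,
    signature: str,
    n_mixtures: int = 202,
    total_counts: int = 10_000_000,
    ct_range: tuple = (0.2, 0.8),
    train_fraction: float = 0.8,
    seed: int = 0,
    ssgsea_alpha: float = 0.25,
    geomean_target: float = 2.5,
) -> MixtureTrainingSet:
    """Generate the mixture cohort and its level-1/level-2 targets.

    Per mixture: one source sample per compartment drawn uniformly, CT
    content uniform over ``ct_range``, the remaining mass split over
    PAN/LE/MVP/LEUKO by a flat Dirichlet.  Source-sample scores are
    unnormalized ssGSEA so that training and inference share one scale.
    The mixture ids are split train/test with the test size floored at
    (1 - train_fraction) of the cohort.
    """
    if not (0 < ct_range[0] < ct_range[1] < 1):
        raise TriaxisError("ct_range must lie inside (0, 1)")
    if signature not in sets:
        raise TriaxisError(f"signature {signature!r} not in gene sets")
    by_niche = {
        c: list(compendium.sample_ids[compendium.niches() == c]) for c in COMPARTMENTS
    }
    for c, ids in by_niche.items():
        if not ids:
            raise TriaxisError(f"compendium has no {c} samples")

    one_set = sets.subset([signature])
    source_scores = ssgsea_scores(
        compendium, one_set, alpha=ssgsea_alpha, normalize=False
    ).row(signature)

    rng = np.random.default_rng(seed)
    specs, cols = [], {}
    rows_l1 = []
    for i in range(n_mixtures):
        sources = {c: by_niche[c][rng.integers(len(by_niche[c]))] for c in COMPARTMENTS}
        ct = float(rng.uniform(*ct_range))
        rest = rng.dirichlet(np.ones(4)) * (1.0 - ct)
        props = {"CT": ct, **{c: float(r) for c, r in zip(("PAN", "LE", "MVP", "LEUKO"), rest)}}
        spec = MixtureSpec(
            source_samples=sources,
            proportions=props,
            total_counts=total_counts,
            seed=int(rng.integers(2**31 - 1)),
        )
        specs.append(spec)
        cols[f"MIX{i:04d}"] = mix_counts(compendium, spec)
        rows_l1.append(
            {
                **{f"prop_{c}": props[c] for c in COMPARTMENTS},
                **{f"score_{c}": float(source_scores[sources[c]]) for c in COMPARTMENTS},
            }
        )

    mix_ids = list(cols)
    values = pd.DataFrame(cols, index=compendium.feature_ids)
    meta = pd.DataFrame(
        {"patient_id": "mixture", "niche": "WHOLE", "modality": "rna_counts"},
        index=pd.Index(mix_ids, name="sample_id"),
    )
    mixtures = ExpressionMatrix(values, meta, "rna_counts")

    centered = center_geometric(mixtures, geomean_target)
    whole = ssgsea_scores(centered, one_set, alpha=ssgsea_alpha, normalize=False).row(signature)
    level1 = pd.DataFrame(rows_l1, index=mix_ids)
    level1.insert(0, "whole_score", whole.to_numpy())
    level2 = level1["score_CT"] / level1["prop_CT"]
    level2.name = "ct_specific"

    n_test = int(np.floor((1.0 - train_fraction) * n_mixtures))
    perm = rng.permutation(n_mixtures)
    test_ids = [mix_ids[j] for j in sorted(perm[:n_test])]
    train_ids = [m for m in mix_ids if m not in set(test_ids)]
    return MixtureTrainingSet(
        signature=signature,
        mixtures=mixtures,
        specs=specs,
        level1_targets=level1,
        level2_target=level2,
        train_ids=train_ids,
        test_ids=test_ids,
        geomean_target=geomean_target,
    )


@dataclass
class DeconvolutionStack:
    signature: str
    level1: dict  # target name -> fitted XGBRegressor (11 models)
    level2: xgb.XGBRegressor
    training_features: list
    feature_medians: pd.Series
    hyperparams: dict
    geomean_target: float
    provenance: dict
    metrics: dict = field(default_factory=dict)  # test-split R2 / Pearson r

    def _align(self, m: ExpressionMatrix) -> np.ndarray:
        X = m.values.reindex(self.training_features).T.fillna(self.feature_medians)
        return X.to_numpy(dtype=float)

    def predict_level1(self, m: ExpressionMatrix) -> pd.DataFrame:
        X = self._align(m)
        return pd.DataFrame(
            {name: reg.predict(X) for name, reg in self.level1.items()},
            index=m.sample_ids,
        )

    def predict(self, m: ExpressionMatrix) -> pd.Series:
        l1 = self.predict_level1(m)
        return pd.Series(
            self.level2.predict(l1.to_numpy(dtype=float)), index=m.sample_ids,
            name=f"{self.signature}_ct_specific",
        )

    def predict_ct_activation(self, m: ExpressionMatrix) -> pd.Series:
        """Content-corrected CT activation: the per-unit-content score times
        the predicted CT proportion, i.e. an estimate of the CT source
        sample's own score.  Because the content scaling cancels, this
        readout is comparable across bulks of different tumour purity."""
        l1 = self.predict_level1(m)
        l2 = self.level2.predict(l1.to_numpy(dtype=float))
        return pd.Series(
            l2 * l1["prop_CT"].to_numpy(), index=m.sample_ids,
            name=f"{self.signature}_ct_activation",
        )


def _make_regressor(hp: dict, seed: int) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        n_estimators=hp["n_rounds"],
        learning_rate=hp["eta"],
        subsample=hp["subsample"],
        max_depth=hp["max_depth"],
        objective="reg:squarederror",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )


def train_stack(
    tset: MixtureTrainingSet, hp: dict | None = None, seed: int = 0
) -> DeconvolutionStack:
    """Fit the 11 level-1 regressors on centered mixture expression, then
    the level-2 regressor on the level-1 *predictions* (stacked
    generalization, matching deployment), reporting test-split metrics."""
    hp = {**DEFAULT_HYPERPARAMS, **(hp or {})}
    if len(tset.train_ids) < 50:
        raise TriaxisError("need >= 50 training mixtures")
    centered = center_geometric(tset.mixtures, tset.geomean_target)
    medians = centered.values.median(axis=1)
    X_all = centered.values.T.to_numpy(dtype=float)
    ids = list(tset.mixtures.sample_ids)
    tr = [ids.index(i) for i in tset.train_ids]
    te = [ids.index(i) for i in tset.test_ids]

    level1, metrics = {}, {}
    preds_train = {}
    preds_test = {}
    for col in tset.level1_targets.columns:
        y = tset.level1_targets[col].to_numpy(dtype=float)
        if np.ptp(y[tr]) == 0:
            raise TriaxisError(f"level-1 target {col!r} has zero variance")
        reg = _make_regressor(hp, seed)
        reg.fit(X_all[tr], y[tr])
        level1[col] = reg
        preds_train[col] = reg.predict(X_all[tr])
        preds_test[col] = reg.predict(X_all[te])
        if te:
            ss_res = float(np.sum((y[te] - preds_test[col]) ** 2))
            ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
            metrics[f"r2_{col}"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    y2 = tset.level2_target.to_numpy(dtype=float)
    if np.ptp(y2[tr]) == 0:
        raise TriaxisError("level-2 target has zero variance")
    L1_train = np.column_stack([preds_train[c] for c in tset.level1_targets.columns])
    level2 = _make_regressor({**LEVEL2_HYPERPARAMS, "eta": hp["eta"], "subsample": hp["subsample"]}, seed + 1)
    level2.fit(L1_train, y2[tr])
    if te:
        L1_test = np.column_stack([preds_test[c] for c in tset.level1_targets.columns])
        pred2 = level2.predict(L1_test)
        metrics["pearson_r_ct_specific"] = float(np.corrcoef(pred2, y2[te])[0, 1])

    return DeconvolutionStack(
        signature=tset.signature,
        level1=level1,
        level2=level2,
        training_features=list(centered.feature_ids),
        feature_medians=medians,
        hyperparams=hp,
        geomean_target=tset.geomean_target,
        provenance={
            "n_mixtures": len(ids),
            "total_counts": tset.specs[0].total_counts if tset.specs else None,
            "n_train": len(tr),
            "n_test": len(te),
        },
        metrics=metrics,
    )


def infer_ct_specific(bulk: ExpressionMatrix, stack: DeconvolutionStack) -> pd.Series:
    """CT-niche-specific activation for each bulk sample: geometric-mean
    centering, feature alignment with median fill, level-1 predictions fed
    into the level-2 model."""
    if bulk.modality not in ("rna_counts", "rna_tpm"):
        raise TriaxisError("bulk matrix must be an RNA modality")
    overlap = sum(g in bulk.feature_ids for g in stack.training_features) / len(
        stack.training_features
    )
    if overlap < 0.5:
        raise TriaxisError(
            f"gene overlap with training features is {overlap:.2f} (< 0.50)"
        )
    centered = center_geometric(bulk, stack.geomean_target)
    return stack.predict(centered)


def leuko_interference_experiment(
    compendium: ExpressionMatrix,
    sets: GeneSetCollection,
    stack: DeconvolutionStack,
    ct_content: float = 0.5,
    leuko_fracs: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    total_counts: int = 100_000,
    n_ct_samples: int = 5,
    seed: int = 0,
    ssgsea_alpha: float = 0.25,
) -> pd.DataFrame:
    """Quantify immune-infiltrate interference at fixed tumour content.

    For each of ``n_ct_samples`` CT sources, bulks are composed with the
    CT content held at ``ct_content`` while the contaminating complement
    shifts from an even PAN/LE/MVP blend to leukocytes.  The CT
    compartment is identical across the series, so any drift in a
    CT-specific readout is error, while the naive whole-sample ssGSEA
    drifts with the infiltrate.  Returns per-source mean relative drifts
    (vs the leukocyte-free bulk) for the naive score, the raw per-unit-
    content inference, and the content-corrected CT activation; the
    drift ratio compares the content-corrected readout to naive.
    """
    rng = np.random.default_rng(seed)
    ct_ids = list(compendium.sample_ids[compendium.niches() == "CT"])[:n_ct_samples]
    other = {c: list(compendium.sample_ids[compendium.niches() == c]) for c in ("PAN", "LE", "MVP", "LEUKO")}
    sig_set = sets.subset([stack.signature])
    freqs = compendium.values / compendium.values.sum(axis=0)
    rows = []
    for ct_id in ct_ids:
        contaminants = {c: other[c][rng.integers(len(other[c]))] for c in other}
        cols = {}
        for i, f in enumerate(leuko_fracs):
            rest = 1.0 - ct_content
            blend = ct_content * freqs[ct_id].to_numpy()
            for c in ("PAN", "LE", "MVP"):
                blend = blend + (rest - f) / 3.0 * freqs[contaminants[c]].to_numpy()
            blend = blend + f * freqs[contaminants["LEUKO"]].to_numpy()
            cols[f"b{i}"] = rng.multinomial(total_counts, blend / blend.sum())
        vals = pd.DataFrame(cols, index=compendium.feature_ids)
        meta = pd.DataFrame(
            {"patient_id": "bulk", "niche": "WHOLE", "modality": "rna_counts"},
            index=pd.Index(vals.columns, name="sample_id"),
        )
        bulk = ExpressionMatrix(vals, meta, "rna_counts")
        naive = ssgsea_scores(bulk, sig_set, alpha=ssgsea_alpha, normalize=False).row(
            stack.signature
        ).to_numpy()
        centered = center_geometric(bulk, stack.geomean_target)
        inferred = stack.predict(centered).to_numpy()
        corrected = stack.predict_ct_activation(centered).to_numpy()

        def _drift(x):
            return float(np.mean(np.abs(x[1:] - x[0])) / abs(x[0]))

        rows.append(
            {
                "ct_sample": ct_id,
                "drift_naive": _drift(naive),
                "drift_inferred": _drift(inferred),
                "drift_ct_activation": _drift(corrected),
                "drift_ratio": _drift(corrected) / _drift(naive),
            }
        )
    return pd.DataFrame(rows).set_index("ct_sample")


class _BoosterPredictor:
    """Minimal predict-only wrapper around a loaded raw booster."""

    def __init__(self, booster: xgb.Booster):
        self.booster = booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


def _dump_model(model, path) -> None:
    booster = model.get_booster() if hasattr(model, "get_booster") else model.booster
    booster.save_model(path)


def _load_model(path) -> _BoosterPredictor:
    booster = xgb.Booster()
    booster.load_model(path)
    return _BoosterPredictor(booster)


def save_stack(stack: DeconvolutionStack, outdir) -> None:
    """Persist the stack as portable boosted-tree JSON dumps plus a
    metadata sidecar (features, medians, hyperparameters, provenance)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, reg in stack.level1.items():
        _dump_model(reg, outdir / f"level1_{name}.json")
    _dump_model(stack.level2, outdir / "level2.json")
    meta = {
        "signature": stack.signature,
        "training_features": stack.training_features,
        "feature_medians": stack.feature_medians.to_dict(),
        "hyperparams": stack.hyperparams,
        "geomean_target": stack.geomean_target,
        "provenance": stack.provenance,
        "metrics": stack.metrics,
        "level1_order": list(stack.level1),
    }
    with open(outdir / "stack.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_stack(outdir) -> DeconvolutionStack:
    import json
    from pathlib import Path

    outdir = Path(outdir)
    with open(outdir / "stack.json") as fh:
        meta = json.load(fh)
    level1 = {name: _load_model(outdir / f"level1_{name}.json") for name in meta["level1_order"]}
    level2 = _load_model(outdir / "level2.json")
    medians = pd.Series(meta["feature_medians"]).reindex(meta["training_features"])
    return DeconvolutionStack(
        signature=meta["signature"],
        level1=level1,
        level2=level2,
        training_features=meta["training_features"],
        feature_medians=medians,
        hyperparams=meta["hyperparams"],
        geomean_target=meta["geomean_target"],
        provenance=meta["provenance"],
        metrics=meta["metrics"],
    )


def stratify_survival(scores: pd.Series, survival: pd.DataFrame) -> SurvivalSplit:
    """Mean split ('high' = score >= mean, 'low' below) followed by the
    two-group log-rank comparison."""
    scores = scores.loc[survival.index]
    if np.ptp(scores.to_numpy()) == 0:
        raise TriaxisError("all scores equal; cannot bin")
    labels = pd.Series(
        np.where(scores >= scores.mean(), "high", "low"), index=scores.index, name="group"
    )
    if min((labels == "high").sum(), (labels == "low").sum()) < 2:
        raise TriaxisError("need >= 2 samples per survival arm")
    return km_logrank(survival, labels)
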