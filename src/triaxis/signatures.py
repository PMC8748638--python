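"""Signature screening: coherence ratios, per-signature boosted-stump
regression models that infer ssGSEA activations from expression, and the
cross-modality (protein vs RNA) concordance selection pipeline.

Boosted trees come from xgboost; the screen itself (coherence gate,
paired-modality modelling, robust concordance fit) is authored here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection, TriaxisError
from .enrichment import robust_linear_fit_iqr, ssgsea_scores

#: Hyperparameters for the signature-inference models.
DEFAULT_HYPERPARAMS = {"eta": 0.1, "subsample": 0.9, "max_depth": 1, "n_rounds": 200}


def coherence_ratio(
    m: ExpressionMatrix, score: pd.Series, genes, p_thresh: float = 0.01
) -> float:
    """Fraction of a set's genes whose expression fits linearly against the
    set's own per-sample score with slope p < ``p_thresh``.

    The slope test is the usual t-test on the regression coefficient
    (equivalently on the Pearson correlation), vectorized over genes.
    """
    score = score.loc[m.sample_ids].to_numpy(dtype=float)
    n = len(score)
    if n < 6:
        raise TriaxisError("need >= 6 samples")
    if np.ptp(score) == 0:
        raise TriaxisError("constant score vector")
    present = [g for g in genes if g in m.feature_ids]
    if not present:
        raise TriaxisError("no set gene present in the matrix")
    X = m.values.loc[present].to_numpy(dtype=float)  # genes x samples
    xc = score - score.mean()
    Yc = X - X.mean(axis=1, keepdims=True)
    sxx = float(xc @ xc)
    sxy = Yc @ xc
    syy = (Yc**2).sum(axis=1)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, sxy / denom, 0.0)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return float(np.mean(p < p_thresh))


@dataclass
class SignatureModel:
    """A boosted ensemble of depth-1 regression trees inferring one
    signature's activation from expression."""

    signature: str
    modality: str
    model: xgb.XGBRegressor
    hyperparams: dict
    training_features: list
    feature_medians: pd.Series  # training median per gene, used as fill
    seed: int

    def predict(self, m: ExpressionMatrix, min_overlap: float = 0.0) -> pd.Series:
        """Predict activations, aligning features to the training order and
        filling genes absent from ``m`` with their training medians."""
        overlap = sum(g in m.feature_ids for g in self.training_features) / len(
            self.training_features
        )
        if overlap < min_overlap:
            raise TriaxisError(
                f"gene overlap {overlap:.2f} below required {min_overlap:.2f} "
                f"({len(self.training_features)} training features)"
            )
        X = m.values.reindex(self.training_features).T.fillna(self.feature_medians)
        pred = self.model.predict(X.to_numpy(dtype=float))
        return pd.Series(pred, index=m.sample_ids, name=self.signature)


def train_signature_model(
    m: ExpressionMatrix,
    scores: pd.Series,
    hp: dict | None = None,
    seed: int = 0,
    signature: str = "signature",
) -> SignatureModel:
    """Fit the gradient-boosted stump regressor expression -> score."""
    hp = {**DEFAULT_HYPERPARAMS, **(hp or {})}
    if hp["max_depth"] != 1:
        raise TriaxisError("signature models use depth-1 trees")
    if m.n_samples < 20:
        raise TriaxisError("need >= 20 samples to train")
    y = scores.loc[m.sample_ids].to_numpy(dtype=float)
    X = m.values.to_numpy(dtype=float).T
    if np.isnan(X).any() or np.isnan(y).any():
        raise TriaxisError("NaN in training inputs")
    reg = xgb.XGBRegressor(
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
    reg.fit(X, y)
    return SignatureModel(
        signature=signature,
        modality=m.modality,
        model=reg,
        hyperparams=hp,
        training_features=list(m.feature_ids),
        feature_medians=m.values.median(axis=1),
        seed=seed,
    )


def concordance_test(
    model_prot: SignatureModel,
    model_rna: SignatureModel,
    protein: ExpressionMatrix,
    rna: ExpressionMatrix,
    p_thresh: float = 0.01,
) -> dict:
    """Cross-modality concordance on an external paired cohort: predict the
    signature from each modality independently and require the robust
    (IQR-pruned, HC2) linear fit between the two predictions to reach
    p < ``p_thresh``."""
    if list(protein.sample_ids) != list(rna.sample_ids):
        raise TriaxisError("paired matrices must share the same samples in order")
    if protein.n_samples < 10:
        raise TriaxisError("need >= 10 matched samples")
    pred_p = model_prot.predict(protein)
    pred_r = model_rna.predict(rna)
    fit = robust_linear_fit_iqr(pred_p.to_numpy(), pred_r.to_numpy())
    return {"pass": bool(fit.p_value < p_thresh), "p": fit.p_value, "fit": fit}


@dataclass
class SelectionResult:
    selected: list
    coherence: pd.DataFrame  # (signature, modality) -> coherence, n_genes, pass
    models: dict  # signature -> {"protein": SignatureModel, "rna": SignatureModel}
    concordance: pd.DataFrame
    audit: dict = field(default_factory=dict)  # per-stage survivor counts


def select_concordant_signatures(
    protein: ExpressionMatrix,
    rna: ExpressionMatrix,
    external_protein: ExpressionMatrix,
    external_rna: ExpressionMatrix,
    sets: GeneSetCollection,
    min_genes: int = 20,
    coherence_min: float = 0.4,
    coherence_p: float = 0.01,
    concordance_p: float = 0.01,
    ssgsea_alpha: float = 0.25,
    hp: dict | None = None,
    seed: int = 0,
) -> SelectionResult:
    """The full screen: size gate, ssGSEA in both modalities, coherence gate
    in both, per-signature model training, external concordance gate.

    Emits an audit trail of survivor counts at each stage; any stage that
    empties the candidate list raises an error naming the stage.
    """
    audit = {"input": len(sets)}

    # stage i: >= min_genes genes present in both matrices
    stage1 = []
    for s in sets:
        n_both = sum(g in protein.feature_ids and g in rna.feature_ids for g in s.genes)
        if n_both >= min_genes:
            stage1.append(s.name)
    audit["min_genes"] = len(stage1)
    if not stage1:
        raise TriaxisError("no set passes the min-genes stage")

    # stage ii: ssGSEA in both modalities
    sub = sets.subset(stage1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores_p = ssgsea_scores(protein, sub, alpha=ssgsea_alpha)
        scores_r = ssgsea_scores(rna, sub, alpha=ssgsea_alpha)

    # stage iii: coherence > threshold in both
    coh_rows, stage3 = [], []
    for name in stage1:
        genes = sub[name].genes
        cp = coherence_ratio(protein, scores_p.row(name), genes, coherence_p)
        cr = coherence_ratio(rna, scores_r.row(name), genes, coherence_p)
        ok = cp > coherence_min and cr > coherence_min
        coh_rows.append(
            {"signature": name, "coherence_protein": cp, "coherence_rna": cr, "pass": ok}
        )
        if ok:
            stage3.append(name)
    coherence = pd.DataFrame(coh_rows).set_index("signature")
    audit["coherence"] = len(stage3)
    if not stage3:
        raise TriaxisError("no set passes the coherence stage")

    # stage iv: per-signature models in each modality
    models = {}
    for name in stage3:
        models[name] = {
            "protein": train_signature_model(
                protein, scores_p.row(name), hp=hp, seed=seed, signature=name
            ),
            "rna": train_signature_model(
                rna, scores_r.row(name), hp=hp, seed=seed, signature=name
            ),
        }
    audit["models"] = len(models)

    # stage v: external paired concordance
    conc_rows, selected = [], []
    for name in stage3:
        res = concordance_test(
            models[name]["protein"],
            models[name]["rna"],
            external_protein,
            external_rna,
            p_thresh=concordance_p,
        )
        conc_rows.append({"signature": name, "p": res["p"], "pass": res["pass"]})
        if res["pass"]:
            selected.append(name)
    concordance = pd.DataFrame(conc_rows).set_index("signature")
    audit["concordant"] = len(selected)
    if not selected:
        raise TriaxisError("no set passes the concordance stage")

    return SelectionResult(
        selected=selected,
        coherence=coherence,
        models=models,
        concordance=concordance,
        audit=audit,
    )
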