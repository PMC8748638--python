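"""Synthetic cohorts with the regional structure the analysis assumes.

The generators emulate a laser-capture glioblastoma study: per-patient
niche samples (LE/IT/CT/PAN/MVP plus a WHOLE bulk mixture), a counts
compendium with a leukocyte compartment, single-cell populations, and a
cell-line pharmacology fixture.  Planted transcriptional programs give
each niche its identity; the cellular-tumour niche carries two mutually
exclusive programs (MYC-like proliferative vs KRAS-like migratory) tied
to a latent axis u in [-1, 1] with myc = (1+u)/2 and kras = (1-u)/2, so
anti-correlation holds by construction.  Every generator is a pure
function of its parameters and seed, and returns enough ground truth to
score downstream recovery without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection, TriaxisError

#: Planted programs and the niche each one marks.
PROGRAMS = {
    "LE_neuronal": "LE",
    "PAN_hypoxia": "PAN",
    "MVP_angio": "MVP",
    "CT_MYC": "CT",
    "CT_KRAS": "CT",
    "LEUKO_immune": "LEUKO",
}

#: Signature names used downstream for each planted program.
PROGRAM_SIGNATURES = {
    "CT_KRAS": "KRAS_targets",
    "CT_MYC": "MYC_targets",
    "PAN_hypoxia": "HYPOXIA",
    "LE_neuronal": "NEURONAL",
    "MVP_angio": "ANGIOGENESIS",
    "LEUKO_immune": "IMMUNE_LEUKO",
}

GENES_PER_PROGRAM = 40


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    gene_ids: list
    program_genes: dict  # program -> tuple of gene ids (pairwise disjoint)
    base_log2: pd.Series  # per-gene baseline log2 abundance (tissue)
    leuko_base_log2: pd.Series | None = None  # leukocyte baseline
    sample_truth: pd.DataFrame | None = None  # niche, myc/kras/hypoxia levels
    mixture_truth: pd.DataFrame | None = None  # per-mixture compartment proportions
    cell_truth: pd.DataFrame | None = None  # per-cell planted group
    drug_truth: pd.DataFrame | None = None  # per-drug axis + direction
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "program_genes": {k: list(v) for k, v in self.program_genes.items()},
            "params": self.params,
        }
        for name in ("sample_truth", "mixture_truth", "cell_truth", "drug_truth"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.reset_index().to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _make_truth(genes: int, seed: int) -> GroundTruth:
    total_program = GENES_PER_PROGRAM * len(PROGRAMS)
    if genes < total_program:
        raise TriaxisError(f"need >= {total_program} genes for the planted programs")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(genes)]
    picks = rng.choice(genes, size=total_program, replace=False)
    program_genes = {}
    for k, prog in enumerate(PROGRAMS):
        idx = picks[k * GENES_PER_PROGRAM : (k + 1) * GENES_PER_PROGRAM]
        program_genes[prog] = tuple(gene_ids[i] for i in sorted(idx))
    base = pd.Series(rng.normal(7.0, 2.0, size=genes), index=gene_ids)
    # planted markers sit in the well-quantified abundance range: regional
    # marker proteins are, by selection, reliably detected across niches
    for prog_genes in program_genes.values():
        base[list(prog_genes)] = rng.normal(9.0, 1.0, size=len(prog_genes))
    # leukocytes carry a globally distinct baseline (blood vs brain tissue),
    # not just the immune program; proliferating immune cells also express
    # the RAS/MAPK- and MYC-target programs strongly, which is what makes
    # infiltrate interfere with whole-sample axis scores
    leuko = pd.Series(rng.normal(7.0, 2.0, size=genes), index=gene_ids)
    leuko[list(program_genes["LEUKO_immune"])] = rng.normal(9.0, 1.0, size=GENES_PER_PROGRAM)
    leuko[list(program_genes["CT_KRAS"])] = rng.normal(10.0, 0.5, size=GENES_PER_PROGRAM)
    leuko[list(program_genes["CT_MYC"])] = rng.normal(10.0, 0.5, size=GENES_PER_PROGRAM)
    return GroundTruth(
        gene_ids=gene_ids, program_genes=program_genes, base_log2=base, leuko_base_log2=leuko
    )


def _expected_log2(
    truth: GroundTruth,
    niche: str,
    myc: float,
    kras: float,
    hypoxia: float,
    effect: float,
    immune: float = 0.0,
) -> pd.Series:
    pg = truth.program_genes
    if niche == "LEUKO":
        mean = (
            truth.leuko_base_log2.copy()
            if truth.leuko_base_log2 is not None
            else truth.base_log2.copy()
        )
        mean[list(pg["LEUKO_immune"])] += 1.5 * effect
        return mean
    mean = truth.base_log2.copy()
    if immune > 0:
        mean[list(pg["LEUKO_immune"])] += effect * immune
    if niche == "LE":
        mean[list(pg["LE_neuronal"])] += effect
    elif niche == "MVP":
        mean[list(pg["MVP_angio"])] += effect
    elif niche == "PAN":
        mean[list(pg["PAN_hypoxia"])] += effect * hypoxia
    elif niche == "CT":
        # both CT programs are elevated in CT overall; the latent axis
        # modulates how strongly each sample expresses each of the two
        mean[list(pg["CT_MYC"])] += effect * (0.35 + 0.65 * myc)
        mean[list(pg["CT_KRAS"])] += effect * (0.35 + 0.65 * kras)
    # IT carries no planted program
    return mean


def _draw_levels(niche: str, rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Latent (myc, kras, hypoxia, immune) for one sample of a niche.

    Leukocyte infiltrate is graded across tissue niches (highest around
    microvascular proliferation), mirroring the varying inflammatory
    content that motivates the LEUKO surrogate compartment.
    """
    if niche == "CT":
        u = rng.uniform(-0.9, 0.9)
        myc = float(np.clip((1 + u) / 2 + rng.normal(0, 0.05), 0, 1))
        kras = float(np.clip((1 - u) / 2 + rng.normal(0, 0.05), 0, 1))
        hyp = float(rng.uniform(0.0, 0.2))
    elif niche == "PAN":
        myc, kras = (float(abs(rng.normal(0, 0.05))) for _ in range(2))
        hyp = float(rng.uniform(0.7, 1.0))
    else:
        myc, kras = (float(abs(rng.normal(0, 0.05))) for _ in range(2))
        hyp = float(rng.uniform(0.0, 0.2))
    immune = float(rng.uniform(0.4, 0.9)) if niche == "MVP" else float(rng.uniform(0.0, 0.4))
    return myc, kras, hyp, immune


# ---------------------------------------------------------------------------
# Regional (per-patient, per-niche) cohort


def generate_regional_cohort(
    n_patients: int = 20,
    genes: int = 2000,
    seed: int = 0,
    modality: str = "protein",
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    dropout_midpoint: float = 4.5,
    dropout_scale: float = 1.0,
    counts_depth: int = 1_000_000,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """One sample per tissue niche per patient plus a WHOLE bulk mixture.

    Baseline expression is log-normal; each niche up-shifts its program
    genes by ``effect_log2`` (scaled by the latent level for CT and PAN).
    WHOLE columns are convex combinations of the patient's own niche
    profiles.  The protein modality applies missing-not-at-random
    dropout, logistic in log2 abundance, recorded in the missing mask.

    Passing ``truth`` reuses an existing gene universe (baselines and
    program memberships) and draws a new, independent patient cohort
    from it — the way an external validation cohort shares the biology
    but not the samples.  Note the returned truth is the shared object;
    its ``sample_truth`` is replaced by the new cohort's table.
    """
    if n_patients < 2:
        raise TriaxisError("need n_patients >= 2")
    if genes < 200:
        raise TriaxisError("need genes >= 200")
    if truth is None:
        truth = _make_truth(genes, seed)
    elif len(truth.gene_ids) != genes:
        raise TriaxisError("supplied truth has a different gene universe size")
    rng = np.random.default_rng(seed + 1)

    cols, meta_rows, truth_rows = {}, [], []
    for p in range(n_patients):
        pid = f"P{p:02d}"
        niche_linear = {}
        for niche in ("LE", "IT", "CT", "PAN", "MVP"):
            myc, kras, hyp, imm = _draw_levels(niche, rng)
            mean = _expected_log2(truth, niche, myc, kras, hyp, effect_log2, imm)
            x = mean.to_numpy() + rng.normal(0, noise_sd, size=genes)
            linear = np.exp2(x)
            sid = f"{pid}_{niche}"
            niche_linear[niche] = linear
            cols[sid] = linear
            meta_rows.append((sid, pid, niche))
            truth_rows.append((sid, pid, niche, myc, kras, hyp, imm))
        w = rng.dirichlet(np.ones(5))
        whole = sum(wi * niche_linear[n] for wi, n in zip(w, ("LE", "IT", "CT", "PAN", "MVP")))
        sid = f"{pid}_WHOLE"
        cols[sid] = whole
        meta_rows.append((sid, pid, "WHOLE"))
        mix_levels = np.array([truth_rows[-5 + i][3:7] for i in range(5)])
        wm, wk, wh, wi_ = (float(v) for v in w @ mix_levels)
        truth_rows.append((sid, pid, "WHOLE", wm, wk, wh, wi_))

    values = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "niche"]).set_index("sample_id")
    meta["modality"] = modality
    truth = GroundTruth(
        gene_ids=truth.gene_ids,
        program_genes=truth.program_genes,
        base_log2=truth.base_log2,
        leuko_base_log2=truth.leuko_base_log2,
    )
    truth.sample_truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "patient_id", "niche", "myc_level", "kras_level", "hypoxia_level", "immune_level"],
    ).set_index("sample_id")
    truth.params = {
        "n_patients": n_patients,
        "genes": genes,
        "seed": seed,
        "modality": modality,
        "effect_log2": effect_log2,
        "noise_sd": noise_sd,
    }

    mask = None
    if modality == "protein":
        log2v = np.log2(values.to_numpy())
        p_miss = 1.0 / (1.0 + np.exp((log2v - dropout_midpoint) / dropout_scale))
        drop = rng.random(values.shape) < p_miss
        vals = values.to_numpy().copy()
        vals[drop] = 0.0
        values = pd.DataFrame(vals, index=values.index, columns=values.columns)
        mask = pd.DataFrame(drop, index=values.index, columns=values.columns)
    elif modality == "rna_counts":
        freqs = values.to_numpy() / values.to_numpy().sum(axis=0, keepdims=True)
        counts = np.column_stack(
            [rng.multinomial(counts_depth, freqs[:, j]) for j in range(freqs.shape[1])]
        )
        values = pd.DataFrame(counts, index=values.index, columns=values.columns)

    return ExpressionMatrix(values, meta, modality, missing_mask=mask), truth


# ---------------------------------------------------------------------------
# Gene-set collection (planted programs + decoys)


def generate_geneset_collection(
    truth: GroundTruth, n_decoys: int = 50, seed: int = 0, set_fraction: float = 0.75
) -> GeneSetCollection:
    """One coherent set per planted program plus size-matched random decoys."""
    if n_decoys < 0:
        raise TriaxisError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed + 2)
    coll = GeneSetCollection()
    sizes = []
    for prog, genes in truth.program_genes.items():
        k = max(20, int(round(set_fraction * len(genes))))
        if len(genes) < 20:
            raise TriaxisError(f"program {prog} has fewer than 20 genes")
        pick = sorted(rng.choice(len(genes), size=min(k, len(genes)), replace=False))
        members = tuple(genes[i] for i in pick)
        sizes.append(len(members))
        coll.add(GeneSet(PROGRAM_SIGNATURES[prog], "synthetic", members))
    universe = np.array(truth.gene_ids)
    for d in range(n_decoys):
        size = sizes[d % len(sizes)]
        pick = rng.choice(len(universe), size=size, replace=False)
        coll.add(GeneSet(f"DECOY_{d:03d}", "synthetic", tuple(sorted(universe[pick]))))
    return coll


# ---------------------------------------------------------------------------
# Counts compendium (niche references + LEUKO surrogate)


def generate_counts_compendium(
    truth: GroundTruth,
    depth: int = 1_000_000,
    seed: int = 0,
    n_per_niche: int = 20,
    niches: tuple = ("CT", "PAN", "LE", "MVP", "LEUKO"),
    effect_log2: float | None = None,
    jitter_sd: float = 0.3,
) -> ExpressionMatrix:
    """Multinomial count samples per niche, consistent with the cohort means.

    LEUKO samples are dominated by the immune program and act as the
    inflammatory-infiltrate surrogate for mixture training.  Column sums
    equal ``depth`` exactly.  Appends the samples' latent levels to
    ``truth.sample_truth``.
    """
    if depth < 10_000:
        raise TriaxisError("depth must be >= 1e4")
    effect = truth.params.get("effect_log2", 2.0) if effect_log2 is None else effect_log2
    rng = np.random.default_rng(seed + 3)
    cols, meta_rows, truth_rows, profile_freqs = {}, [], [], []
    i = 0
    # latent profiles are drawn before any counting so that the same seed
    # yields the same underlying samples at every depth
    for niche in niches:
        for _ in range(n_per_niche):
            myc, kras, hyp, imm = _draw_levels(niche, rng)
            mean = _expected_log2(truth, niche, myc, kras, hyp, effect, imm)
            linear = np.exp2(mean.to_numpy() + rng.normal(0, jitter_sd, size=len(mean)))
            profile_freqs.append(linear / linear.sum())
            sid = f"C{i:03d}_{niche}"
            meta_rows.append((sid, "compendium", niche))
            truth_rows.append((sid, "compendium", niche, myc, kras, hyp, imm))
            i += 1
    for (sid, _, _), freq in zip(meta_rows, profile_freqs):
        cols[sid] = rng.multinomial(depth, freq)
    values = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "niche"]).set_index("sample_id")
    meta["modality"] = "rna_counts"
    new_truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "patient_id", "niche", "myc_level", "kras_level", "hypoxia_level", "immune_level"],
    ).set_index("sample_id")
    truth.sample_truth = (
        new_truth if truth.sample_truth is None else pd.concat([truth.sample_truth, new_truth])
    )
    return ExpressionMatrix(values, meta, "rna_counts")


# ---------------------------------------------------------------------------
# Single cells


def generate_single_cell(
    n_cells: int = 600,
    seed: int = 0,
    genes: int = 2000,
    effect_log2: float = 2.5,
    group_probs: tuple = (0.35, 0.35, 0.30),
    lib_median: float = 15_000.0,
    lib_sigma: float = 0.35,
    jitter_sd: float = 0.2,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Cells from three populations with mutually exclusive axis programs.

    KRAS_high cells up-shift the migratory program, MYC_high cells the
    proliferative program, Central cells neither; no cell carries both.
    Per-cell library sizes are log-normal around ``lib_median`` so a
    minority of cells falls below the 10,000-UMI quality bar.
    """
    if n_cells < 100:
        raise TriaxisError("need n_cells >= 100")
    truth = _make_truth(genes, seed)
    rng = np.random.default_rng(seed + 4)
    group_names = ("KRAS_high", "MYC_high", "Central")
    groups = rng.choice(3, size=n_cells, p=np.asarray(group_probs))
    libs = np.maximum(
        100, np.round(np.exp(rng.normal(np.log(lib_median), lib_sigma, size=n_cells)))
    ).astype(int)

    base = truth.base_log2.to_numpy()
    kras_idx = [truth.gene_ids.index(g) for g in truth.program_genes["CT_KRAS"]]
    myc_idx = [truth.gene_ids.index(g) for g in truth.program_genes["CT_MYC"]]
    cols, meta_rows, truth_rows = {}, [], []
    for c in range(n_cells):
        mean = base + rng.normal(0, jitter_sd, size=genes)
        if group_names[groups[c]] == "KRAS_high":
            mean[kras_idx] += effect_log2
        elif group_names[groups[c]] == "MYC_high":
            mean[myc_idx] += effect_log2
        linear = np.exp2(mean)
        cid = f"cell{c:04d}"
        cols[cid] = rng.multinomial(libs[c], linear / linear.sum())
        meta_rows.append((cid, "sc", "NA"))
        truth_rows.append((cid, group_names[groups[c]], int(libs[c])))
    values = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "niche"]).set_index("sample_id")
    meta["modality"] = "sc_counts"
    truth.cell_truth = pd.DataFrame(truth_rows, columns=["cell_id", "group", "umi_total"]).set_index(
        "cell_id"
    )
    truth.params = {"n_cells": n_cells, "seed": seed, "genes": genes, "effect_log2": effect_log2}
    return ExpressionMatrix(values, meta, "sc_counts"), truth


# ---------------------------------------------------------------------------
# Pharmacology fixture (cell lines, drugs, survival)


def generate_pharmaco_fixture(
    n_lines: int = 40,
    n_drugs: int = 24,
    seed: int = 0,
    genes: int = 2000,
    effect_log2: float = 2.0,
    noise_sd: float = 0.4,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cell-line expression with graded axis levels, DSS1 drug table and
    survival times whose hazard increases with the KRAS-like level.

    A quarter of the drugs are MYC-axis drugs (sensitive only in
    MYC-high lines), a quarter KRAS-axis drugs with flat low DSS1
    (resistance everywhere), the rest null drugs flat at a low mean.
    Passing ``truth`` reuses an existing gene universe so that models
    trained on a tissue cohort transfer to the lines.
    """
    if n_lines < 12:
        raise TriaxisError("need n_lines >= 12 for quartile groups of 4")
    if truth is None:
        truth = _make_truth(genes, seed)
    elif len(truth.gene_ids) != genes:
        raise TriaxisError("supplied truth has a different gene universe size")
    truth = GroundTruth(
        gene_ids=truth.gene_ids,
        program_genes=truth.program_genes,
        base_log2=truth.base_log2,
        leuko_base_log2=truth.leuko_base_log2,
    )
    rng = np.random.default_rng(seed + 5)

    myc = rng.uniform(0, 1, n_lines)
    kras = rng.uniform(0, 1, n_lines)
    hyp = rng.uniform(0, 1, n_lines)
    cols, meta_rows, truth_rows = {}, [], []
    pg = truth.program_genes
    for i in range(n_lines):
        mean = truth.base_log2.copy()
        # lines are tumour (CT-like) cells: same axis geometry as the CT niche
        mean[list(pg["CT_MYC"])] += effect_log2 * (0.35 + 0.65 * myc[i])
        mean[list(pg["CT_KRAS"])] += effect_log2 * (0.35 + 0.65 * kras[i])
        mean[list(pg["PAN_hypoxia"])] += effect_log2 * hyp[i]
        sid = f"LINE{i:03d}"
        cols[sid] = np.exp2(mean.to_numpy() + rng.normal(0, noise_sd, size=genes))
        meta_rows.append((sid, sid, "NA"))
        truth_rows.append((sid, sid, "NA", myc[i], kras[i], hyp[i]))
    values = pd.DataFrame(cols, index=truth.gene_ids)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "niche"]).set_index("sample_id")
    meta["modality"] = "rna_tpm"
    expr = ExpressionMatrix(values, meta, "rna_tpm")
    truth.sample_truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "patient_id", "niche", "myc_level", "kras_level", "hypoxia_level"],
    ).set_index("sample_id")

    n_myc = n_drugs // 4
    n_kras = n_drugs // 4
    drug_rows, truth_drug = [], []
    lines = list(values.columns)
    for d in range(n_drugs):
        if d < n_myc:
            name, axis, direction = f"DRUG_MYC_{d:02d}", "MYC", "sensitive_in_high"
            dss = 0.04 + 0.35 / (1 + np.exp(-(myc - 0.6) / 0.08)) + rng.normal(0, 0.02, n_lines)
        elif d < n_myc + n_kras:
            name, axis, direction = f"DRUG_KRAS_{d:02d}", "KRAS", "resistant_everywhere"
            dss = 0.03 + rng.normal(0, 0.015, n_lines)
        else:
            name, axis, direction = f"DRUG_NULL_{d:02d}", "none", "none"
            dss = 0.05 + rng.normal(0, 0.03, n_lines)
        dss = np.clip(dss, 0.0, 1.0)
        drug_rows.extend((lines[i], name, float(dss[i])) for i in range(n_lines))
        truth_drug.append((name, axis, direction))
    drug_table = pd.DataFrame(drug_rows, columns=["cell_line", "drug", "dss1"])
    truth.drug_truth = pd.DataFrame(truth_drug, columns=["drug", "axis", "effect_direction"]).set_index(
        "drug"
    )

    rate = 0.03 * np.exp(1.3 * kras)
    raw_t = rng.exponential(1.0 / rate)
    horizon = 60.0
    surv = pd.DataFrame(
        {
            "sample_id": lines,
            "time": np.minimum(raw_t, horizon),
            "event": (raw_t <= horizon).astype(int),
        }
    ).set_index("sample_id")
    truth.params = {"n_lines": n_lines, "n_drugs": n_drugs, "seed": seed, "genes": genes}
    return expr, drug_table, surv, truth
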