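"""Generate the synthetic study datasets used by the downstream analyses.

Writes a 20-patient regional proteomic + transcriptomic cohort (shared
gene universe), an external paired validation cohort, a niche counts
compendium with a leukocyte compartment, a single-cell dataset and a
cell-line pharmacology fixture under results/data/.
"""

from pathlib import Path

from triaxis import io, synthetic

SEED = 7
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    prot, truth = synthetic.generate_regional_cohort(20, 2000, seed=SEED, modality="protein")
    rna, _ = synthetic.generate_regional_cohort(20, 2000, seed=SEED, modality="rna_tpm")
    io.write_expression_table(prot, OUT / "cohort_protein.tsv", OUT / "cohort_meta.tsv")
    io.write_expression_table(rna, OUT / "cohort_rna.tsv")
    truth.to_json(OUT / "cohort_truth.json")

    ext_p, _ = synthetic.generate_regional_cohort(6, 2000, seed=SEED + 10, modality="protein", truth=truth)
    ext_r, _ = synthetic.generate_regional_cohort(6, 2000, seed=SEED + 10, modality="rna_tpm", truth=truth)
    io.write_expression_table(ext_p, OUT / "external_protein.tsv", OUT / "external_meta.tsv")
    io.write_expression_table(ext_r, OUT / "external_rna.tsv")

    sets = synthetic.generate_geneset_collection(truth, n_decoys=50, seed=SEED)
    io.write_gmt(sets, OUT / "signatures.gmt")

    comp = synthetic.generate_counts_compendium(truth, depth=1_000_000, seed=SEED)
    io.write_expression_table(comp, OUT / "compendium.tsv", OUT / "compendium_meta.tsv")

    sc, sc_truth = synthetic.generate_single_cell(600, seed=SEED)
    io.write_expression_table(sc, OUT / "sc_counts.tsv", OUT / "sc_meta.tsv")
    sc_truth.to_json(OUT / "sc_truth.json")

    expr, drugs, surv, ph_truth = synthetic.generate_pharmaco_fixture(40, 24, seed=SEED)
    io.write_expression_table(expr, OUT / "lines_rna.tsv", OUT / "lines_meta.tsv")
    drugs.to_csv(OUT / "drugs_dss1.csv", index=False)
    surv.reset_index().to_csv(OUT / "survival.csv", index=False)
    ph_truth.to_json(OUT / "pharmaco_truth.json")

    print(f"cohort: {prot.n_features} proteins x {prot.n_samples} samples "
          f"({prot.missing_mask.to_numpy().mean():.1%} label-free missingness)")
    print(f"gene sets: {len(sets)} ({6} planted programs + 50 decoys)")
    print(f"compendium: {comp.n_samples} samples at depth 1e6; single cells: {sc.n_samples}")
    print(f"pharmacology: {expr.n_samples} lines x {drugs['drug'].nunique()} drugs")
    print(f"all tables under {OUT}/")


if __name__ == "__main__":
    main()
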