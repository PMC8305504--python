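#!/usr/bin/env python
"""Principal-component variance analysis of expression and splicing.

PCA of the log-CPM expression matrix and of the filtered PSI matrix,
followed by the weighted per-factor variance decomposition over the top
10 PCs (ancestry, location, disease, location x disease).  Writes
results/{expression,psi}_pcva.tsv and the PC score tables.
"""

from pathlib import Path

from psipath import log_cpm, pcva, read_counts, read_metadata, read_psi_matrix, run_pca

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    matrices = {
        "expression": log_cpm(read_counts(ROOT / "cohort" / "counts.tsv")),
        "psi": read_psi_matrix(ROOT / "psi_filtered.tsv"),
    }
    for name, matrix in matrices.items():
        scores, frac = run_pca(matrix)
        decomp = pcva(scores, frac, meta)
        scores.to_csv(ROOT / f"{name}_pcs.tsv", sep="\t", index_label="sample_id")
        decomp.to_table().to_csv(ROOT / f"{name}_pcva.tsv", sep="\t", index=False)
        w = decomp.weighted_components
        print(f"{name}: PC1-PC10 hold {100 * decomp.sum_pc_variance:.1f}% of variance")
        for factor, value in w.items():
            print(f"    {factor:>18}: {100 * value:5.1f}%")


if __name__ == "__main__":
    main()
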