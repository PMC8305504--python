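#!/usr/bin/env python
"""Score tissue compartments (epithelial / immune / fibroblast).

Derives marker sets from the cell-type reference (> 5 CPM in one
compartment, < 1 CPM in the other two), scores every sample by PC1 of
its marker submatrix, and compares fibroblast scores between ancestry
groups with a two-sided Welch t-test.  Writes
results/compartment_scores.tsv.
"""

from pathlib import Path

import pandas as pd

from psipath import build_marker_sets, compare_groups, log_cpm, read_counts, read_metadata
from psipath.compartments import score_samples

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    reference = pd.read_csv(ROOT / "cohort" / "reference_cpm.tsv", sep="\t", index_col=0)
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    markers = build_marker_sets(reference)
    for comp, ms in markers.items():
        print(f"  {comp}: {len(ms.genes)} marker genes")
    scores = score_samples(log_cpm(read_counts(ROOT / "cohort" / "counts.tsv")), markers)
    scores.to_csv(ROOT / "compartment_scores.tsv", sep="\t", index_label="sample_id")
    for comp in scores.columns:
        t, p = compare_groups(scores[comp], meta.loc[scores.index, "location"])
        print(f"  {comp} score, ileum vs rectum: t = {t:.2f}, p = {p:.2g}")
    t, p = compare_groups(scores["fibroblast"], meta.loc[scores.index, "ancestry"])
    print(f"  fibroblast score, African vs European ancestry: t = {t:.2f}, p = {p:.2g}")


if __name__ == "__main__":
    main()
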