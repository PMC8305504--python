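"""Compartment (cell-type) scoring of bulk samples.

Marker genes for the epithelial, immune and fibroblast compartments are
derived from a cell-type reference expression table: a gene is a marker
of the compartment where it exceeds 5 CPM while staying below 1 CPM in
both other compartments, which forces the three sets to be disjoint.
Each bulk sample is then scored by PC1 over the marker-gene submatrix of
the normalized expression matrix — a surrogate for the compartment's
proportion in the biopsy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from psipath.config import COMPARTMENTS
from psipath.pcva import run_pca

logger = logging.getLogger(__name__)

CPM_HI = 5.0  # own-compartment expression must exceed this
CPM_LO = 1.0  # other-compartment expression must stay below this


@dataclass(frozen=True)
class MarkerGeneSet:
    compartment: str
    genes: tuple[str, ...]


def build_marker_sets(
    reference: pd.DataFrame, hi: float = CPM_HI, lo: float = CPM_LO
) -> dict[str, MarkerGeneSet]:
    """Derive per-compartment marker sets from a genes x cell-types CPM table.

    Gene g is a marker of compartment c iff CPM(g, c) > hi and
    CPM(g, c') < lo for every other compartment c' (strict inequalities).
    """
    sets = {}
    for comp in reference.columns:
        others = [c for c in reference.columns if c != comp]
        mask = reference[comp] > hi
        for o in others:
            mask &= reference[o] < lo
        sets[comp] = MarkerGeneSet(str(comp), tuple(reference.index[mask]))
        logger.info("markers[%s]: %d genes", comp, mask.sum())
    return sets


def compartment_pc1(expression: pd.DataFrame, markers: MarkerGeneSet) -> pd.Series:
    """Per-sample PC1 score over the marker-gene submatrix.

    ``expression`` is a normalized genes x samples matrix.  The score is
    sign-oriented to correlate positively with the mean marker
    expression across samples, so higher always means "more of this
    compartment".  Raises if fewer than two markers are present,
    listing the missing genes.
    """
    present = [g for g in markers.genes if g in expression.index]
    if len(present) < 2:
        missing = [g for g in markers.genes if g not in expression.index]
        raise ValueError(
            f"{markers.compartment}: need >= 2 marker genes in the matrix, "
            f"found {len(present)}; missing: {missing[:10]}"
        )
    sub = expression.loc[present]
    mean_expr = sub.mean(axis=0)
    if float(sub.var(axis=1).sum()) == 0.0:  # all samples identical
        return pd.Series(0.0, index=sub.columns, name=markers.compartment)
    scores, _ = run_pca(sub, n_components=1)
    pc1 = scores.iloc[:, 0]
    r = np.corrcoef(pc1.to_numpy(), mean_expr.to_numpy())[0, 1]
    if np.isfinite(r) and r < 0:
        pc1 = -pc1
    return pc1.rename(markers.compartment)


def score_samples(
    expression: pd.DataFrame, marker_sets: dict[str, MarkerGeneSet]
) -> pd.DataFrame:
    """Samples x compartments score table."""
    cols = {c: compartment_pc1(expression, ms) for c, ms in marker_sets.items()}
    order = [c for c in COMPARTMENTS if c in cols] + [
        c for c in cols if c not in COMPARTMENTS
    ]
    return pd.DataFrame(cols)[order]


def compare_groups(
    scores: pd.Series, grouping: pd.Series
) -> tuple[float, float]:
    """Two-sided Welch t-test of a score between two groups.

    Returns (t statistic, p-value).
    """
    levels = sorted(grouping.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    a = scores[grouping == levels[0]].to_numpy(dtype=float)
    b = scores[grouping == levels[1]].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # zero variance in both groups and equal means
        return 0.0, 1.0
    return float(t), float(p)
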