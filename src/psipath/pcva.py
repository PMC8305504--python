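"""PCA plus weighted per-factor variance decomposition (PCVA).

For each of the top principal components of a features x samples matrix,
an ordinary linear model of the PC score on the experimental factors
(ancestry, location, disease, location x disease by default) attributes
a fraction of that PC's variance to each factor via Type-II-style sums
of squares.  The per-factor fractions are then summed over PCs weighted
by each PC's share of total variance, giving one variance component per
factor; by construction no component can exceed the summed variance
share of the PCs analyzed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

DEFAULT_FACTORS = ("ancestry", "location", "disease", "location:disease")


def log_cpm(counts: pd.DataFrame, min_mean: float = 5.0) -> pd.DataFrame:
    """Library-size-normalize a genes x samples count matrix.

    Genes with mean count <= ``min_mean`` are dropped (strict "> min_mean"
    expression rule); the rest become log2(CPM + 1).
    """
    kept = counts.loc[counts.mean(axis=1) > min_mean]
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = kept / lib * 1e6
    logger.info("log_cpm: %d of %d genes kept", len(kept), len(counts))
    return np.log2(cpm + 1.0)


def run_pca(
    matrix: pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a features x samples matrix over samples.

    Features are centered but not scaled to unit variance (PSI and
    log-CPM already share a common scale).  Returns per-sample scores
    and each PC's fraction of total feature variance.  Sign convention:
    every PC is oriented so its largest-magnitude feature loading is
    positive, making results reproducible across linear-algebra backends.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError(
            "matrix contains missing values; apply the filtering cascade "
            "(psipath.filters) before PCA"
        )
    X = matrix.to_numpy(dtype=float).T  # samples x features
    k = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    if k < 1:
        raise ValueError("need at least 2 samples and 1 feature for PCA")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    frac = pca.explained_variance_ratio_.copy()
    score_df = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return score_df, frac


@dataclass
class VarianceDecomposition:
    """Per-PC variance fractions and weighted per-factor components."""

    pc_variance_fractions: np.ndarray  # length n_pcs
    per_pc_factor_fractions: pd.DataFrame  # n_pcs x factors
    weighted_components: pd.Series  # per factor
    sum_pc_variance: float

    def __post_init__(self) -> None:
        w = self.pc_variance_fractions @ self.per_pc_factor_fractions.to_numpy()
        if not np.allclose(w, self.weighted_components.to_numpy(), atol=1e-10):
            raise ValueError("weighted components do not match their definition")
        if (self.weighted_components > self.sum_pc_variance + 1e-10).any():
            raise ValueError("a weighted component exceeds the summed PC variance")
        if (self.per_pc_factor_fractions.to_numpy() < -1e-10).any():
            raise ValueError("negative variance fraction")

    def to_table(self) -> pd.DataFrame:
        """Long-format summary: PC rows, the PC sum, and component rows."""
        rows = [
            {"row": f"PC{i + 1}", "value": v}
            for i, v in enumerate(self.pc_variance_fractions)
        ]
        rows.append({"row": "SUM_PC", "value": self.sum_pc_variance})
        rows += [
            {"row": f"component:{f}", "value": v}
            for f, v in self.weighted_components.items()
        ]
        return pd.DataFrame(rows)


def _check_design(meta: pd.DataFrame, base_factors: list[str]) -> None:
    for f in base_factors:
        if f not in meta.columns:
            raise ValueError(f"metadata lacks factor column {f!r}")
        if meta[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level; cannot decompose")
    for a, b in combinations(base_factors, 2):
        tab = pd.crosstab(meta[a], meta[b])
        if ((tab > 0).sum(axis=1) == 1).all() or ((tab > 0).sum(axis=0) == 1).all():
            raise ValueError(f"factors {a!r} and {b!r} are aliased (confounded design)")


def pcva(
    scores: pd.DataFrame,
    variance_fractions: np.ndarray,
    meta: pd.DataFrame,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> VarianceDecomposition:
    """Weighted variance-component decomposition of PC scores.

    For each PC, a single linear model containing every factor term is
    fit and each term's Type-II sum of squares is divided by the PC
    score's total sum of squares; the resulting per-PC fractions are
    combined across PCs weighted by ``variance_fractions``.
    """
    meta = meta.loc[scores.index]
    base = sorted({f for term in factors for f in term.split(":")})
    _check_design(meta, base)
    terms = [
        ":".join(f"C({f})" for f in term.split(":")) if ":" in term else f"C({term})"
        for term in factors
    ]
    formula_rhs = " + ".join(terms)
    term_to_factor = dict(zip(terms, factors))

    n_pcs = scores.shape[1]
    frac_rows = []
    for j in range(n_pcs):
        df = meta[base].copy()
        df["score"] = scores.iloc[:, j].to_numpy()
        fit = smf.ols(f"score ~ {formula_rhs}", data=df).fit()
        ss_total = float(((df["score"] - df["score"].mean()) ** 2).sum())
        table = anova_lm(fit, typ=2)
        row = {}
        for term, factor in term_to_factor.items():
            if term not in table.index:
                raise ValueError(f"term {factor!r} missing from the fitted model")
            row[factor] = max(0.0, float(table.loc[term, "sum_sq"]) / ss_total)
        frac_rows.append(row)
    per_pc = pd.DataFrame(frac_rows, index=scores.columns)[list(factors)]
    weights = np.asarray(variance_fractions[:n_pcs], dtype=float)
    weighted = pd.Series(weights @ per_pc.to_numpy(), index=per_pc.columns)
    return VarianceDecomposition(
        pc_variance_fractions=weights,
        per_pc_factor_fractions=per_pc,
        weighted_components=weighted,
        sum_pc_variance=float(weights.sum()),
    )
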