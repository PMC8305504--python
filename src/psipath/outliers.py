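"""Detection and characterization of tissue-discordant ("spliceopathy") samples.

A sample is called discordant when, in the top principal components of
the filtered PSI matrix, it lies closer to the centroid of the opposite
tissue location than to its own.  The discordance score is the ratio of
the two centroid distances; centroids are re-estimated once without the
initially flagged samples so an outlier cannot drag its own tissue's
centroid toward itself.

Characterization follows the outlier-analysis recipe: |delta PSI|
profiles between sample groups, intersection of outlier-significant
with location-significant bins ("rectal-like" sites), tissue assignment
restricted to those sites, and complete-linkage hierarchical clustering
of the top differential bins for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from psipath.pcva import run_pca

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaPsiProfile:
    """Histogram of |mean(A) - mean(B)| per bin, 0.05-wide classes."""

    label: str
    edges: np.ndarray  # len k+1, strictly increasing on [0, 1]
    proportions: np.ndarray  # len k, sums to 1

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if len(self.proportions) and abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def mass_at_or_above(self, edge: float) -> float:
        """Total proportion in classes starting at or above ``edge``."""
        return float(self.proportions[self.edges[:-1] >= edge - 1e-12].sum())


def delta_psi_profile(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    width: float = 0.05,
    label: str = "",
) -> DeltaPsiProfile:
    """Per-bin |difference of group mean PSI|, binned at ``width`` steps.

    Classes are half-open [0, w), [w, 2w), ... with the last class
    closed, so a difference of exactly 0.05 falls in the second class.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    d = (matrix[group_a].mean(axis=1) - matrix[group_b].mean(axis=1)).abs()
    edges = np.round(np.arange(0.0, 1.0 + width / 2, width), 10)
    counts, _ = np.histogram(d.to_numpy(), bins=edges)
    props = counts / counts.sum() if counts.sum() else counts.astype(float)
    return DeltaPsiProfile(label or "A_vs_B", edges, props)


@dataclass(frozen=True)
class OutlierCall:
    sample_id: str
    location: str
    d_own: float
    d_opposite: float
    score: float
    flagged: bool


def detect_discordant_samples(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    n_pcs: int = 2,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag samples closer to the opposite tissue's PSI centroid.

    Scores = distance to own-tissue centroid / distance to opposite-
    tissue centroid in the top ``n_pcs`` PC space; samples with score
    strictly above ``threshold`` are flagged.  Centroids are computed
    from all samples, then once more excluding the flagged ones.
    """
    meta = meta.loc[matrix.columns]
    locations = sorted(meta["location"].unique())
    if len(locations) != 2:
        raise ValueError("discordance detection needs exactly two locations")
    counts = meta["location"].value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"location(s) {small} have fewer than 3 samples")
    scores, _ = run_pca(matrix, n_components=n_pcs)
    X = scores.to_numpy()
    loc = meta["location"].to_numpy()

    def one_pass(exclude: set[str]) -> pd.DataFrame:
        centroids = {}
        for tissue in locations:
            use = (loc == tissue) & ~scores.index.isin(list(exclude))
            if not use.any():  # fall back to all samples of the tissue
                use = loc == tissue
            centroids[tissue] = X[use].mean(axis=0)
        rows = []
        for i, sid in enumerate(scores.index):
            own = locations[0] if loc[i] == locations[0] else locations[1]
            opp = locations[1] if own == locations[0] else locations[0]
            d_own = float(np.linalg.norm(X[i] - centroids[own]))
            d_opp = float(np.linalg.norm(X[i] - centroids[opp]))
            score = d_own / d_opp if d_opp > 0 else (1.0 if d_own == 0 else np.inf)
            rows.append(
                OutlierCall(sid, own, d_own, d_opp, score, score > threshold)
            )
        return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")

    first = one_pass(set())
    flagged = set(first.index[first["flagged"]])
    final = one_pass(flagged)
    logger.info(
        "discordance: %d flagged (first pass %d)", final["flagged"].sum(), len(flagged)
    )
    return final


def rectal_like_sites(
    spliceo_significant: set[str], location_significant: set[str]
) -> set[str]:
    """Outlier-divergent bins that are also tissue-differential."""
    return set(spliceo_significant) & set(location_significant)


def classify_on_sites(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spliceo_ids: list[str] | set[str] = (),
    n_pcs: int = 2,
) -> pd.Series:
    """Assign each sample to the nearer tissue centroid on a site subset.

    ``matrix`` is the PSI matrix restricted to the site set of interest;
    centroids are computed from non-outlier samples only, so the
    assignment of the outliers is an out-of-group classification.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty site set")
    meta = meta.loc[matrix.columns]
    spliceo_ids = set(spliceo_ids) | set(meta.index[meta.get("group_label", "") == "spliceopathy"])
    scores, _ = run_pca(matrix, n_components=min(n_pcs, matrix.shape[0]))
    X = scores.to_numpy()
    loc = meta["location"].to_numpy()
    centroids = {}
    for tissue in sorted(meta["location"].unique()):
        use = (loc == tissue) & ~scores.index.isin(list(spliceo_ids))
        centroids[tissue] = X[use].mean(axis=0)
    assignments = {}
    for i, sid in enumerate(scores.index):
        dists = {t: float(np.linalg.norm(X[i] - c)) for t, c in centroids.items()}
        assignments[sid] = min(sorted(dists), key=dists.get)
    return pd.Series(assignments, name="assigned_location")


def select_top_location_bins(results: pd.DataFrame, k: int = 50) -> list[str]:
    """The k most location-significant bins from tidy per-bin results.

    Ties broken by larger |estimate|, then lexicographic bin id.
    """
    loc = results.loc[results["term"] == "location"].copy()
    if len(loc) < k:
        raise ValueError(f"only {len(loc)} location results available, need {k}")
    loc["abs_est"] = -loc["estimate"].abs()
    loc = loc.sort_values(["pvalue", "abs_est", "bin_id"], kind="mergesort")
    return loc["bin_id"].head(k).tolist()


@dataclass
class ClusterResult:
    row_order: list[str]  # bin ids, dendrogram leaf order
    col_order: list[str]  # sample ids, dendrogram leaf order
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def heatmap_cluster(matrix: pd.DataFrame, bin_ids: list[str]) -> ClusterResult:
    """Two-way complete-linkage Euclidean clustering of a bin subset.

    Rows and columns are sorted by id before linkage so leaf orders are
    deterministic under ties.
    """
    missing = [b for b in bin_ids if b not in matrix.index]
    if missing:
        raise ValueError(f"bins not in matrix: {missing[:5]}")
    sub = matrix.loc[sorted(bin_ids), sorted(matrix.columns)]
    if sub.isna().to_numpy().any():
        raise ValueError("matrix subset contains missing values")
    row_link = linkage(sub.to_numpy(), method="complete", metric="euclidean")
    col_link = linkage(sub.to_numpy().T, method="complete", metric="euclidean")
    return ClusterResult(
        row_order=[sub.index[i] for i in leaves_list(row_link)],
        col_order=[sub.columns[i] for i in leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
    )


def plot_heatmap(matrix: pd.DataFrame, cluster: ClusterResult, path) -> None:
    """Optional PNG heatmap in dendrogram order (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.loc[cluster.row_order, cluster.col_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=0, vmax=1)
    ax.set_xlabel("samples")
    ax.set_ylabel("exonic bins")
    fig.colorbar(im, ax=ax, label="PSI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
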