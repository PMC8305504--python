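"""Per-exon-bin linear mixed models for differential splicing.

Each bin's PSI row is modeled untransformed on [0, 1]:

    PSI ~ disease + location + ancestry + disease:location + (1 | individual)

Per-term p-values come from likelihood-ratio tests of maximum-likelihood
fits with and without the term; the interaction is tested against the
main-effects model, the disease and location main effects are tested
between models without the interaction (they are marginal to it), and
ancestry is tested with the interaction retained.  When the
random-intercept variance estimates to zero or the fit fails, the bin is
refit by ordinary least squares and flagged — never silently dropped.

The outlier-group variant swaps the fixed effects for group (ileum,
rectum, spliceopathy) + ancestry and reports the two group contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TERMS = ("location", "disease", "ancestry", "disease:location")
GROUP_TERMS = ("group", "spliceopathy_vs_ileum", "spliceopathy_vs_rectum")

#: random-intercept variance below this fraction of the residual variance
#: is treated as a singular (boundary) fit
_RE_VAR_REL_TOL = 1e-6


@dataclass
class BinModelResult:
    """Fitted per-bin model: one row per term (estimate in PSI units)."""

    bin_id: str
    results: pd.DataFrame  # columns: term, estimate, se, pvalue
    converged: bool
    fallback: bool  # True when the OLS fallback (or degenerate path) was used

    def pvalue(self, term: str) -> float:
        return float(self.results.set_index("term").loc[term, "pvalue"])

    def estimate(self, term: str) -> float:
        return float(self.results.set_index("term").loc[term, "estimate"])


class _Fit:
    """Minimal facade over a fitted MixedLM or OLS result."""

    __slots__ = ("llf", "params", "cov", "converged", "re_var", "resid_var")

    def __init__(self, llf, params, cov, converged, re_var, resid_var):
        self.llf = llf
        self.params = params
        self.cov = cov
        self.converged = converged
        self.re_var = re_var
        self.resid_var = resid_var


def _fit_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> _Fit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, X, groups=groups).fit(reml=False, disp=False)
    return _Fit(
        llf=float(res.llf),
        params=np.asarray(res.fe_params),
        cov=np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]],
        converged=bool(res.converged),
        re_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
    )


def _fit_ols(y: np.ndarray, X: np.ndarray) -> _Fit:
    res = sm.OLS(y, X).fit()
    return _Fit(
        llf=float(res.llf),
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        converged=True,
        re_var=0.0,
        resid_var=float(res.scale),
    )


def _lrt_p(full: _Fit, reduced: _Fit, df: int) -> float:
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return float(stats.chi2.sf(stat, df))


class DesignMatrices:
    """Design matrices for the per-bin models, built from metadata once."""

    def __init__(self, meta: pd.DataFrame):
        self.samples = list(meta.index)
        self.groups = meta["individual_id"].to_numpy()
        n = len(meta)
        const = np.ones(n)
        loc = (meta["location"] == "rectum").to_numpy(float)
        dis = (meta["disease"] == "UC").to_numpy(float)
        anc = (meta["ancestry"] == "African").to_numpy(float)
        inter = loc * dis
        self.X = {
            "full": np.column_stack([const, loc, dis, anc, inter]),
            "main": np.column_stack([const, loc, dis, anc]),
            "no_loc": np.column_stack([const, dis, anc]),
            "no_dis": np.column_stack([const, loc, anc]),
            "no_anc": np.column_stack([const, loc, dis, inter]),
        }
        # (estimate source model, column index) per term
        self.term_coord = {
            "location": ("main", 1),
            "disease": ("main", 2),
            "ancestry": ("full", 3),
            "disease:location": ("full", 4),
        }
        # (full model, reduced model) per term for the LRT
        self.term_lrt = {
            "location": ("main", "no_loc"),
            "disease": ("main", "no_dis"),
            "ancestry": ("full", "no_anc"),
            "disease:location": ("full", "main"),
        }

        grp = np.where(
            meta.get("group_label", pd.Series("differentiated", index=meta.index))
            == "spliceopathy",
            "spliceopathy",
            meta["location"],
        )
        g_rec = (grp == "rectum").astype(float)
        g_spl = (grp == "spliceopathy").astype(float)
        self.group_labels = grp
        self.Xg = {
            "full": np.column_stack([const, g_rec, g_spl, anc]),
            "no_group": np.column_stack([const, anc]),
        }


def _degenerate(bin_id: str, terms: tuple[str, ...]) -> BinModelResult:
    res = pd.DataFrame(
        {"term": list(terms), "estimate": 0.0, "se": 0.0, "pvalue": 1.0}
    )
    return BinModelResult(bin_id, res, converged=True, fallback=True)


def _fit_models(
    y: np.ndarray, designs: dict[str, np.ndarray], groups: np.ndarray
) -> tuple[dict[str, _Fit], bool]:
    """Fit the needed models as mixed models; fall back to OLS on singular fits."""
    fits: dict[str, _Fit] = {}
    fallback = False
    ref_name = "full" if "full" in designs else next(iter(designs))
    try:
        for name, X in designs.items():
            fits[name] = _fit_mixed(y, X, groups)
        ref = fits[ref_name]
        if (not all(f.converged for f in fits.values())) or ref.re_var <= (
            _RE_VAR_REL_TOL * max(ref.resid_var, 1e-300)
        ):
            fallback = True
    except (np.linalg.LinAlgError, ValueError):
        fallback = True
    if fallback:
        fits = {name: _fit_ols(y, X) for name, X in designs.items()}
    return fits, fallback


def fit_bin_lmm(
    psi_row: pd.Series,
    meta: pd.DataFrame,
    designs: DesignMatrices | None = None,
    test: str = "lrt",
    terms: tuple[str, ...] = TERMS,
) -> BinModelResult:
    """Fit the four-term mixed model to one fully observed PSI row.

    ``terms`` restricts output (and the models actually fitted) to a
    subset of the per-term tests, which saves refits in large screens.
    """
    if test not in ("lrt", "wald"):
        raise ValueError("test must be 'lrt' or 'wald'")
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    designs = designs or DesignMatrices(meta.loc[psi_row.index])
    y = psi_row.loc[designs.samples].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"{psi_row.name}: missing values; filter the matrix first")
    bin_id = str(psi_row.name)
    if np.ptp(y) == 0.0:
        return _degenerate(bin_id, terms)
    needed = set()
    for term in terms:
        needed.add(designs.term_coord[term][0])
        if test == "lrt":
            needed.update(designs.term_lrt[term])
    fits, fallback = _fit_models(
        y, {k: designs.X[k] for k in designs.X if k in needed}, designs.groups
    )
    rows = []
    for term in terms:
        model, col = designs.term_coord[term]
        est = float(fits[model].params[col])
        se = float(np.sqrt(max(0.0, fits[model].cov[col, col])))
        if test == "lrt":
            full_m, red_m = designs.term_lrt[term]
            p = _lrt_p(fits[full_m], fits[red_m], df=1)
        else:
            p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
        rows.append({"term": term, "estimate": est, "se": se, "pvalue": p})
    converged = all(f.converged for f in fits.values())
    return BinModelResult(bin_id, pd.DataFrame(rows), converged, fallback)


def fit_group_lmm(
    psi_row: pd.Series,
    meta: pd.DataFrame,
    designs: DesignMatrices | None = None,
    include_group_lrt: bool = True,
) -> BinModelResult:
    """Three-group model (ileum / rectum / spliceopathy) + ancestry.

    The overall group term is tested by a 2-df likelihood-ratio test;
    the spliceopathy-ileum and spliceopathy-rectum contrasts carry Wald
    p-values from the full fit.
    """
    designs = designs or DesignMatrices(meta.loc[psi_row.index])
    if not (designs.group_labels == "spliceopathy").any():
        raise ValueError("no spliceopathy samples in the metadata group labels")
    y = psi_row.loc[designs.samples].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"{psi_row.name}: missing values; filter the matrix first")
    bin_id = str(psi_row.name)
    if np.ptp(y) == 0.0:
        return _degenerate(bin_id, GROUP_TERMS if include_group_lrt else GROUP_TERMS[1:])
    models = designs.Xg if include_group_lrt else {"full": designs.Xg["full"]}
    fits, fallback = _fit_models(y, models, designs.groups)
    full = fits["full"]
    rows = []
    if include_group_lrt:
        p_group = _lrt_p(full, fits["no_group"], df=2)
        rows.append(
            {"term": "group", "estimate": np.nan, "se": np.nan, "pvalue": p_group}
        )
    # contrasts: c' beta with beta = (const, rectum, spliceopathy, ancestry)
    for term, c in (
        ("spliceopathy_vs_ileum", np.array([0.0, 0.0, 1.0, 0.0])),
        ("spliceopathy_vs_rectum", np.array([0.0, -1.0, 1.0, 0.0])),
    ):
        est = float(c @ full.params)
        se = float(np.sqrt(max(0.0, c @ full.cov @ c)))
        p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
        rows.append({"term": term, "estimate": est, "se": se, "pvalue": p})
    converged = all(f.converged for f in fits.values())
    return BinModelResult(bin_id, pd.DataFrame(rows), converged, fallback)


def _tidy(results: list[BinModelResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        df = r.results.copy()
        df.insert(0, "bin_id", r.bin_id)
        df["converged"] = r.converged
        df["fallback"] = r.fallback
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fit_all_bins(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    test: str = "lrt",
    terms: tuple[str, ...] = TERMS,
) -> pd.DataFrame:
    """Tidy per-term results for every row of a filtered PSI matrix."""
    designs = DesignMatrices(meta.loc[matrix.columns])
    out = _tidy(
        [
            fit_bin_lmm(matrix.loc[b], meta, designs, test=test, terms=terms)
            for b in matrix.index
        ]
    )
    n_fb = out.loc[out["term"] == terms[0], "fallback"].sum()
    logger.info("fit_all_bins: %d bins, %d OLS fallbacks", len(matrix), n_fb)
    return out


def fit_group_all(
    matrix: pd.DataFrame, meta: pd.DataFrame, include_group_lrt: bool = True
) -> pd.DataFrame:
    """Tidy group-model results for every row of a relaxed-filtered matrix."""
    designs = DesignMatrices(meta.loc[matrix.columns])
    return _tidy(
        [
            fit_group_lmm(matrix.loc[b], meta, designs, include_group_lrt)
            for b in matrix.index
        ]
    )


def fdr_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns (significant flags, adjusted p-values) in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([], dtype=bool), np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1] and non-missing")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj
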