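"""The exonic-bin filtering cascade and its relaxed outlier-analysis variant.

Strict cascade (applied in order):

1. ``filter_complete`` — drop rows where any sample lacks coverage, so
   analysis is limited to bins measurable in every sample.
2. ``filter_constant`` — drop rows identically 0 or identically 1
   across samples (no variability in exon usage).
3. ``filter_constitutive`` — drop rows where 40% of samples sit above
   0.95 or below 0.05 PSI (near-constitutively included/excluded bins).

The relaxed variant for the outlier (spliceopathy) analysis tolerates up
to five missing ileal and five missing rectal samples per row (imputing
them with the tissue-location mean) but no missing outlier samples, then
reapplies the constant and constitutive stages.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterReport:
    """Row bookkeeping for one cascade stage."""

    stage: str
    bins_in: int
    bins_removed: int
    bins_out: int

    def __post_init__(self) -> None:
        if self.bins_out != self.bins_in - self.bins_removed:
            raise ValueError(
                f"inconsistent report for {self.stage}: "
                f"{self.bins_in} - {self.bins_removed} != {self.bins_out}"
            )


def _report(stage: str, before: pd.DataFrame, after: pd.DataFrame) -> FilterReport:
    rep = FilterReport(stage, len(before), len(before) - len(after), len(after))
    logger.info("%s: %d -> %d rows", stage, rep.bins_in, rep.bins_out)
    return rep


def filter_complete(matrix: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop every row containing one or more missing values."""
    out = matrix.dropna(axis=0, how="any")
    return out, _report("complete", matrix, out)


def filter_constant(matrix: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows where every sample has the exact same PSI of 0 or 1."""
    vals = matrix.to_numpy()
    all_zero = (vals == 0.0).all(axis=1)
    all_one = (vals == 1.0).all(axis=1)
    out = matrix.loc[~(all_zero | all_one)]
    return out, _report("constant", matrix, out)


def filter_constitutive(
    matrix: pd.DataFrame,
    frac: float = 0.40,
    hi: float = 0.95,
    lo: float = 0.05,
    rule: str = "per_direction",
    boundary: str = "ge",
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop near-constitutively included or excluded bins.

    A row is dropped when the number of samples with PSI > ``hi`` (or,
    separately, with PSI < ``lo``) reaches ``ceil(frac * n_samples)``.
    ``rule='combined'`` adds the two directions before comparing;
    ``boundary='gt'`` requires strictly more than the threshold.
    """
    n = matrix.shape[1]
    threshold = math.ceil(frac * n)
    vals = matrix.to_numpy()
    n_hi = (vals > hi).sum(axis=1)
    n_lo = (vals < lo).sum(axis=1)
    if rule == "combined":
        counts = [n_hi + n_lo]
    elif rule == "per_direction":
        counts = [n_hi, n_lo]
    else:
        raise ValueError("rule must be 'per_direction' or 'combined'")
    if boundary == "ge":
        drop = np.any([c >= threshold for c in counts], axis=0)
    elif boundary == "gt":
        drop = np.any([c > threshold for c in counts], axis=0)
    else:
        raise ValueError("boundary must be 'ge' or 'gt'")
    out = matrix.loc[~drop]
    return out, _report("constitutive", matrix, out)


def strict_cascade(
    matrix: pd.DataFrame, **constitutive_kwargs
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """complete -> constant -> constitutive, with per-stage reports."""
    out, r1 = filter_complete(matrix)
    out, r2 = filter_constant(out)
    out, r3 = filter_constitutive(out, **constitutive_kwargs)
    return out, [r1, r2, r3]


def relaxed_filter_spliceopathy(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    spliceo_ids: list[str] | set[str],
    max_missing_per_tissue: int = 5,
    **constitutive_kwargs,
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Relaxed coverage rule with tissue-mean imputation, then the
    constant and constitutive stages as in the strict cascade.

    Rows are dropped when more than ``max_missing_per_tissue`` ileal or
    rectal samples, or any outlier-group sample, lack coverage; the
    remaining missing values are imputed with the mean over non-missing
    samples of the same tissue location (outlier samples excluded from
    the imputation pool, since they form their own analysis group).
    """
    spliceo_ids = set(spliceo_ids)
    unknown = spliceo_ids - set(matrix.columns)
    if unknown:
        raise ValueError(f"spliceopathy samples not in matrix: {sorted(unknown)}")
    loc = meta.loc[matrix.columns, "location"]
    tissue_cols = {
        tissue: [
            c for c in matrix.columns if loc[c] == tissue and c not in spliceo_ids
        ]
        for tissue in loc.unique()
    }
    spl_cols = [c for c in matrix.columns if c in spliceo_ids]

    missing = matrix.isna()
    drop = missing[spl_cols].any(axis=1) if spl_cols else pd.Series(False, index=matrix.index)
    for cols in tissue_cols.values():
        drop |= missing[cols].sum(axis=1) > max_missing_per_tissue
    kept = matrix.loc[~drop].copy()
    r1 = _report("relaxed_coverage", matrix, kept)

    for tissue, cols in tissue_cols.items():
        block = kept[cols]
        tissue_mean = block.mean(axis=1, skipna=True)
        # The drop rule guarantees >= 1 observed sample per tissue here.
        assert not tissue_mean.isna().any(), "retained row with an all-missing tissue"
        kept[cols] = block.apply(lambda col: col.fillna(tissue_mean))
    assert not kept.isna().to_numpy().any()

    out, r2 = filter_constant(kept)
    out, r3 = filter_constitutive(out, **constitutive_kwargs)
    return out, [r1, r2, r3]


def reports_to_json(reports: list[FilterReport], path: str | Path) -> None:
    """Write the machine-readable cascade report."""
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=1)


def check_cascade(reports: list[FilterReport]) -> None:
    """Assert stage reports chain: bins_out of stage k = bins_in of k+1."""
    for a, b in zip(reports, reports[1:]):
        if a.bins_out != b.bins_in:
            raise ValueError(
                f"cascade mismatch: {a.stage} out={a.bins_out} != {b.stage} in={b.bins_in}"
            )
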