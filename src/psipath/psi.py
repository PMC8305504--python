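"""Junction counts -> per-bin inclusion/exclusion counts -> PSI.

PSI (percent spliced in) for an exonic bin is IR / (IR + ER), where IR
counts junction reads whose intron ends at the bin's upstream edge or
starts at its downstream edge (the bin was included), and ER counts
reads from junctions whose intron strictly spans the bin (the bin was
skipped).  Low-count handling: with fewer than 10 exclusion reads the
estimate is unstable, so PSI is rounded *up* to the nearest tenth when
inclusion coverage is adequate (IR >= 10) and reported missing
otherwise.  Boundary cases resolve to the favorable branch: ER >= 10
takes the exact ratio, IR >= 10 takes the round-up.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from psipath.annotation import ExonBin, MIN_UNIQUE_READS

logger = logging.getLogger(__name__)

ER_EXACT_MIN = 10  # >= this many exclusion reads: exact ratio
IR_ROUND_MIN = 10  # >= this many inclusion reads: round-up branch


def compute_psi(ir: float, er: float) -> float:
    """PSI for one (IR, ER) count pair; ``nan`` when coverage is inadequate.

    - ER >= 10: exact IR / (IR + ER)
    - ER < 10 and IR >= 10: IR / (IR + ER) rounded up to the nearest 0.1
    - otherwise (including IR = ER = 0): missing
    """
    if ir < 0 or er < 0:
        raise ValueError("counts must be non-negative")
    if er >= ER_EXACT_MIN:
        return ir / (ir + er)
    if ir >= IR_ROUND_MIN:
        return _ceil_tenth(ir, er)
    return math.nan


def _ceil_tenth(ir: float, er: float) -> float:
    # Counts are integers or half-integers (flank averaging), so doubling
    # makes them exact; the ceiling is then pure integer arithmetic and
    # grid values like 0.8 never drift by a float epsilon.
    n2 = round(2 * ir)
    d2 = round(2 * (ir + er))
    return -((-10 * n2) // d2) / 10.0


def compute_psi_array(ir: np.ndarray, er: np.ndarray) -> np.ndarray:
    """Vectorized :func:`compute_psi` over matching count arrays."""
    ir = np.asarray(ir, dtype=float)
    er = np.asarray(er, dtype=float)
    if (ir < 0).any() or (er < 0).any():
        raise ValueError("counts must be non-negative")
    total = ir + er
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, ir / np.where(total > 0, total, 1.0), np.nan)
    out = np.full(ir.shape, np.nan)
    exact = er >= ER_EXACT_MIN
    out[exact] = psi[exact]
    roundup = (~exact) & (ir >= IR_ROUND_MIN)
    if roundup.any():
        n2 = np.rint(2 * ir[roundup]).astype(np.int64)
        d2 = np.rint(2 * total[roundup]).astype(np.int64)
        out[roundup] = -((-10 * n2) // d2) / 10.0
    return out


def junctions_to_bin_counts(
    junctions: pd.DataFrame, bins: list[ExonBin], ir_mode: str = "mean"
) -> pd.DataFrame:
    """Assign junction reads to bins as inclusion/exclusion counts.

    Inclusion junctions of a bin end at ``start - 1`` (upstream flank) or
    start at ``end + 1`` (downstream flank).  IR combines the two flank
    totals — their mean when both flanks have a matching junction, else
    the single available flank (``ir_mode='sum'`` adds them instead).
    ER sums reads over junctions whose intron strictly contains the bin.
    Bins with no matching junction get IR = ER = 0.
    """
    if ir_mode not in ("mean", "sum"):
        raise ValueError("ir_mode must be 'mean' or 'sum'")
    up_lookup: dict[tuple[str, int], float] = {}
    down_lookup: dict[tuple[str, int], float] = {}
    trees: dict[str, IntervalTree] = {}
    if len(junctions):
        grp_end = junctions.groupby(["chrom", "intron_end"])["unique_reads"].sum()
        up_lookup = grp_end.to_dict()
        grp_start = junctions.groupby(["chrom", "intron_start"])["unique_reads"].sum()
        down_lookup = grp_start.to_dict()
        for chrom, sub in junctions.groupby("chrom"):
            trees[str(chrom)] = IntervalTree.from_tuples(
                zip(
                    sub["intron_start"].to_numpy(),
                    sub["intron_end"].to_numpy() + 1,
                    sub["unique_reads"].to_numpy(),
                )
            )
    rows = []
    for b in bins:
        up = up_lookup.get((b.chrom, b.start - 1))
        down = down_lookup.get((b.chrom, b.end + 1))
        flanks = [x for x in (up, down) if x is not None]
        if not flanks:
            ir = 0.0
        elif ir_mode == "sum":
            ir = float(sum(flanks))
        else:
            ir = float(sum(flanks)) / len(flanks)
        er = 0.0
        tree = trees.get(b.chrom)
        if tree is not None:
            for iv in tree.overlap(b.start - 1, b.start):
                # iv covers base start-1, so intron_start <= start - 1;
                # strict containment additionally needs intron_end >= end + 1.
                if iv.end - 1 >= b.end + 1:
                    er += iv.data
        rows.append((b.bin_id, ir, er))
    return pd.DataFrame(rows, columns=["bin_id", "IR", "ER"]).set_index("bin_id")


def quantify_samples(
    junction_tables: dict[str, pd.DataFrame],
    bins: list[ExonBin],
    ir_mode: str = "mean",
    min_unique: int = MIN_UNIQUE_READS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSI matrix (bins x samples) plus an IR/ER audit table.

    ``min_unique`` mirrors the aligner-side junction support threshold
    and is applied before counting, so in-memory junction tables behave
    identically to tables read back from ``SJ.out.tab`` files.
    """
    psi_cols = {}
    audit = []
    for sid, junc in junction_tables.items():
        junc = junc.loc[junc["unique_reads"] >= min_unique]
        counts = junctions_to_bin_counts(junc, bins, ir_mode=ir_mode)
        psi_cols[sid] = compute_psi_array(counts["IR"].to_numpy(), counts["ER"].to_numpy())
        counts = counts.assign(sample_id=sid)
        audit.append(counts)
    index = pd.Index([b.bin_id for b in bins], name="bin_id")
    matrix = pd.DataFrame(psi_cols, index=index)
    audit_df = pd.concat(audit).reset_index() if audit else pd.DataFrame()
    logger.info(
        "quantified %d bins x %d samples (%.1f%% missing)",
        matrix.shape[0],
        matrix.shape[1],
        100 * matrix.isna().to_numpy().mean() if matrix.size else 0.0,
    )
    return matrix, audit_df


def quantify_cohort(cohort, ir_mode: str = "mean", variable_only: bool = False):
    """Convenience wrapper: quantify a simulated cohort's junction tables."""
    bins = cohort.all_bins
    if variable_only:
        keep = set(cohort.var_bin_ids)
        bins = [b for b in bins if b.bin_id in keep]
    return quantify_samples(cohort.junctions, bins, ir_mode=ir_mode)
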