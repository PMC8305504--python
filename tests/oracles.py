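"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written from the rule definitions, deliberately not
sharing code with the implementation it checks.
"""

import math
from fractions import Fraction

import numpy as np


def oracle_psi(ir: int, er: int) -> float:
    """Low-count PSI rules in exact rational arithmetic."""
    if er >= 10:
        return ir / (ir + er)
    if ir >= 10:
        return float(math.ceil(Fraction(ir, ir + er) * 10)) / 10
    return math.nan


def brute_force_flatten(exons):
    """Per-base labelling then run-length segmentation into bins."""
    covered = set()
    boundaries = set()
    for s, e in exons:
        covered.update(range(s, e + 1))
        boundaries.add(s)
        boundaries.add(e + 1)
    bins, cur = [], None
    for pos in sorted(covered):
        if cur is None:
            cur = [pos, pos]
        elif pos == cur[1] + 1 and pos not in boundaries:
            cur[1] = pos
        else:
            bins.append(tuple(cur))
            cur = [pos, pos]
    if cur:
        bins.append(tuple(cur))
    return bins


def brute_force_filter(matrix, meta=None, spliceo=(), relaxed=False):
    """Row-by-row re-check of the filtering cascade predicates.

    Returns {bin_id: final row values} for the rows a correct cascade
    must retain (with imputed values for the relaxed variant).
    """
    selected = {}
    n = matrix.shape[1]
    thr = math.ceil(0.4 * n)
    spliceo = set(spliceo)
    for bin_id, row in matrix.iterrows():
        if relaxed:
            il = [s for s in matrix.columns
                  if meta.loc[s, "location"] == "ileum" and s not in spliceo]
            re_ = [s for s in matrix.columns
                   if meta.loc[s, "location"] == "rectum" and s not in spliceo]
            if spliceo and row[list(spliceo)].isna().any():
                continue
            if row[il].isna().sum() > 5 or row[re_].isna().sum() > 5:
                continue
            row = row.copy()
            row[il] = row[il].fillna(row[il].mean())
            row[re_] = row[re_].fillna(row[re_].mean())
            vals = row.to_numpy(dtype=float)
        else:
            vals = row.to_numpy(dtype=float)
            if np.isnan(vals).any():
                continue
        if (vals == 0).all() or (vals == 1).all():
            continue
        if (vals > 0.95).sum() >= thr or (vals < 0.05).sum() >= thr:
            continue
        selected[bin_id] = vals
    return selected


def brute_force_bh(pvals, q):
    """Benjamini-Hochberg step-up from its definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject[order[:k_max]] = True
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return reject, adj
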