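"""Synthetic paired-biopsy cohort generator with known ground truth.

The generator emulates a cohort of individuals with duplicate ileal and
rectal biopsies: bin-level true PSI with planted tissue-location and
ancestry effects, per-individual random intercepts on the logit-PSI
scale, negative-binomial junction coverage split binomially into
inclusion/exclusion reads, compartment-mixture gene expression, and
planted "spliceopathy" individuals whose ileal samples draw the rectal
true PSI at a subset of tissue-differential bins.

Genome layout.  All splice genes live on one synthetic chromosome.  A
gene with ``m`` variable bins alternates constitutive anchor exons with
variable exons (A0 V1 A1 V2 ... Vm Am); every exon is 100 bp and every
intron 200 bp.  Each variable exon receives two flanking inclusion
junctions (both carrying the inclusion count) and one skipping junction
from anchor to anchor (carrying the exclusion count), which makes the
junction -> bin assignment exactly invertible for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from psipath.config import COMPARTMENTS, SimConfig
from psipath.annotation import (
    ExonBin,
    bins_to_gtf,
    write_counts,
    write_metadata,
    write_sj_tab,
)

CHROM = "chrS"
EXON_LEN = 100
INTRON_LEN = 200
GENE_GAP = 10_000
VAR_BINS_PER_GENE = 5
PSI_CLIP = (0.001, 0.999)


# ---------------------------------------------------------------------------
# genome layout


def synthetic_layout(n_bins: int) -> tuple[list[ExonBin], list[str]]:
    """Lay out ``n_bins`` variable bins across genes on one chromosome.

    Returns all exonic bins (anchors and variable exons, as a flattened
    annotation would produce them) and the ordered ids of the variable
    bins, which are the quantification targets carrying simulated PSI.
    """
    all_bins: list[ExonBin] = []
    var_ids: list[str] = []
    remaining = n_bins
    gene_no = 0
    pos = 1
    while remaining > 0:
        gene_no += 1
        m = min(VAR_BINS_PER_GENE, remaining)
        remaining -= m
        gene_id = f"SG{gene_no:04d}"
        n_exons = 2 * m + 1
        for j in range(n_exons):
            start = pos + j * (EXON_LEN + INTRON_LEN)
            b = ExonBin(gene_id, j + 1, CHROM, start, start + EXON_LEN - 1, "+")
            all_bins.append(b)
            if j % 2 == 1:  # odd exon index -> variable exon
                var_ids.append(b.bin_id)
        pos += n_exons * (EXON_LEN + INTRON_LEN) + GENE_GAP
    return all_bins, var_ids


def _variable_bin_introns(all_bins: list[ExonBin], var_ids: list[str]) -> pd.DataFrame:
    """Upstream/downstream/skip intron coordinates per variable bin."""
    lookup = {b.bin_id: b for b in all_bins}
    rows = []
    for bid in var_ids:
        b = lookup[bid]
        rows.append(
            {
                "bin_id": bid,
                "up_start": b.start - INTRON_LEN,
                "up_end": b.start - 1,
                "down_start": b.end + 1,
                "down_end": b.end + INTRON_LEN,
            }
        )
    return pd.DataFrame(rows).set_index("bin_id")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class SimTruth:
    """Ground truth of a synthetic cohort, for recovery tests."""

    true_psi: pd.DataFrame  # bins x "tissue:ancestry" group columns
    sample_psi: pd.DataFrame  # bins x samples, the realized binomial parameter
    location_effect_bins: list[str]
    ancestry_effect_bins: list[str]
    spliceopathy_samples: list[str]
    spliceopathy_bins: list[str]
    compartment_proportions: pd.DataFrame  # samples x 3
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        blob = {
            "true_psi": self.true_psi.round(9).to_dict(orient="index"),
            "sample_psi": self.sample_psi.round(9).to_dict(orient="index"),
            "location_effect_bins": self.location_effect_bins,
            "ancestry_effect_bins": self.ancestry_effect_bins,
            "spliceopathy_samples": self.spliceopathy_samples,
            "spliceopathy_bins": self.spliceopathy_bins,
            "compartment_proportions": self.compartment_proportions.round(9).to_dict(
                orient="index"
            ),
            "marker_genes": self.marker_genes,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            true_psi=pd.DataFrame.from_dict(blob["true_psi"], orient="index"),
            sample_psi=pd.DataFrame.from_dict(blob["sample_psi"], orient="index"),
            location_effect_bins=blob["location_effect_bins"],
            ancestry_effect_bins=blob["ancestry_effect_bins"],
            spliceopathy_samples=blob["spliceopathy_samples"],
            spliceopathy_bins=blob["spliceopathy_bins"],
            compartment_proportions=pd.DataFrame.from_dict(
                blob["compartment_proportions"], orient="index"
            ),
            marker_genes=blob["marker_genes"],
        )


@dataclass
class Cohort:
    """In-memory synthetic cohort: inputs for every downstream stage."""

    config: SimConfig
    all_bins: list[ExonBin]
    var_bin_ids: list[str]
    junctions: dict[str, pd.DataFrame]  # sample -> junction table
    gene_counts: pd.DataFrame  # genes x samples
    meta: pd.DataFrame  # samples table, indexed by sample_id
    reference: pd.DataFrame  # genes x compartments, CPM
    truth: SimTruth


# ---------------------------------------------------------------------------
# sampling primitives


def simulate_bin_counts(
    psi_true: float, coverage: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (inclusion, exclusion) reads for one bin in one sample.

    IR ~ Binomial(coverage, psi_true); ER = coverage - IR.
    """
    if not 0.0 <= psi_true <= 1.0:
        raise ValueError(f"psi_true must be in [0, 1], got {psi_true}")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    ir = int(rng.binomial(coverage, psi_true))
    return ir, coverage - ir


def _draw_coverage(
    shape: tuple[int, ...], mean: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial coverage with mean ``mean`` and size ``dispersion``."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape)


# ---------------------------------------------------------------------------
# cohort assembly


def _assign_levels(
    ids: list[str], frac_first: float, levels: tuple[str, str], rng: np.random.Generator
) -> pd.Series:
    n_first = int(round(frac_first * len(ids)))
    labels = np.array([levels[0]] * n_first + [levels[1]] * (len(ids) - n_first))
    rng.shuffle(labels)
    return pd.Series(labels, index=ids)


def _build_meta(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    individuals = [f"IND{i + 1:02d}" for i in range(config.n_individuals)]
    ancestry = _assign_levels(individuals, config.ancestry_split, ("European", "African"), rng)
    disease = _assign_levels(individuals, config.disease_split, ("CD", "UC"), rng)
    status = _assign_levels(individuals, config.status_split, ("established", "diagnosis"), rng)
    spliceo_inds = sorted(
        rng.choice(individuals, size=config.n_spliceopathy_individuals, replace=False)
    )
    rows = []
    for ind in individuals:
        for tissue in config.tissues:
            keep = rng.random(config.replicates_per_tissue) >= config.missing_sample_rate
            if not keep.any():
                keep[0] = True  # every individual keeps >= 1 biopsy per location
            for rep in range(config.replicates_per_tissue):
                if not keep[rep]:
                    continue
                sid = f"{ind}_{tissue[0].upper()}{rep + 1}"
                group = (
                    "spliceopathy"
                    if (ind in spliceo_inds and tissue == "ileum")
                    else "differentiated"
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "individual_id": ind,
                        "location": tissue,
                        "ancestry": ancestry[ind],
                        "disease": disease[ind],
                        "status": status[ind],
                        "group_label": group,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _plant_true_psi(
    config: SimConfig, var_ids: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    n = len(var_ids)
    n_loc = int(round(config.frac_location_bins * n))
    n_anc = int(round(config.frac_ancestry_bins * n))
    n_spl = int(round(config.frac_spliceopathy_bins * n))
    n_spl = min(n_spl, n_loc)
    order = rng.permutation(n)
    loc_idx = order[:n_loc]
    anc_idx = order[n_loc : n_loc + n_anc]  # disjoint from location bins
    spl_idx = rng.choice(loc_idx, size=n_spl, replace=False) if n_spl else np.array([], int)

    base = rng.uniform(0.10, 0.90, size=n)
    loc_dir = rng.choice([-1.0, 1.0], size=n)
    anc_dir = rng.choice([-1.0, 1.0], size=n)
    # Re-draw baselines at effect bins so base + delta stays inside [0.05, 0.95].
    d_loc, d_anc = config.location_delta_psi, config.ancestry_delta_psi
    for idx, delta, direction in ((loc_idx, d_loc, loc_dir), (anc_idx, d_anc, anc_dir)):
        if len(idx) == 0 or delta == 0:
            continue
        lo = 0.05 + np.where(direction[idx] < 0, delta, 0.0)
        hi = 0.95 - np.where(direction[idx] > 0, delta, 0.0)
        base[idx] = rng.uniform(lo, hi)

    loc_effect = np.zeros(n)
    loc_effect[loc_idx] = d_loc * loc_dir[loc_idx]
    anc_effect = np.zeros(n)
    anc_effect[anc_idx] = d_anc * anc_dir[anc_idx]

    cols = {}
    for tissue in config.tissues:
        for anc in ("European", "African"):
            psi = base.copy()
            if tissue == config.tissues[1]:  # second tissue (rectum) carries the shift
                psi = psi + loc_effect
            if anc == "African":
                psi = psi + anc_effect
            cols[f"{tissue}:{anc}"] = np.clip(psi, *PSI_CLIP)
    true_psi = pd.DataFrame(cols, index=var_ids)
    as_ids = lambda idx: sorted(var_ids[i] for i in idx)
    return true_psi, as_ids(loc_idx), as_ids(anc_idx), as_ids(spl_idx)


def _sample_psi(
    config: SimConfig,
    true_psi: pd.DataFrame,
    meta: pd.DataFrame,
    spliceo_bins: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_bins = len(true_psi)
    individuals = sorted(meta["individual_id"].unique())
    ind_idx = {ind: i for i, ind in enumerate(individuals)}
    intercepts = (
        rng.normal(0.0, config.individual_sd, size=(len(individuals), n_bins))
        if config.individual_sd > 0
        else np.zeros((len(individuals), n_bins))
    )
    rectum = config.tissues[1]
    spl_mask = true_psi.index.isin(spliceo_bins)
    cols = {}
    for sid, row in meta.iterrows():
        g = true_psi[f"{row['location']}:{row['ancestry']}"].to_numpy().copy()
        if row["group_label"] == "spliceopathy":
            g[spl_mask] = true_psi.loc[spl_mask, f"{rectum}:{row['ancestry']}"]
        if config.individual_sd > 0:
            u = intercepts[ind_idx[row["individual_id"]]]
            g = np.clip(expit(logit(g) + u), *PSI_CLIP)
        cols[sid] = g
    return pd.DataFrame(cols, index=true_psi.index)


def _junction_tables(
    all_bins: list[ExonBin],
    var_ids: list[str],
    ir: np.ndarray,
    er: np.ndarray,
    samples: list[str],
) -> dict[str, pd.DataFrame]:
    introns = _variable_bin_introns(all_bins, var_ids)
    up = introns[["up_start", "up_end"]].to_numpy()
    down = introns[["down_start", "down_end"]].to_numpy()
    skip = np.column_stack([introns["up_start"], introns["down_end"]])
    starts = np.concatenate([up[:, 0], down[:, 0], skip[:, 0]])
    ends = np.concatenate([up[:, 1], down[:, 1], skip[:, 1]])
    out = {}
    for j, sid in enumerate(samples):
        reads = np.concatenate([ir[:, j], ir[:, j], er[:, j]])
        keep = reads > 0
        df = pd.DataFrame(
            {
                "chrom": CHROM,
                "intron_start": starts[keep],
                "intron_end": ends[keep],
                "strand_code": 1,
                "unique_reads": reads[keep],
            }
        ).sort_values(["intron_start", "intron_end"], kind="mergesort")
        out[sid] = df.reset_index(drop=True)
    return out


def _marker_block_size(n_genes: int) -> int:
    return max(2, round(0.125 * n_genes))


def _build_reference(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Cell-type reference CPM table with disjoint planted marker blocks."""
    n = config.n_genes
    k = _marker_block_size(n)
    if 3 * k >= n:
        raise ValueError(f"n_genes={n} too small for three marker blocks of {k}")
    genes = [f"EXG{i + 1:04d}" for i in range(n)]
    ref = np.empty((n, 3))
    markers: dict[str, list[str]] = {}
    for c in range(3):
        block = slice(c * k, (c + 1) * k)
        for cc in range(3):
            if cc == c:
                ref[block, cc] = rng.uniform(50, 500, size=k)
            else:
                ref[block, cc] = rng.uniform(0.05, 0.5, size=k)
        markers[COMPARTMENTS[c]] = genes[c * k : (c + 1) * k]
    bg = slice(3 * k, n)
    n_bg = n - 3 * k
    base = rng.uniform(20, 100, size=n_bg)
    for cc in range(3):
        ref[bg, cc] = base * rng.uniform(0.8, 1.25, size=n_bg)
    return pd.DataFrame(ref, index=genes, columns=list(COMPARTMENTS)), markers


def _gene_counts(
    config: SimConfig,
    reference: pd.DataFrame,
    meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compartment-mixture expression with log-normal noise, as counts."""
    baselines = {t: np.asarray(p) for t, p in config.compartment_baselines.items()}
    props = {}
    for sid, row in meta.iterrows():
        b = baselines[row["location"]]
        if row["group_label"] == "spliceopathy":
            # intermediate gene expression: proportions between the tissues
            b = 0.5 * (baselines[config.tissues[0]] + baselines[config.tissues[1]])
        props[sid] = rng.dirichlet(b * 100.0)
    prop_df = pd.DataFrame(props, index=list(COMPARTMENTS)).T
    S = reference.to_numpy()
    counts = {}
    for sid in meta.index:
        expected = S @ prop_df.loc[sid].to_numpy()
        noisy = expected * rng.lognormal(0.0, 0.2, size=len(expected))
        lib = rng.uniform(150_000, 250_000)
        counts[sid] = rng.poisson(noisy / noisy.sum() * lib)
    return pd.DataFrame(counts, index=reference.index), prop_df


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort with ground truth.

    Returns junction tables per sample, a gene count matrix, the samples
    metadata table, a cell-type reference CPM table, and a
    :class:`SimTruth` recording every planted effect.  Fixing
    ``config.seed`` makes the output reproducible bit for bit.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    all_bins, var_ids = synthetic_layout(config.n_bins)
    meta = _build_meta(config, rng)
    true_psi, loc_bins, anc_bins, spl_bins = _plant_true_psi(config, var_ids, rng)
    sample_psi = _sample_psi(config, true_psi, meta, spl_bins, rng)
    samples = list(meta.index)
    coverage = _draw_coverage(
        (len(var_ids), len(samples)), config.coverage_mean, config.coverage_dispersion, rng
    )
    ir = rng.binomial(coverage, sample_psi.to_numpy())
    er = coverage - ir
    junctions = _junction_tables(all_bins, var_ids, ir, er, samples)
    reference, markers = _build_reference(config, rng)
    gene_counts, prop_df = _gene_counts(config, reference, meta, rng)
    spliceo_samples = sorted(meta.index[meta["group_label"] == "spliceopathy"])
    truth = SimTruth(
        true_psi=true_psi,
        sample_psi=sample_psi,
        location_effect_bins=loc_bins,
        ancestry_effect_bins=anc_bins,
        spliceopathy_samples=spliceo_samples,
        spliceopathy_bins=spl_bins,
        compartment_proportions=prop_df,
        marker_genes=markers,
    )
    return Cohort(
        config=config,
        all_bins=all_bins,
        var_bin_ids=var_ids,
        junctions=junctions,
        gene_counts=gene_counts,
        meta=meta,
        reference=reference,
        truth=truth,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Serialize a cohort: SJ files, TSV matrices, GTF, and truth JSON."""
    outdir = Path(outdir)
    (outdir / "sj").mkdir(parents=True, exist_ok=True)
    for sid, junc in cohort.junctions.items():
        write_sj_tab(junc, outdir / "sj" / f"{sid}.SJ.out.tab")
    write_counts(cohort.gene_counts, outdir / "counts.tsv")
    write_metadata(cohort.meta, outdir / "metadata.tsv")
    cohort.reference.round(6).to_csv(outdir / "reference_cpm.tsv", sep="\t", index_label="gene_id")
    bins_to_gtf(cohort.all_bins, outdir / "annotation.gtf")
    cohort.truth.to_json(outdir / "truth.json")
    cohort.config and (outdir / "sim_config.json").write_text(
        json.dumps(cohort.config.to_dict(), sort_keys=True, indent=1)
    )
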