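"""End-to-end orchestration: simulate -> psi -> filter -> pcva -> diff ->
compartments -> spliceopathy, with file-based handoff between stages.

Stages communicate exclusively through TSV/JSON files in the run
directory, so every stage is independently inspectable and resumable.
A manifest records the configuration hash, seed, package versions and
the SHA-256 of every output file; identical config + seed reproduces
identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import psipath
from psipath.config import PipelineConfig
from psipath.annotation import (
    flatten_gtf,
    read_counts,
    read_metadata,
    read_psi_matrix,
    read_sj_tab,
    validate_samples,
    write_psi_matrix,
)
from psipath.simulate import simulate_cohort, write_cohort
from psipath.psi import quantify_samples
from psipath import filters
from psipath.pcva import log_cpm, pcva, run_pca
from psipath.diff_splice import fdr_adjust, fit_all_bins, fit_group_all
from psipath.compartments import build_marker_sets, score_samples
from psipath import outliers

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the failing stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise PipelineError(f"stage '{stage}': missing inputs {missing}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(config.data_dir) if config.data_dir else out / "cohort"

    if "simulate" not in config.stages:
        _require("inputs", data / "metadata.tsv", data / "annotation.gtf")

    adjusted = {}
    for stage in config.stages:
        try:
            _run_stage(stage, config, out, data)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        adjusted[stage] = True

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages_run": list(adjusted),
        "versions": {
            "psipath": psipath.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _run_stage(stage: str, config: PipelineConfig, out: Path, data: Path) -> None:
    logger.info("=== stage %s ===", stage)
    if stage == "simulate":
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, data)
    elif stage == "psi":
        _require(stage, data / "annotation.gtf", data / "sj")
        bins = flatten_gtf(data / "annotation.gtf")
        tables = {
            p.name.replace(".SJ.out.tab", ""): read_sj_tab(
                p, min_unique=config.min_unique_reads
            )
            for p in sorted((data / "sj").glob("*.SJ.out.tab"))
        }
        if not tables:
            raise PipelineError(f"stage 'psi': no SJ files under {data / 'sj'}")
        matrix, audit = quantify_samples(
            tables, bins, ir_mode=config.ir_mode, min_unique=config.min_unique_reads
        )
        write_psi_matrix(matrix, out / "psi_matrix.tsv")
        audit.to_csv(out / "psi_counts_audit.tsv", sep="\t", index=False)
    elif stage == "filter":
        _require(stage, out / "psi_matrix.tsv", data / "metadata.tsv")
        matrix = read_psi_matrix(out / "psi_matrix.tsv")
        meta = read_metadata(data / "metadata.tsv")
        validate_samples(matrix, meta)
        kw = dict(
            frac=config.constitutive_frac,
            hi=config.constitutive_hi,
            lo=config.constitutive_lo,
            rule=config.constitutive_rule,
            boundary=config.constitutive_boundary,
        )
        filtered, reports = filters.strict_cascade(matrix, **kw)
        write_psi_matrix(filtered, out / "psi_filtered.tsv")
        filters.reports_to_json(reports, out / "cascade_report.json")
        spliceo = meta.index[meta["group_label"] == "spliceopathy"].tolist()
        if spliceo:
            relaxed, rel_reports = filters.relaxed_filter_spliceopathy(
                matrix, meta, spliceo, **kw
            )
            write_psi_matrix(relaxed, out / "psi_relaxed.tsv")
            filters.reports_to_json(rel_reports, out / "relaxed_report.json")
    elif stage == "pcva":
        _require(stage, out / "psi_filtered.tsv", data / "counts.tsv", data / "metadata.tsv")
        meta = read_metadata(data / "metadata.tsv")
        norm = log_cpm(read_counts(data / "counts.tsv"))
        for name, matrix in (
            ("expression", norm),
            ("psi", read_psi_matrix(out / "psi_filtered.tsv")),
        ):
            scores, frac = run_pca(matrix)
            decomp = pcva(scores, frac, meta)
            scores.to_csv(out / f"{name}_pcs.tsv", sep="\t", index_label="sample_id")
            decomp.to_table().to_csv(out / f"{name}_pcva.tsv", sep="\t", index=False)
    elif stage == "diff":
        _require(stage, out / "psi_filtered.tsv", data / "metadata.tsv")
        matrix = read_psi_matrix(out / "psi_filtered.tsv")
        meta = read_metadata(data / "metadata.tsv")
        results = fit_all_bins(matrix, meta, test=config.lmm_test)
        results["p_adjusted"] = np.nan
        results["significant"] = False
        for term, idx in results.groupby("term").groups.items():
            rej, adj = fdr_adjust(results.loc[idx, "pvalue"], q=config.fdr_q)
            results.loc[idx, "p_adjusted"] = adj
            results.loc[idx, "significant"] = rej
        results.to_csv(out / "diff_results.tsv", sep="\t", index=False)
    elif stage == "compartments":
        _require(stage, data / "counts.tsv", data / "reference_cpm.tsv")
        reference = pd.read_csv(data / "reference_cpm.tsv", sep="\t", index_col=0)
        markers = build_marker_sets(reference)
        norm = log_cpm(read_counts(data / "counts.tsv"))
        scores = score_samples(norm, markers)
        scores.to_csv(out / "compartment_scores.tsv", sep="\t", index_label="sample_id")
        with open(out / "marker_sets.json", "w") as fh:
            json.dump({c: list(m.genes) for c, m in markers.items()}, fh, indent=1)
    elif stage == "spliceopathy":
        _require(
            stage, out / "psi_filtered.tsv", out / "diff_results.tsv", data / "metadata.tsv"
        )
        matrix = read_psi_matrix(out / "psi_filtered.tsv")
        meta = read_metadata(data / "metadata.tsv")
        calls = outliers.detect_discordant_samples(
            matrix, meta, n_pcs=config.outlier_n_pcs, threshold=config.outlier_threshold
        )
        calls.to_csv(out / "outlier_calls.tsv", sep="\t", index_label="sample_id")

        results = pd.read_csv(out / "diff_results.tsv", sep="\t")
        loc_sig = set(
            results.loc[(results["term"] == "location") & results["significant"], "bin_id"]
        )
        k = min(config.heatmap_k, (results["term"] == "location").sum())
        top = outliers.select_top_location_bins(results, k=k)
        cl = outliers.heatmap_cluster(matrix, top)
        pd.DataFrame({"bin_id": cl.row_order}).to_csv(
            out / "heatmap_row_order.tsv", sep="\t", index=False
        )
        pd.DataFrame({"sample_id": cl.col_order}).to_csv(
            out / "heatmap_col_order.tsv", sep="\t", index=False
        )

        relaxed_path = out / "psi_relaxed.tsv"
        if relaxed_path.exists():
            relaxed = read_psi_matrix(relaxed_path)
            gres = fit_group_all(relaxed, meta)
            gres["p_adjusted"] = np.nan
            gres["significant"] = False
            for term, idx in gres.groupby("term").groups.items():
                rej, adj = fdr_adjust(gres.loc[idx, "pvalue"], q=config.fdr_q)
                gres.loc[idx, "p_adjusted"] = adj
                gres.loc[idx, "significant"] = rej
            gres.to_csv(out / "group_results.tsv", sep="\t", index=False)
            spl_sig = set(
                gres.loc[
                    (gres["term"] == "spliceopathy_vs_ileum") & gres["significant"],
                    "bin_id",
                ]
            )
            sites = sorted(outliers.rectal_like_sites(spl_sig, loc_sig))
            (out / "rectal_like_sites.txt").write_text("\n".join(sites) + "\n")
            if len(sites) >= 2:
                assign = outliers.classify_on_sites(relaxed.loc[sites], meta)
                assign.to_csv(out / "site_classification.tsv", sep="\t", index_label="sample_id")

            groups = {
                "ileum": meta.index[
                    (meta["location"] == "ileum") & (meta["group_label"] != "spliceopathy")
                ].tolist(),
                "rectum": meta.index[meta["location"] == "rectum"].tolist(),
                "spliceopathy": meta.index[meta["group_label"] == "spliceopathy"].tolist(),
            }
            profiles = []
            for a, b in (
                ("ileum", "rectum"),
                ("spliceopathy", "ileum"),
                ("spliceopathy", "rectum"),
            ):
                if groups[a] and groups[b]:
                    prof = outliers.delta_psi_profile(
                        matrix, groups[a], groups[b], label=f"{a}_vs_{b}"
                    )
                    for lo, p in zip(prof.edges[:-1], prof.proportions):
                        profiles.append(
                            {"comparison": prof.label, "bin_lo": lo, "proportion": p}
                        )
            pd.DataFrame(profiles).to_csv(out / "delta_psi_profiles.tsv", sep="\t", index=False)
    else:  # pragma: no cover - PipelineConfig already validates
        raise PipelineError(f"unknown stage '{stage}'")
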