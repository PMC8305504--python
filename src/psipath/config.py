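"""Configuration objects for the synthetic cohort and the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Any

import yaml

#: Tissue-compartment labels used throughout (order matters for tables).
COMPARTMENTS = ("epithelial", "immune", "fibroblast")


def _check_prop(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic paired-biopsy cohort.

    The defaults describe the study design the generator emulates: 34
    individuals with paired ileal and rectal biopsies in duplicate, a
    fraction of samples lost to quality control, two ancestry groups and
    two disease subtypes, bin-level true PSI with planted tissue and
    ancestry effects, per-individual random intercepts on the logit-PSI
    scale, negative-binomial junction coverage, and a small number of
    "spliceopathy" individuals whose ileal samples carry the rectal PSI
    at a subset of tissue-differential bins.
    """

    n_individuals: int = 34
    ancestry_split: float = 18 / 34  # fraction European (rest African)
    disease_split: float = 20 / 34  # fraction Crohn's disease (rest UC)
    status_split: float = 20 / 34  # fraction established (rest at diagnosis)
    tissues: tuple[str, ...] = ("ileum", "rectum")
    replicates_per_tissue: int = 2
    missing_sample_rate: float = 0.125
    n_bins: int = 300
    n_genes: int = 120
    frac_location_bins: float = 0.06
    location_delta_psi: float = 0.25
    frac_ancestry_bins: float = 0.03
    ancestry_delta_psi: float = 0.10
    individual_sd: float = 0.2  # SD of per-individual intercepts, logit-PSI scale
    coverage_mean: float = 170.0  # mean informative junction reads per bin
    coverage_dispersion: float = 5.0  # NB size parameter r (var = m + m^2/r)
    n_spliceopathy_individuals: int = 2
    frac_spliceopathy_bins: float = 0.05
    compartment_baselines: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ileum": (0.60, 0.25, 0.15),
            "rectum": (0.45, 0.35, 0.20),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ancestry_split",
            "disease_split",
            "status_split",
            "missing_sample_rate",
            "frac_location_bins",
            "location_delta_psi",
            "frac_ancestry_bins",
            "ancestry_delta_psi",
            "frac_spliceopathy_bins",
        ):
            _check_prop(name, getattr(self, name))
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates_per_tissue < 1:
            raise ValueError("replicates_per_tissue must be >= 1")
        if len(self.tissues) != 2:
            raise ValueError("exactly two tissue locations are supported")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.n_spliceopathy_individuals >= self.n_individuals:
            raise ValueError(
                "n_spliceopathy_individuals must be smaller than n_individuals"
            )
        if self.n_spliceopathy_individuals < 0:
            raise ValueError("n_spliceopathy_individuals must be >= 0")
        # Discordant bins are drawn among the tissue-differential bins: a
        # rectal PSI draw at a bin with no tissue difference is a no-op.
        if self.frac_spliceopathy_bins > self.frac_location_bins:
            raise ValueError(
                "frac_spliceopathy_bins cannot exceed frac_location_bins "
                "(spliceopathy bins are drawn among location-effect bins)"
            )
        self.tissues = tuple(self.tissues)
        for tissue in self.tissues:
            if tissue not in self.compartment_baselines:
                raise ValueError(f"compartment_baselines missing tissue {tissue!r}")
            props = tuple(self.compartment_baselines[tissue])
            if len(props) != len(COMPARTMENTS):
                raise ValueError("compartment baselines must have three entries")
            if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(
                    f"compartment proportions for {tissue!r} must be >= 0 and sum to 1"
                )
            self.compartment_baselines[tissue] = props

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["compartment_baselines"] = {
            k: list(v) for k, v in self.compartment_baselines.items()
        }
        return d


@dataclass
class PipelineConfig:
    """End-to-end run configuration (all module switches in one place)."""

    out_dir: str = "psipath_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "psi",
        "filter",
        "pcva",
        "diff",
        "compartments",
        "spliceopathy",
    )
    data_dir: str | None = None  # existing cohort directory; required unless simulating
    sim: SimConfig = field(default_factory=SimConfig)
    ir_mode: str = "mean"  # how flank inclusion counts combine: mean | sum
    min_unique_reads: int = 5
    constitutive_frac: float = 0.40
    constitutive_hi: float = 0.95
    constitutive_lo: float = 0.05
    constitutive_rule: str = "per_direction"  # per_direction | combined
    constitutive_boundary: str = "ge"  # ge | gt against ceil(frac * n)
    fdr_q: float = 0.05
    lmm_test: str = "lrt"  # lrt | wald
    outlier_threshold: float = 1.0
    outlier_n_pcs: int = 2
    heatmap_k: int = 50

    _KNOWN_STAGES = (
        "simulate",
        "psi",
        "filter",
        "pcva",
        "diff",
        "compartments",
        "spliceopathy",
    )

    def __post_init__(self) -> None:
        if self.ir_mode not in ("mean", "sum"):
            raise ValueError("ir_mode must be 'mean' or 'sum'")
        if self.constitutive_rule not in ("per_direction", "combined"):
            raise ValueError("constitutive_rule must be 'per_direction' or 'combined'")
        if self.constitutive_boundary not in ("ge", "gt"):
            raise ValueError("constitutive_boundary must be 'ge' or 'gt'")
        if self.lmm_test not in ("lrt", "wald"):
            raise ValueError("lmm_test must be 'lrt' or 'wald'")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        self.stages = tuple(self.stages)
        unknown = [s for s in self.stages if s not in self._KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if "simulate" not in self.stages and self.data_dir is None:
            raise ValueError("data_dir is required when the simulate stage is omitted")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = SimConfig.from_dict(data["sim"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["sim"] = self.sim.to_dict()
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
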