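"""Configuration objects for the synthetic-data generators and the pipeline.

``SyntheticConfig`` holds every planted quantity of the simulated study:
the sizes of the differentially-expressed gene sets under driver knock-down
(KD) and overexpression (OVX), the sizes of each stage of the miRNA-layer
selection cascade, and the effect sizes (Spearman rho, hazard ratio) planted
into the synthetic patient cohorts.  ``PAPER_SCALE`` is the preset matching
the published scale of the NEAT1-driven network in multiple myeloma:
515 KD DEGs (108 up / 407 down), 1256 OVX DEGs (641 up / 615 down),
40 candidate targets, 445 target-binding miRNAs, 491 driver-binding miRNAs,
218 in their intersection, 96 passing the plasma-cell expression filter, and
a 137-node / 1152-edge bipartite network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["SyntheticConfig", "PAPER_SCALE", "PipelineConfig"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted ground truth for one synthetic study.

    All counts are exact: the generators guarantee that recomputing each
    quantity downstream recovers the configured value, for any seed.
    """

    n_genes: int = 20000
    n_mirnas: int = 1200
    # planted DEG counts per contrast
    n_kd_up: int = 108
    n_kd_down: int = 407
    n_ovx_up: int = 641
    n_ovx_down: int = 615
    # selection cascade sizes
    n_candidates: int = 40
    n_target_binders: int = 445
    n_driver_binders: int = 491
    n_intersection: int = 218
    n_expressed: int = 96
    n_mt_edges: int = 1056
    # miRNA expression-matrix sample groups (N / MM / PCL)
    n_samples_n: int = 4
    n_samples_mm: int = 113
    n_samples_pcl: int = 30
    # cohort structure
    cohort_n: int = 753
    rho_planted: float = 0.4
    hr_planted: float = 2.5
    fdr_alpha: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.n_samples_n + self.n_samples_mm + self.n_samples_pcl

    def validate(self) -> None:
        """Raise ``ValueError`` on any infeasible planted configuration."""
        c = self
        counts = {
            k: getattr(c, k)
            for k in (
                "n_genes", "n_mirnas", "n_kd_up", "n_kd_down", "n_ovx_up",
                "n_ovx_down", "n_candidates", "n_target_binders",
                "n_driver_binders", "n_intersection", "n_expressed",
                "n_mt_edges", "n_samples_n", "n_samples_mm", "n_samples_pcl",
                "cohort_n",
            )
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not 0.0 < c.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1), got {c.fdr_alpha}")
        if not -1.0 <= c.rho_planted <= 1.0:
            raise ValueError(f"rho_planted must lie in [-1, 1], got {c.rho_planted}")
        if c.hr_planted <= 0:
            raise ValueError(f"hr_planted must be positive, got {c.hr_planted}")
        if c.n_candidates > min(c.n_kd_down, c.n_ovx_up):
            raise ValueError(
                "n_candidates exceeds min(n_kd_down, n_ovx_up): "
                f"{c.n_candidates} > min({c.n_kd_down}, {c.n_ovx_up})"
            )
        if c.n_intersection > min(c.n_target_binders, c.n_driver_binders):
            raise ValueError(
                "n_intersection exceeds min(n_target_binders, n_driver_binders)"
            )
        if c.n_expressed > c.n_intersection:
            raise ValueError(
                f"n_expressed ({c.n_expressed}) exceeds n_intersection "
                f"({c.n_intersection})"
            )
        if c.n_expressed > 0 and c.n_candidates > 0:
            if c.n_mt_edges < max(c.n_expressed, c.n_candidates):
                raise ValueError(
                    "n_mt_edges cannot cover every selected node: "
                    f"{c.n_mt_edges} < max({c.n_expressed}, {c.n_candidates})"
                )
            if c.n_mt_edges > c.n_expressed * c.n_candidates:
                raise ValueError(
                    "n_mt_edges exceeds the expressed-miRNA x candidate grid"
                )
        # the DE planting uses disjoint blocks for the two contrasts
        needed = (
            c.n_candidates
            + c.n_kd_up
            + (c.n_kd_down - c.n_candidates)
            + (c.n_ovx_up - c.n_candidates)
            + c.n_ovx_down
        )
        if needed > c.n_genes:
            raise ValueError(
                f"gene universe too small: need >= {needed}, have {c.n_genes}"
            )
        n_mirnas_needed = c.n_target_binders + c.n_driver_binders - c.n_intersection
        if n_mirnas_needed > c.n_mirnas:
            raise ValueError(
                f"miRNA universe too small: need >= {n_mirnas_needed}, "
                f"have {c.n_mirnas}"
            )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


#: Preset matching the published scale of the study (all cascade counts and
#: the 4+113+30-sample miRNA array layout).  137 nodes = 1 driver + 96 miRNAs
#: + 40 targets; 1152 edges = 1056 miRNA-target + 96 driver-miRNA.
PAPER_SCALE = SyntheticConfig()

assert PAPER_SCALE.n_expressed + PAPER_SCALE.n_mt_edges == 1152


@dataclass
class PipelineConfig:
    """File paths and thresholds for one end-to-end pipeline run."""

    de_kd: str = ""
    de_ovx: str = ""
    interactions: str = ""
    driver_binders: str = ""
    mirna_expression: str = ""
    mirna_groups: str = ""
    cohort_expression: str = ""
    cohort_survival: str = ""
    gene_sets: str = ""
    ranked_lists: dict = field(default_factory=dict)  # condition -> TSV path
    condition_direction: dict = field(default_factory=dict)  # condition -> +1/-1
    driver_id: str = "NEAT1"
    fdr_alpha: float = 0.05
    log2_threshold: float = 4.0
    min_samples: int = 10
    nes_threshold: float = 1.5
    padj_threshold: float = 0.05
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    n_perm: int = 1000
    seed: int = 17
    outdir: str = "cernanet_out"

    def validate(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must lie in (0, 1)")
        if self.nes_threshold < 0:
            raise ValueError("nes_threshold must be non-negative")
        if self.min_samples < 1:
            raise ValueError("min_samples must be at least 1")
        if not 1 <= self.gsea_min_size <= self.gsea_max_size:
            raise ValueError("gene-set size bounds must satisfy 1 <= min <= max")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        cfg = cls(**data)
        cfg.validate()
        return cfg
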