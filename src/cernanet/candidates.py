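"""Dual-condition candidate selection from paired perturbation DE tables.

The driver lncRNA is silenced in one experiment (KD) and activated in the
other (OVX).  A gene behaving as a ceRNA partner of the driver should move
with it: down when the driver is down, up when the driver is up.  The
selection filter therefore intersects the two differential-expression
tables and keeps genes significantly down in KD and significantly up in
OVX, both at FDR < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["DETable", "CandidateSet", "summarize_degs", "select_candidates"]

DE_COLUMNS = ["gene_id", "log2fc", "pvalue", "fdr"]


@dataclass
class DETable:
    """Per-gene differential-expression statistics for one contrast.

    ``data`` has columns gene_id, log2fc, pvalue, fdr; gene_id is unique.
    """

    data: pd.DataFrame
    contrast_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"DETable missing columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in DE table: {list(dupes[:5])}")
        for col in ("pvalue", "fdr"):
            v = self.data[col]
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def read_tsv(cls, path: str | Path, contrast_label: str = "") -> "DETable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        return cls(df[DE_COLUMNS].copy(), contrast_label or Path(path).stem)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class CandidateSet:
    """Genes down in KD and up in OVX, with the supporting statistics.

    ``evidence`` is indexed by gene_id (lexicographic order) with columns
    kd_log2fc, kd_fdr, ovx_log2fc, ovx_fdr.
    """

    evidence: pd.DataFrame
    alpha: float = 0.05

    @property
    def gene_ids(self) -> list[str]:
        return list(self.evidence.index)

    def __len__(self) -> int:
        return len(self.evidence)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.evidence.index

    def write_tsv(self, path: str | Path) -> None:
        self.evidence.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path: str | Path, alpha: float = 0.05) -> "CandidateSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
        return cls(df, alpha=alpha)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


def summarize_degs(de: DETable, alpha: float = 0.05) -> tuple[int, int]:
    """Count significant up- and downregulated genes at FDR < alpha.

    Genes with log2fc exactly 0 count in neither direction.
    """
    _check_alpha(alpha)
    sig = de.data["fdr"] < alpha
    n_up = int((sig & (de.data["log2fc"] > 0)).sum())
    n_down = int((sig & (de.data["log2fc"] < 0)).sum())
    return n_up, n_down


def select_candidates(
    de_kd: DETable, de_ovx: DETable, alpha: float = 0.05
) -> CandidateSet:
    """Intersect the two contrasts under the dual sign/significance criterion.

    Keeps genes present in both tables with kd_fdr < alpha, kd_log2fc < 0,
    ovx_fdr < alpha and ovx_log2fc > 0 (all strict).  Genes measured in only
    one table are excluded; disjoint gene namespaces raise, as that almost
    always signals an identifier-convention mismatch.
    """
    _check_alpha(alpha)
    if len(de_kd) == 0 or len(de_ovx) == 0:
        raise ValueError("both DE tables must be nonempty")
    kd = de_kd.data.set_index("gene_id")
    ovx = de_ovx.data.set_index("gene_id")
    shared = kd.index.intersection(ovx.index)
    if len(shared) == 0:
        raise ValueError(
            "gene-id namespaces of the two DE tables are disjoint; "
            "check identifier conventions"
        )
    kd = kd.loc[shared]
    ovx = ovx.loc[shared]
    keep = (
        (kd["fdr"] < alpha)
        & (kd["log2fc"] < 0)
        & (ovx["fdr"] < alpha)
        & (ovx["log2fc"] > 0)
    )
    genes = sorted(shared[keep])
    evidence = pd.DataFrame(
        {
            "kd_log2fc": kd.loc[genes, "log2fc"],
            "kd_fdr": kd.loc[genes, "fdr"],
            "ovx_log2fc": ovx.loc[genes, "log2fc"],
            "ovx_fdr": ovx.loc[genes, "fdr"],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return CandidateSet(evidence, alpha=alpha)
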