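"""miRNA-layer intersection, expression filtering and bipartite network assembly.

The ceRNA hypothesis requires a shared miRNA pool: a miRNA belongs in the
network only if it (a) has supported interactions with at least one selected
target mRNA, (b) binds the driver lncRNA, and (c) is actually expressed in
the tissue of interest.  The surviving miRNAs and targets form a tripartite
star-plus-bipartite graph: one driver node wired to every miRNA, and
miRNA-target edges carrying the interaction evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .candidates import CandidateSet

__all__ = [
    "InteractionDB",
    "MiRNAExpressionMatrix",
    "CeRNANetwork",
    "mirnas_targeting",
    "intersect_driver_binders",
    "filter_expressed",
    "assemble_network",
    "extract_subnetwork",
]

logger = logging.getLogger(__name__)


@dataclass
class InteractionDB:
    """Supported miRNA->gene pairs plus the driver-binding miRNA list.

    ``mt_pairs`` maps (mirna_id, gene_id) -> evidence tag; identifiers are
    matched exact-string after whitespace trimming.
    """

    mt_pairs: dict[tuple[str, str], str]
    driver_binders: set[str]

    def __post_init__(self) -> None:
        cleaned: dict[tuple[str, str], str] = {}
        for (m, g), ev in self.mt_pairs.items():
            m, g = m.strip(), g.strip()
            if not m or not g:
                raise ValueError("empty identifier in interaction pair")
            cleaned[(m, g)] = ev
        self.mt_pairs = cleaned
        self.driver_binders = {m.strip() for m in self.driver_binders}
        if any(not m for m in self.driver_binders):
            raise ValueError("empty identifier in driver-binder list")

    @classmethod
    def read_tsv(
        cls, pairs_path: str | Path, binders_path: str | Path
    ) -> "InteractionDB":
        df = pd.read_csv(pairs_path, sep="\t", dtype=str)
        pairs = {
            (r.mirna_id, r.gene_id): getattr(r, "evidence", "")
            for r in df.itertuples()
        }
        binders = {
            line.strip()
            for line in Path(binders_path).read_text().splitlines()
            if line.strip()
        }
        return cls(pairs, binders)

    def write_tsv(self, pairs_path: str | Path, binders_path: str | Path) -> None:
        rows = sorted((m, g, ev) for (m, g), ev in self.mt_pairs.items())
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence"]).to_csv(
            pairs_path, sep="\t", index=False
        )
        Path(binders_path).write_text(
            "\n".join(sorted(self.driver_binders)) + "\n"
        )


@dataclass
class MiRNAExpressionMatrix:
    """miRNA x sample matrix of log2 expression with N/MM/PCL group labels."""

    values: pd.DataFrame  # index: mirna_id, columns: sample ids
    sample_groups: pd.Series  # index: sample ids, values in {N, MM, PCL}

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unlabeled = self.values.columns.difference(self.sample_groups.index)
        if len(unlabeled):
            raise ValueError(f"samples without group label: {list(unlabeled[:5])}")

    @classmethod
    def read_tsv(
        cls, values_path: str | Path, groups_path: str | Path
    ) -> "MiRNAExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(values, groups)

    def write_tsv(self, values_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="mirna_id")
        self.sample_groups.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample_id"
        )


@dataclass
class CeRNANetwork:
    """Typed bipartite sponge network: driver -- miRNAs -- targets."""

    driver: str
    mirna_nodes: set[str]
    target_nodes: set[str]
    mt_edges: set[tuple[str, str]]  # (mirna, target)
    driver_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.driver_edges:
            self.driver_edges = {(self.driver, m) for m in sorted(self.mirna_nodes)}
        self.validate()

    def validate(self) -> None:
        for m, t in self.mt_edges:
            if m not in self.mirna_nodes or t not in self.target_nodes:
                raise ValueError(f"edge ({m}, {t}) has an undeclared endpoint")
        wired = {m for m, _ in self.mt_edges}
        if wired != self.mirna_nodes:
            raise ValueError("every miRNA node needs at least one target edge")
        if self.driver_edges != {(self.driver, m) for m in self.mirna_nodes}:
            raise ValueError("every miRNA node needs exactly one driver edge")

    @property
    def n_nodes(self) -> int:
        return 1 + len(self.mirna_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.mt_edges) + len(self.driver_edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_node(self.driver, kind="driver")
        g.add_nodes_from(sorted(self.mirna_nodes), kind="mirna")
        g.add_nodes_from(sorted(self.target_nodes), kind="target")
        g.add_edges_from(sorted(self.driver_edges), edge_type="driver_mirna")
        g.add_edges_from(sorted(self.mt_edges), edge_type="mirna_target")
        return g

    def write_edgelist(self, path: str | Path) -> None:
        rows = [(d, m, "driver_mirna") for d, m in sorted(self.driver_edges)]
        rows += [(m, t, "mirna_target") for m, t in sorted(self.mt_edges)]
        pd.DataFrame(rows, columns=["source", "target", "edge_type"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_edgelist(cls, path: str | Path) -> "CeRNANetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        drv = df[df.edge_type == "driver_mirna"]
        mt = df[df.edge_type == "mirna_target"]
        drivers = set(drv.source)
        if len(drivers) != 1:
            raise ValueError(f"edge list must name exactly one driver, got {drivers}")
        return cls(
            driver=next(iter(drivers)),
            mirna_nodes=set(mt.source),
            target_nodes=set(mt.target),
            mt_edges=set(zip(mt.source, mt.target)),
            driver_edges=set(zip(drv.source, drv.target)),
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _as_gene_set(candidates: CandidateSet | set[str]) -> set[str]:
    if isinstance(candidates, CandidateSet):
        return set(candidates.gene_ids)
    return set(candidates)


def mirnas_targeting(
    db: InteractionDB, candidates: CandidateSet | set[str]
) -> set[str]:
    """miRNAs with at least one supported interaction to a candidate gene."""
    genes = _as_gene_set(candidates)
    if not genes:
        raise ValueError("candidate set is empty")
    return {m for (m, g) in db.mt_pairs if g in genes}


def intersect_driver_binders(
    target_binders: set[str], db: InteractionDB
) -> set[str]:
    """miRNAs that both target a candidate and bind the driver lncRNA."""
    return set(target_binders) & db.driver_binders


def filter_expressed(
    mirnas: set[str],
    expr: MiRNAExpressionMatrix,
    log2_threshold: float = 4.0,
    min_samples: int = 10,
) -> set[str]:
    """Keep miRNAs with log2 expression strictly above the threshold in at
    least ``min_samples`` samples.

    miRNAs absent from the matrix fail the filter and are logged as a
    warning rather than raising: on real array platforms the probe content
    never covers the full miRBase namespace.
    """
    missing = sorted(m for m in mirnas if m not in expr.values.index)
    if missing:
        logger.warning(
            "%d miRNAs absent from the expression matrix fail the filter: %s",
            len(missing),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    present = sorted(set(mirnas) - set(missing))
    if not present:
        return set()
    counts = (expr.values.loc[present] > log2_threshold).sum(axis=1)
    return set(counts.index[counts >= min_samples])


def assemble_network(
    driver_id: str,
    mirnas: set[str],
    candidates: CandidateSet | set[str],
    db: InteractionDB,
) -> CeRNANetwork:
    """Build the sponge network over the selected miRNAs and targets.

    Edges are the interaction pairs restricted to mirnas x candidates; a
    driver edge is materialised for every retained miRNA.  Nodes left with
    no miRNA-target edge cannot participate in sponging and are dropped
    (and logged).
    """
    genes = _as_gene_set(candidates)
    if not mirnas or not genes:
        raise ValueError("need nonempty miRNA and candidate sets")
    mt = {(m, g) for (m, g) in db.mt_pairs if m in mirnas and g in genes}
    if not mt:
        raise ValueError("no interaction pair survives the restriction; no network")
    kept_m = {m for m, _ in mt}
    kept_t = {g for _, g in mt}
    for label, dropped in (
        ("miRNAs", sorted(mirnas - kept_m)),
        ("targets", sorted(genes - kept_t)),
    ):
        if dropped:
            logger.info("dropped %d edgeless %s: %s", len(dropped), label, dropped)
    return CeRNANetwork(
        driver=driver_id,
        mirna_nodes=kept_m,
        target_nodes=kept_t,
        mt_edges=mt,
    )


def extract_subnetwork(net: CeRNANetwork, gene_set: set[str]) -> CeRNANetwork:
    """Restrict the network to targets in ``gene_set`` and their miRNAs.

    Used to pull out the pathway-level subnetworks (e.g., the targets
    enriched in the mitotic cell-cycle gene set together with every miRNA
    still wired to at least one of them).
    """
    targets = net.target_nodes & set(gene_set)
    if not targets:
        raise ValueError("gene_set shares no member with the network targets")
    mt = {(m, t) for (m, t) in net.mt_edges if t in targets}
    mirnas = {m for m, _ in mt}
    return CeRNANetwork(
        driver=net.driver,
        mirna_nodes=mirnas,
        target_nodes=targets,
        mt_edges=mt,
    )
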