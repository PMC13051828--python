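"""Gene-set enrichment: hypergeometric ORA, GSEA and the validation matrix.

Two complementary enrichment layers are implemented.  Over-representation
analysis (ORA) asks whether the discrete candidate-target list overlaps a
gene set more than a hypergeometric draw would; it nominates the sets.
GSEA then asks, per experimental condition, whether the members of a
nominated set drift coherently up or down the condition's fold-change
ranking, scored by the weighted Kolmogorov-Smirnov enrichment statistic
with a permutation null (random same-size gene draws for pre-ranked input,
sample-label permutations for expression-matrix input).  A gene set is
"validated" in a condition when |NES| clears a threshold with permutation
FDR below a cap, and the validation matrix collects those calls across
conditions together with a sign-consistency flag (enrichment must move
with the driver: down under knock-down, up under overexpression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "RankedList",
    "EnrichmentResult",
    "ValidationMatrix",
    "ora",
    "gsea_es",
    "gsea_preranked",
    "gsea_sample_perm",
    "build_validation_matrix",
    "count_validated",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (Hallmark/Reactome/KEGG-style)."""

    sets: dict[str, set[str]]
    label: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: set(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return sorted(self.sets)

    @classmethod
    def read_gmt(cls, path: str | Path, label: str = "") -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"gene set {name!r} has no genes")
            sets[name] = genes
        return cls(sets, label or Path(path).stem)

    def write_gmt(self, path: str | Path, descriptions: dict | None = None) -> None:
        lines = []
        for name in self.names():
            desc = (descriptions or {}).get(name, "na")
            lines.append("\t".join([name, desc, *sorted(self.sets[name])]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RankedList:
    """Gene ids ordered by descending score (ties broken by gene id)."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("ranked list contains duplicate gene ids")
        order = np.lexsort((genes, -scores))
        self.genes = genes[order]
        self.scores = scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(np.asarray(s.index, dtype=object), s.to_numpy(dtype=float))

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.genes, name="gene_id"),
                         name="score")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        return cls(df["gene_id"].to_numpy(dtype=object),
                   df["score"].to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        self.to_series().reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    """Per-set enrichment statistics for one condition."""

    table: pd.DataFrame  # index set name; columns es, nes, pval, padj, size
    condition: str = ""
    params: dict = field(default_factory=dict)


def ora(query, collection: GeneSetCollection, background) -> pd.DataFrame:
    """Over-representation analysis by the one-sided hypergeometric tail.

    For each set: population = background, successes = set ∩ background,
    draws = query, p = P(X >= overlap); Benjamini-Hochberg across sets.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("query gene set is empty")
    if not background:
        raise ValueError("background universe is empty")
    stray = query - background
    if stray:
        raise ValueError(
            f"query genes outside the background universe: {sorted(stray)[:5]}"
        )
    M, n_draws = len(background), len(query)
    rows = {}
    for name in collection.names():
        members = collection.sets[name] & background
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(members), n_draws))
        rows[name] = (overlap, len(members), min(p, 1.0))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["overlap", "set_size", "p"]
    )
    table.index.name = "set_name"
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def _es_from_hits(scores: np.ndarray, hit_idx: np.ndarray, weight: float) -> float:
    """Enrichment score from hit positions in a descending score vector.

    The running sum is piecewise linear between hits, so its extremes occur
    immediately after or immediately before a hit; only those 2k points are
    evaluated.
    """
    N = len(scores)
    k = len(hit_idx)
    if k == 0:
        raise ValueError("gene set has no member in the ranked list")
    if k == N:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(scores[hit_idx]) ** weight
    nr = w.sum()
    if nr == 0:  # all in-set scores exactly zero: fall back to uniform weights
        w = np.ones(k)
        nr = float(k)
    miss = 1.0 / (N - k)
    cum = np.cumsum(w) / nr
    j = np.arange(k)
    after = cum - (hit_idx - j) * miss
    before = np.concatenate(([0.0], cum[:-1])) - (hit_idx - j) * miss
    pos = max(after.max(), 0.0)
    neg = min(before.min(), 0.0)
    return float(pos) if pos >= -neg else float(neg)


def gsea_es(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score for one gene set.

    Walking the ranked list, set members add |score|^weight (normalized by
    the in-set total) and non-members subtract 1/(N - N_hit); the ES is the
    signed maximum deviation of this running sum from zero.  Returns
    (ES, running sum over all N positions, hit indices).
    """
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                           count=len(ranked))
    hit_idx = np.flatnonzero(hit_mask)
    es = _es_from_hits(ranked.scores, hit_idx, weight)
    N, k = len(ranked), len(hit_idx)
    w = np.abs(ranked.scores[hit_idx]) ** weight
    nr = w.sum()
    steps = np.full(N, -1.0 / (N - k))
    steps[hit_idx] = (w / nr) if nr > 0 else (1.0 / k)
    running = np.cumsum(steps)
    return es, running, hit_idx


def _nes(es: float, null_es: np.ndarray) -> float:
    """Normalize an ES by the mean |null ES| of matching sign."""
    same = null_es >= 0 if es >= 0 else null_es < 0
    pool = np.abs(null_es[same])
    if len(pool) == 0 or pool.mean() == 0:
        pool = np.abs(null_es)
    denom = pool.mean()
    return float(es / denom) if denom > 0 else 0.0


def _nominal_p(es: float, null_es: np.ndarray) -> float:
    same = null_es >= 0 if es >= 0 else null_es < 0
    pool = null_es[same]
    return (1.0 + float((np.abs(pool) >= abs(es)).sum())) / (1.0 + len(pool))


def _pooled_fdr(nes_obs: np.ndarray, null_nes_pool: np.ndarray) -> np.ndarray:
    """Permutation FDR q-values from the sign-split pooled-NES procedure."""
    q = np.ones(len(nes_obs))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            null_side = null_nes_pool[null_nes_pool >= 0]
            obs_side = nes_obs[nes_obs >= 0]
            num = (null_side >= nes).mean() if len(null_side) else 1.0
            den = (obs_side >= nes).mean() if len(obs_side) else 1.0
        else:
            null_side = null_nes_pool[null_nes_pool < 0]
            obs_side = nes_obs[nes_obs < 0]
            num = (null_side <= nes).mean() if len(null_side) else 1.0
            den = (obs_side <= nes).mean() if len(obs_side) else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    floor = np.finfo(float).tiny
    return np.clip(q, floor, 1.0)


def _size_filtered(
    collection: GeneSetCollection, universe: set, min_size: int, max_size: int
) -> dict[str, set[str]]:
    kept = {}
    for name in collection.names():
        members = collection.sets[name] & universe
        if min_size <= len(members) <= max_size:
            kept[name] = members
    if not kept:
        raise ValueError(
            f"no gene set survives the size bounds [{min_size}, {max_size}]"
        )
    return kept


def _finalize(
    names, es_obs, sizes, null_es_per_set, condition, params
) -> EnrichmentResult:
    nes_obs = np.array(
        [_nes(es, null) for es, null in zip(es_obs, null_es_per_set)]
    )
    pvals = np.array(
        [_nominal_p(es, null) for es, null in zip(es_obs, null_es_per_set)]
    )
    null_nes = []
    for null in null_es_per_set:
        pos = null[null >= 0]
        neg = null[null < 0]
        mpos = pos.mean() if len(pos) else np.abs(null).mean()
        mneg = np.abs(neg).mean() if len(neg) else np.abs(null).mean()
        scaled = np.where(null >= 0,
                          null / mpos if mpos > 0 else 0.0,
                          null / mneg if mneg > 0 else 0.0)
        null_nes.append(scaled)
    qvals = _pooled_fdr(nes_obs, np.concatenate(null_nes))
    table = pd.DataFrame(
        {"es": es_obs, "nes": nes_obs, "pval": pvals, "padj": qvals,
         "size": sizes},
        index=pd.Index(names, name="set_name"),
    )
    return EnrichmentResult(table, condition=condition, params=params)


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    condition: str = "",
) -> EnrichmentResult:
    """Pre-ranked GSEA with a random-gene-draw permutation null.

    Size bounds are applied after intersecting each set with the ranked
    universe.  The null for a set of size k is the ES of n_perm random
    k-gene draws from the ranked list; NES divides the observed ES by the
    mean |null ES| of matching sign, the nominal p uses the +1-corrected
    same-sign tail, and FDR q comes from the sign-split pooled-NES
    procedure.
    """
    N = len(ranked)
    if N < max(2 * min_size, 100):
        raise ValueError(f"ranked list too short for GSEA: {N} genes")
    universe = set(ranked.genes)
    kept = _size_filtered(collection, universe, min_size, max_size)
    rng = np.random.default_rng(seed)
    names = sorted(kept)
    es_obs, sizes, nulls = [], [], []
    null_cache: dict[int, np.ndarray] = {}
    for name in names:
        members = kept[name]
        es, _, _ = gsea_es(ranked, members, weight)
        k = len(members)
        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                idx = np.sort(rng.choice(N, size=k, replace=False))
                null[b] = _es_from_hits(ranked.scores, idx, weight)
            null_cache[k] = null
        es_obs.append(es)
        sizes.append(k)
        nulls.append(null_cache[k])
    return _finalize(
        names, np.array(es_obs), sizes, nulls, condition,
        {"mode": "preranked", "min_size": min_size, "max_size": max_size,
         "n_perm": n_perm, "weight": weight, "seed": seed},
    )


def _log2fc_metric(values: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Per-gene difference of group means on log2-scale data (= log2 FC)."""
    return values[:, mask_b].mean(axis=1) - values[:, ~mask_b].mean(axis=1)


def gsea_sample_perm(
    expr: pd.DataFrame,
    labels,
    collection: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    condition: str = "",
) -> EnrichmentResult:
    """GSEA with a sample-permutation null on a two-group expression matrix.

    The ranking metric is the per-gene log2 fold change of group means
    (second group minus first, groups ordered lexicographically); it is
    recomputed under every label permutation, which preserves inter-gene
    correlation in the null.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    counts = labels.value_counts()
    if counts.min() < 7:
        raise ValueError(
            f"need at least 7 samples per group, got {counts.to_dict()}"
        )
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    values = expr.to_numpy(dtype=float)
    genes = np.asarray(expr.index, dtype=object)
    mask_b = (labels == uniq[1]).to_numpy()
    ranked = RankedList(genes, _log2fc_metric(values, mask_b))
    universe = set(genes)
    kept = _size_filtered(collection, universe, min_size, max_size)
    names = sorted(kept)
    es_obs, sizes = [], []
    hit_masks = {}
    for name in names:
        members = kept[name]
        es, _, _ = gsea_es(ranked, members, weight)
        es_obs.append(es)
        sizes.append(len(members))
        hit_masks[name] = np.fromiter(
            (g in members for g in genes), dtype=bool, count=len(genes)
        )
    rng = np.random.default_rng(seed)
    nulls = {name: np.empty(n_perm) for name in names}
    n_samples = values.shape[1]
    n_b = int(mask_b.sum())
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        pm = np.zeros(n_samples, dtype=bool)
        pm[perm[:n_b]] = True
        metric = _log2fc_metric(values, pm)
        order = np.lexsort((genes, -metric))
        scores = metric[order]
        for name in names:
            hit_idx = np.flatnonzero(hit_masks[name][order])
            nulls[name][b] = _es_from_hits(scores, hit_idx, weight)
    return _finalize(
        names, np.array(es_obs), sizes, [nulls[n] for n in names], condition,
        {"mode": "sample_perm", "min_size": min_size, "max_size": max_size,
         "n_perm": n_perm, "weight": weight, "seed": seed},
    )


@dataclass
class ValidationMatrix:
    """Gene-set x condition grid of (NES, FDR, pass) validation calls."""

    nes: pd.DataFrame  # set x condition, NaN where the set was not tested
    padj: pd.DataFrame
    passes: pd.DataFrame  # boolean
    conditions_passed: pd.Series
    sign_consistent: pd.Series
    nes_threshold: float
    padj_threshold: float

    @property
    def conditions(self) -> list[str]:
        return list(self.nes.columns)

    def write_tsv(self, path: str | Path) -> None:
        wide = pd.concat(
            {"nes": self.nes.round(4), "padj": self.padj.round(4)}, axis=1
        ).swaplevel(axis=1).sort_index(axis=1, level=0)
        wide.columns = [f"{cond}_{stat}" for cond, stat in wide.columns]
        wide["conditions_passed"] = self.conditions_passed
        wide["sign_consistent"] = self.sign_consistent
        wide.to_csv(path, sep="\t", index_label="set_name")


def build_validation_matrix(
    results: dict[str, EnrichmentResult | pd.DataFrame],
    candidate_sets,
    nes_threshold: float = 1.5,
    padj_threshold: float = 0.05,
    condition_direction: dict[str, int] | None = None,
) -> ValidationMatrix:
    """Cross-condition validation grid under the |NES| >= t, FDR < cap rule.

    ``results`` maps condition label -> per-set enrichment table (columns
    nes, padj); ``candidate_sets`` fixes the row universe (sets nominated
    by ORA).  A cell passes iff |NES| >= nes_threshold and p_adj <
    padj_threshold.  ``condition_direction`` gives the expected NES sign
    per condition (-1 for driver knock-down, +1 for overexpression / high
    driver); a row is sign-consistent when every passing cell matches it.
    """
    condition_direction = condition_direction or {}
    unknown = set(condition_direction) - set(results)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    conditions = list(results)
    rows = sorted(set(candidate_sets))
    nes = pd.DataFrame(np.nan, index=rows, columns=conditions)
    padj = pd.DataFrame(np.nan, index=rows, columns=conditions)
    for cond, res in results.items():
        table = res.table if isinstance(res, EnrichmentResult) else res
        shared = table.index.intersection(rows)
        nes.loc[shared, cond] = table.loc[shared, "nes"]
        padj.loc[shared, cond] = table.loc[shared, "padj"]
    passes = (nes.abs() >= nes_threshold) & (padj < padj_threshold)
    passes = passes.fillna(False).astype(bool)
    conditions_passed = passes.sum(axis=1).astype(int)
    sign_ok = pd.Series(True, index=nes.index)
    for cond, direction in condition_direction.items():
        cell_ok = ~passes[cond] | (np.sign(nes[cond]).fillna(0) == np.sign(direction))
        sign_ok &= cell_ok
    nes.index.name = padj.index.name = passes.index.name = "set_name"
    return ValidationMatrix(
        nes, padj, passes, conditions_passed, sign_ok,
        nes_threshold, padj_threshold,
    )


def count_validated(
    matrix: ValidationMatrix, min_conditions: int
) -> tuple[list[str], int]:
    """Sets validated in at least ``min_conditions`` conditions."""
    names = sorted(
        matrix.conditions_passed.index[matrix.conditions_passed >= min_conditions]
    )
    return names, len(names)
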