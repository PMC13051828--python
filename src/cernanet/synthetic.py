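"""Synthetic study generator with planted, exactly-recoverable ground truth.

Every input the pipeline consumes can be simulated here: paired KD/OVX
differential-expression tables, a miRNA-target / driver-binder interaction
database, a grouped miRNA expression matrix, patient cohorts with planted
driver co-expression and planted prognostic hazard, and two-group
expression for enrichment testing.  All planted counts (DEG totals,
candidate overlap, miRNA intersections, expression-filter survivors, edge
counts) are exact by construction for any seed, so downstream recomputation
is a strict test of the pipeline, not a statistical one.  Effect-size
parameters (Spearman rho, hazard ratio, set-level shift) are planted
through models whose population value equals the configured value, so
recovery tests are statistical at the configured cohort size.

Randomness: each generator derives its own stream from (config.seed,
stream-id); there is no global random state.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import DETable, select_candidates
from .cohort import CohortDataset
from .config import SyntheticConfig
from .enrichment import GeneSetCollection, RankedList
from .network import InteractionDB, MiRNAExpressionMatrix

__all__ = [
    "generate_de_pair",
    "generate_interaction_db",
    "generate_mirna_expression",
    "generate_cohort",
    "generate_enrichment_input",
    "generate_gene_set_collection",
    "write_bundle",
    "gene_universe",
    "mirna_universe",
]

# fixed sub-stream ids so generators are independent yet reproducible
_STREAM_DE = 1
_STREAM_DB = 2
_STREAM_EXPR = 3
_STREAM_COHORT = 4
_STREAM_ENRICH = 5
_STREAM_SETS = 6


def gene_universe(config: SyntheticConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def mirna_universe(config: SyntheticConfig) -> list[str]:
    return [f"miR-{i:04d}" for i in range(config.n_mirnas)]


def _expressed_subset(intersection, n_expressed: int) -> list[str]:
    """The planted expressed miRNAs: lexicographically first members.

    Both the interaction-database and expression-matrix generators apply
    this rule, so the miRNAs carrying the counted edges are exactly the
    ones that survive the expression filter, without shared state.
    """
    return sorted(intersection)[:n_expressed]


def _planted_stats(rng, n: int, alpha: float, sign: int):
    """FDR/p/log2fc draws for significant genes (strictly inside bounds)."""
    fdr = alpha * rng.uniform(1e-6, 0.999, n)
    pval = fdr * rng.uniform(0.1, 1.0, n)
    lfc = sign * (np.abs(rng.normal(0.0, 1.0, n)) + 0.25)
    return fdr, pval, lfc


def generate_de_pair(config: SyntheticConfig) -> tuple[DETable, DETable]:
    """Paired KD/OVX differential-expression tables with planted DEG counts.

    Exactly n_kd_up / n_kd_down genes are significant in the knock-down
    contrast and n_ovx_up / n_ovx_down in the overexpression contrast (at
    FDR < fdr_alpha with the planted sign); exactly n_candidates genes are
    simultaneously down-in-KD and up-in-OVX.  Null genes draw FDR uniformly
    on [alpha, 1].  Deterministic for a fixed config.
    """
    c = config
    c.validate()
    rng = np.random.default_rng([c.seed, _STREAM_DE])
    genes = np.array(gene_universe(c), dtype=object)
    perm = rng.permutation(c.n_genes)

    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        block = perm[pos: pos + k]
        pos += k
        return block

    cand = take(c.n_candidates)
    kd_down_rest = take(c.n_kd_down - c.n_candidates)
    kd_up = take(c.n_kd_up)
    ovx_up_rest = take(c.n_ovx_up - c.n_candidates)
    ovx_down = take(c.n_ovx_down)

    def build(up_idx, down_idx, label) -> DETable:
        fdr = rng.uniform(c.fdr_alpha, 1.0, c.n_genes)
        pval = fdr * rng.uniform(0.0, 1.0, c.n_genes)
        lfc = rng.normal(0.0, 0.3, c.n_genes)
        for idx, sign in ((up_idx, +1), (down_idx, -1)):
            f, p, l = _planted_stats(rng, len(idx), c.fdr_alpha, sign)
            fdr[idx], pval[idx], lfc[idx] = f, p, l
        df = pd.DataFrame(
            {"gene_id": genes, "log2fc": lfc, "pvalue": pval, "fdr": fdr}
        ).sort_values("gene_id", ignore_index=True)
        return DETable(df, contrast_label=label)

    kd = build(kd_up, np.concatenate([cand, kd_down_rest]), "KD_vs_SCR")
    ovx = build(np.concatenate([cand, ovx_up_rest]), ovx_down, "OVX_vs_SCR")
    return kd, ovx


def generate_interaction_db(
    config: SyntheticConfig, candidates
) -> InteractionDB:
    """Interaction database with planted miRNA-layer cascade sizes.

    Exactly n_target_binders miRNAs carry >= 1 pair with a candidate,
    exactly n_driver_binders bind the driver, their intersection has
    exactly n_intersection members, and the pair set restricted to
    (planted-expressed intersection miRNAs x candidates) has exactly
    n_mt_edges pairs covering both sides.  Decoy pairs to non-candidate
    genes are added for realism and never touch the counted quantities.
    """
    c = config
    c.validate()
    candidates = sorted({str(g).strip() for g in candidates})
    if len(candidates) != c.n_candidates:
        raise ValueError(
            f"candidate set size {len(candidates)} != n_candidates "
            f"{c.n_candidates}"
        )
    rng = np.random.default_rng([c.seed, _STREAM_DB])
    mirnas = np.array(mirna_universe(c), dtype=object)
    perm = rng.permutation(c.n_mirnas)
    inter = list(mirnas[perm[: c.n_intersection]])
    tb_only = list(
        mirnas[perm[c.n_intersection: c.n_target_binders]]
    )
    db_only = list(
        mirnas[
            perm[
                c.n_target_binders: c.n_target_binders
                + (c.n_driver_binders - c.n_intersection)
            ]
        ]
    )
    driver_binders = set(inter) | set(db_only)
    expressed = _expressed_subset(inter, c.n_expressed)

    pairs: dict[tuple[str, str], str] = {}
    # exact edge set on the (expressed x candidates) grid
    nE, nC = len(expressed), len(candidates)
    if nE > 0 and nC > 0:
        if c.n_mt_edges < max(nE, nC) or c.n_mt_edges > nE * nC:
            raise ValueError("n_mt_edges cannot cover every selected node")
        base = {(expressed[i], candidates[i % nC]) for i in range(nE)}
        base |= {(expressed[j % nE], candidates[j]) for j in range(nC)}
        grid = [
            (m, g) for m in expressed for g in candidates if (m, g) not in base
        ]
        extra_n = c.n_mt_edges - len(base)
        extra_idx = rng.choice(len(grid), size=extra_n, replace=False)
        for i in extra_idx:
            base.add(grid[i])
        for m, g in base:
            pairs[(m, g)] = "tarbase"
    # every remaining target binder gets one candidate pair
    rest = [m for m in inter if m not in set(expressed)] + tb_only
    if candidates:
        for m in rest:
            g = candidates[int(rng.integers(0, nC))] if nC else None
            if g is not None:
                pairs[(m, g)] = "tarbase"
    # decoy pairs to non-candidate genes (do not affect any counted stage)
    genes = gene_universe(c)
    non_cand = sorted(set(genes) - set(candidates))
    if non_cand:
        for m in mirnas[perm[: c.n_target_binders]]:
            for g_idx in rng.integers(0, len(non_cand), 2):
                pairs[(str(m), non_cand[int(g_idx)])] = "tarbase"
    return InteractionDB(pairs, driver_binders)


def generate_mirna_expression(
    config: SyntheticConfig, intersection
) -> MiRNAExpressionMatrix:
    """Grouped (N/MM/PCL) miRNA log2-expression matrix with a planted filter.

    Exactly n_expressed of the intersection miRNAs (lexicographically
    first, matching the interaction generator) exceed log2 = 4 in >= 10
    samples; every other intersection miRNA exceeds 4 in at most 9.
    """
    c = config
    c.validate()
    intersection = sorted({str(m).strip() for m in intersection})
    if len(intersection) != c.n_intersection:
        raise ValueError(
            f"intersection size {len(intersection)} != n_intersection "
            f"{c.n_intersection}"
        )
    if c.n_expressed > len(intersection):
        raise ValueError("n_expressed exceeds the intersection size")
    rng = np.random.default_rng([c.seed, _STREAM_EXPR])
    n_samples = c.n_samples
    if n_samples < 10:
        raise ValueError("need >= 10 samples for the expression filter")
    samples = (
        [f"N{i + 1:02d}" for i in range(c.n_samples_n)]
        + [f"MM{i + 1:03d}" for i in range(c.n_samples_mm)]
        + [f"PCL{i + 1:02d}" for i in range(c.n_samples_pcl)]
    )
    groups = pd.Series(
        ["N"] * c.n_samples_n + ["MM"] * c.n_samples_mm
        + ["PCL"] * c.n_samples_pcl,
        index=samples,
        name="group",
    )
    expressed = set(_expressed_subset(intersection, c.n_expressed))
    values = np.empty((len(intersection), n_samples))
    n_guaranteed = min(12, n_samples)
    for i, m in enumerate(intersection):
        if m in expressed:
            row = rng.uniform(0.5, 9.5, n_samples)
            idx = rng.choice(n_samples, n_guaranteed, replace=False)
            row[idx] = rng.uniform(4.6, 9.5, n_guaranteed)
        else:
            row = rng.uniform(0.5, 3.9, n_samples)
            k = int(rng.integers(0, 10))
            idx = rng.choice(n_samples, k, replace=False)
            row[idx] = rng.uniform(4.2, 8.0, k)
        values[i] = row
    df = pd.DataFrame(values, index=pd.Index(intersection, name="mirna_id"),
                      columns=samples)
    return MiRNAExpressionMatrix(df, groups)


def generate_cohort(
    config: SyntheticConfig,
    targets,
    planted_correlated=(),
    planted_prognostic=(),
    driver_id: str = "NEAT1",
    cohort_label: str = "synthetic_cohort",
    cohort_index: int = 0,
) -> CohortDataset:
    """Patient cohort with planted driver co-expression and prognostic genes.

    The driver is a latent standard normal Z; each planted-correlated gene
    is rho'*Z + sqrt(1 - rho'^2)*eps with rho' = 2*sin(pi*rho/6), the
    Gaussian-copula value whose population Spearman correlation equals
    rho_planted.  Other targets are independent of the driver.  OS/PFS
    times are exponential; the hazard is multiplied by hr_planted once per
    planted-prognostic gene the patient is above the median of.  Censoring
    is administrative at a horizon giving ~30% censoring under the null.
    """
    c = config
    targets = sorted({str(g) for g in targets})
    planted_correlated = {str(g) for g in planted_correlated}
    planted_prognostic = {str(g) for g in planted_prognostic}
    for name, sub in (
        ("planted_correlated", planted_correlated),
        ("planted_prognostic", planted_prognostic),
    ):
        if not sub <= set(targets):
            raise ValueError(f"{name} is not a subset of targets")
    if c.cohort_n < 8:
        raise ValueError(
            f"cohort_n {c.cohort_n} too small for median split + log-rank"
        )
    rng = np.random.default_rng([c.seed, _STREAM_COHORT, cohort_index])
    n = c.cohort_n
    z = rng.standard_normal(n)
    rho_prime = 2.0 * np.sin(np.pi * c.rho_planted / 6.0)
    expr = {driver_id: z}
    for g in targets:
        if g in planted_correlated:
            eps = rng.standard_normal(n)
            expr[g] = rho_prime * z + np.sqrt(1.0 - rho_prime**2) * eps
        else:
            expr[g] = rng.standard_normal(n)
    patients = [f"P{i + 1:04d}" for i in range(n)]
    expr_df = pd.DataFrame(expr, index=patients).T
    expr_df.index.name = "gene_id"

    # per-patient hazard multiplier from the planted prognostic genes
    log_mult = np.zeros(n)
    for g in sorted(planted_prognostic):
        v = expr_df.loc[g].to_numpy()
        log_mult += (v > np.median(v)) * np.log(c.hr_planted)
    mult = np.exp(log_mult)

    surv = {}
    for endpoint, median_months in (("os", 60.0), ("pfs", 30.0)):
        lam0 = np.log(2.0) / median_months
        horizon = -np.log(0.3) / lam0  # ~30% administrative censoring at null
        t = rng.exponential(1.0 / (lam0 * mult))
        event = (t <= horizon).astype(int)
        surv[f"{endpoint}_time"] = np.minimum(t, horizon)
        surv[f"{endpoint}_event"] = event
    surv_df = pd.DataFrame(surv, index=pd.Index(patients, name="patient_id"))
    return CohortDataset(expr_df, survival=surv_df, cohort_label=cohort_label)


def generate_gene_set_collection(
    config: SyntheticConfig,
    n_sets: int = 20,
    set_size: int = 40,
    universe_size: int = 2000,
    planted_member_sets: dict[str, list[str]] | None = None,
) -> GeneSetCollection:
    """Random gene-set collection over a slice of the gene universe.

    ``planted_member_sets`` maps a set name to genes that must be members
    (e.g., candidate targets, so ORA has signal to find); the set is padded
    with random universe genes up to ``set_size``.
    """
    c = config
    rng = np.random.default_rng([c.seed, _STREAM_SETS])
    genes = gene_universe(c)
    universe = [genes[i] for i in rng.choice(c.n_genes, min(universe_size, c.n_genes),
                                             replace=False)]
    sets: dict[str, set[str]] = {}
    for name, members in (planted_member_sets or {}).items():
        members = set(members)
        pad = set_size - len(members)
        if pad > 0:
            pool = [g for g in universe if g not in members]
            members |= {pool[i] for i in rng.choice(len(pool), pad, replace=False)}
        sets[name] = members
    for i in range(n_sets - len(sets)):
        idx = rng.choice(len(universe), set_size, replace=False)
        sets[f"SET_{i + 1:03d}"] = {universe[j] for j in idx}
    return GeneSetCollection(sets, label="synthetic")


def generate_enrichment_input(
    config: SyntheticConfig,
    collection: GeneSetCollection,
    shifted_sets,
    shift: float,
    n_per_group: int = 50,
    universe=None,
    stream: int = 0,
) -> tuple[pd.DataFrame, pd.Series, RankedList]:
    """Two-group expression with a planted set-level shift, plus its ranking.

    Genes in ``shifted_sets`` have their group-B mean shifted by ``shift``
    standard deviations; the returned RankedList is the per-gene log2 fold
    change B vs A.  Returns (expression matrix, group labels, ranked list).
    """
    c = config
    shifted_sets = set(shifted_sets)
    unknown = shifted_sets - set(collection.sets)
    if unknown:
        raise ValueError(f"shifted_sets not in the collection: {sorted(unknown)}")
    if universe is None:
        universe = sorted(set().union(*collection.sets.values()))
    else:
        universe = sorted(set(universe))
    for name in sorted(shifted_sets):
        if not collection.sets[name] & set(universe):
            raise ValueError(f"shifted set {name!r} has no genes in the universe")
    rng = np.random.default_rng([c.seed, _STREAM_ENRICH, stream])
    n_genes = len(universe)
    n_samples = 2 * n_per_group
    values = rng.standard_normal((n_genes, n_samples))
    shifted_genes = set().union(*(collection.sets[s] for s in shifted_sets)) \
        if shifted_sets else set()
    mask = np.fromiter((g in shifted_genes for g in universe), dtype=bool,
                       count=n_genes)
    values[np.ix_(mask, np.arange(n_per_group, n_samples))] += shift
    samples = [f"A{i + 1:03d}" for i in range(n_per_group)] + [
        f"B{i + 1:03d}" for i in range(n_per_group)
    ]
    labels = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=samples, name="group")
    expr = pd.DataFrame(values, index=pd.Index(universe, name="gene_id"),
                        columns=samples)
    lfc = expr.loc[:, labels == "B"].mean(axis=1) - \
        expr.loc[:, labels == "A"].mean(axis=1)
    return expr, labels, RankedList.from_series(lfc)


def write_bundle(
    config: SyntheticConfig,
    outdir: str | Path,
    driver_id: str = "NEAT1",
    n_correlated: int = 13,
    n_prognostic: int = 13,
    n_planted_sets: int = 2,
    enrichment_shift: float = 1.0,
) -> dict:
    """Write a complete synthetic input bundle plus a ground-truth manifest.

    The manifest (planted candidate / miRNA / effect-gene identities) is
    for tests and audit only; the pipeline never reads it.  Returns a dict
    of file paths and the manifest.
    """
    c = config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    kd, ovx = generate_de_pair(c)
    candidates = select_candidates(kd, ovx, alpha=c.fdr_alpha)
    cand_ids = candidates.gene_ids
    db = generate_interaction_db(c, cand_ids)
    from .network import intersect_driver_binders, mirnas_targeting

    inter = intersect_driver_binders(mirnas_targeting(db, candidates), db)
    expr = generate_mirna_expression(c, inter)

    rng = np.random.default_rng([c.seed, 7])
    corr = sorted(
        np.array(cand_ids, dtype=object)[
            rng.choice(len(cand_ids), min(n_correlated, len(cand_ids)),
                       replace=False)
        ]
    )
    prog = sorted(
        np.array(cand_ids, dtype=object)[
            rng.choice(len(cand_ids), min(n_prognostic, len(cand_ids)),
                       replace=False)
        ]
    )
    cohort = generate_cohort(
        c, cand_ids, planted_correlated=corr, planted_prognostic=prog,
        driver_id=driver_id,
    )

    planted_sets = {
        f"PLANTED_{i + 1:02d}": list(
            np.array(cand_ids, dtype=object)[
                rng.choice(len(cand_ids), min(12, len(cand_ids)), replace=False)
            ]
        )
        for i in range(n_planted_sets)
    }
    collection = generate_gene_set_collection(
        c, planted_member_sets=planted_sets
    )
    conditions = {"KD": -1, "OVX": +1}
    ranked_paths = {}
    for stream, (cond, sign) in enumerate(conditions.items()):
        _, _, ranked = generate_enrichment_input(
            c, collection, set(planted_sets), sign * enrichment_shift,
            stream=stream,
        )
        path = out / f"ranked_{cond}.tsv"
        ranked.write_tsv(path)
        ranked_paths[cond] = str(path)

    paths = {
        "de_kd": str(out / "de_kd.tsv"),
        "de_ovx": str(out / "de_ovx.tsv"),
        "interactions": str(out / "interactions.tsv"),
        "driver_binders": str(out / "driver_binders.txt"),
        "mirna_expression": str(out / "mirna_expression.tsv"),
        "mirna_groups": str(out / "mirna_groups.tsv"),
        "cohort_expression": str(out / "cohort_expression.tsv"),
        "cohort_survival": str(out / "cohort_survival.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
        "ranked_lists": ranked_paths,
        "condition_direction": conditions,
    }
    kd.write_tsv(paths["de_kd"])
    ovx.write_tsv(paths["de_ovx"])
    db.write_tsv(paths["interactions"], paths["driver_binders"])
    expr.write_tsv(paths["mirna_expression"], paths["mirna_groups"])
    cohort.write_tsv(paths["cohort_expression"], paths["cohort_survival"])
    collection.write_gmt(paths["gene_sets"])

    manifest = {
        "config": c.to_dict(),
        "driver_id": driver_id,
        "candidates": cand_ids,
        "n_intersection": len(inter),
        "intersection": sorted(inter),
        "expressed": _expressed_subset(inter, c.n_expressed),
        "planted_correlated": list(corr),
        "planted_prognostic": list(prog),
        "planted_sets": sorted(planted_sets),
        "condition_direction": conditions,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    paths["manifest"] = str(manifest_path)
    return {"paths": paths, "manifest": manifest}
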