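"""Packaged transcriptions of the published target and validation tables.

``table1`` is the 40-target summary (tumour-vs-normal upregulation p, plus
median-split OS/PFS log-rank p from the 753-patient cohort).  ``table3``
is the 17-row gene-set validation grid (NES and permutation FDR across the
six experimental conditions).  Printed "p < 0.0001" cells are stored as
"<0.0001" and parsed to the bound value; only the p < 0.05 threshold is
consumed downstream, so the bound is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Table1Fixture",
    "Table3Fixture",
    "load_table_fixtures",
    "CONDITIONS",
    "CONDITION_DIRECTION",
]

#: condition labels of the validation grid, in published column order
CONDITIONS = ["amo1_kd", "h929_kd", "lp1_kd", "kms27_kd", "amo1_ovx", "commpass"]

#: expected NES sign per condition: driver loss -> negative enrichment,
#: driver gain / high-driver stratum -> positive
CONDITION_DIRECTION = {
    "amo1_kd": -1,
    "h929_kd": -1,
    "lp1_kd": -1,
    "kms27_kd": -1,
    "amo1_ovx": +1,
    "commpass": +1,
}


def _parse_p(value) -> float:
    """Parse a printed p cell: a number, a '<bound' string, or blank."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if not s:
        return np.nan
    if s.startswith("<"):
        return float(s[1:])
    return float(s)


@dataclass
class Table1Fixture:
    """40 targets x (upregulation p, OS p, PFS p); NaN where not significant."""

    table: pd.DataFrame  # index gene_symbol; columns ensembl_id, upreg_p, os_p, pfs_p

    def __len__(self) -> int:
        return len(self.table)

    @property
    def upreg_flags(self) -> pd.Series:
        return self.table["upreg_p"].notna()

    def survival_table(self) -> pd.DataFrame:
        """os_p/pfs_p frame suitable for summarize_target_table."""
        return self.table[["os_p", "pfs_p"]]


@dataclass
class Table3Fixture:
    """17 gene sets x 6 conditions of (NES, FDR); NaN where not reported."""

    nes: pd.DataFrame  # index pathway; columns CONDITIONS
    fdr: pd.DataFrame

    def __len__(self) -> int:
        return len(self.nes)

    def condition_results(self) -> dict[str, pd.DataFrame]:
        """Per-condition (nes, padj) frames for build_validation_matrix."""
        out = {}
        for cond in self.nes.columns:
            df = pd.DataFrame(
                {"nes": self.nes[cond], "padj": self.fdr[cond]}
            ).dropna()
            df.index.name = "set_name"
            out[cond] = df
        return out


def _data_path(name: str):
    return resources.files("cernanet.data").joinpath(name)


def load_table_fixtures() -> tuple[Table1Fixture, Table3Fixture]:
    """Load both packaged table transcriptions, validating their shape."""
    with resources.as_file(_data_path("table1_targets.tsv")) as path:
        t1 = pd.read_csv(path, sep="\t", dtype=str)
    expected1 = ["gene_symbol", "ensembl_id", "upreg_p", "os_p", "pfs_p"]
    if list(t1.columns) != expected1:
        raise ValueError(f"target-table fixture columns malformed: {list(t1.columns)}")
    if len(t1) != 40:
        raise ValueError(f"target-table fixture must have 40 rows, got {len(t1)}")
    t1 = t1.set_index("gene_symbol")
    for col in ("upreg_p", "os_p", "pfs_p"):
        t1[col] = t1[col].map(_parse_p)
    table1 = Table1Fixture(t1)

    with resources.as_file(_data_path("table3_validation.tsv")) as path:
        t3 = pd.read_csv(path, sep="\t", dtype=str)
    expected3 = ["pathway"] + [
        f"{cond}_{stat}" for cond in CONDITIONS for stat in ("nes", "fdr")
    ]
    if list(t3.columns) != expected3:
        raise ValueError(f"validation-grid fixture columns malformed: {list(t3.columns)}")
    if len(t3) != 17:
        raise ValueError(f"validation-grid fixture must have 17 rows, got {len(t3)}")
    t3 = t3.set_index("pathway")
    nes = pd.DataFrame(
        {c: t3[f"{c}_nes"].astype(float) for c in CONDITIONS}, index=t3.index
    )
    fdr = pd.DataFrame(
        {c: t3[f"{c}_fdr"].map(_parse_p) for c in CONDITIONS}, index=t3.index
    )
    if ((nes.isna()) != (fdr.isna())).any().any():
        raise ValueError("NES/FDR cells of the validation grid must pair up")
    return table1, Table3Fixture(nes, fdr)
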