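"""Marker-order concordance between two maps of the same loci.

Compares, per linkage group, the order of shared markers between two maps
(e.g. a heterozygosity-derived genetic map against physical assembly
positions) by Spearman rank correlation with average ranks for ties.
Orientation is informative: a reversed group yields rho = -1 rather than
being folded to +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConcordanceRecord:
    group: str
    n_shared: int
    rho: float  # NaN when fewer than 2 shared markers
    shared_markers: tuple[str, ...]


def _as_map_frame(table: pd.DataFrame) -> pd.DataFrame:
    required = {"marker", "group", "position"}
    if not required.issubset(table.columns):
        raise ValueError(f"map table needs columns {sorted(required)}")
    return table[["marker", "group", "position"]].astype({"marker": str, "group": str})


def order_correlation(
    map_a: pd.DataFrame, map_b: pd.DataFrame
) -> tuple[list[ConcordanceRecord], pd.DataFrame]:
    """Per-group rank correlation of marker positions across two maps.

    Both inputs need columns ``marker``, ``group``, ``position``. Markers
    assigned to different groups in the two maps are returned as a
    conflict table, not silently dropped; groups with fewer than two
    shared markers get an undefined (NaN) correlation. Raises if the maps
    share no markers at all.
    """
    a = _as_map_frame(map_a)
    b = _as_map_frame(map_b)
    merged = a.merge(b, on="marker", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("the two maps share no markers")
    conflicts = merged[merged["group_a"] != merged["group_b"]]
    agreed = merged[merged["group_a"] == merged["group_b"]]

    records = []
    for group, sub in agreed.groupby("group_a", sort=False):
        if len(sub) < 2 or sub["position_a"].nunique() < 2 or sub["position_b"].nunique() < 2:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(sub["position_a"], sub["position_b"]).statistic)
        records.append(
            ConcordanceRecord(
                group=str(group),
                n_shared=len(sub),
                rho=rho,
                shared_markers=tuple(sub["marker"]),
            )
        )
    conflict_table = conflicts.rename(
        columns={"group_a": "group_in_map_a", "group_b": "group_in_map_b"}
    )[["marker", "group_in_map_a", "group_in_map_b"]].reset_index(drop=True)
    return records, conflict_table


def concordance_table(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": r.group, "n_shared": r.n_shared, "spearman_rho": r.rho}
            for r in records
        ]
    )
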