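"""Gene-centromere mapping from progeny heterozygote frequencies.

In half-tetrad data from second-polar-body retention, the fraction ``y``
of heterozygous offspring at a locus is the locus's second-division
segregation frequency. Under complete chiasma interference (at most one
exchange per arm) the marker-centromere map distance is simply

    d = 100 * (y / 2)   cM,

ranging from 0 cM (centromeric, ``y = 0``) to 50 cM (fully telomeric,
``y = 1``). The Kosambi map function is provided as a standalone utility
for converting pairwise recombination fractions to distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from halftetrad.genotypes import GenotypeMatrix, is_het, is_missing


class LocusClass(str, Enum):
    TELOMERIC_CANDIDATE = "telomeric_candidate"
    CENTROMERIC_CANDIDATE = "centromeric_candidate"
    INTERFERENCE_INDICATOR = "interference_indicator"
    INTERIOR = "interior"


@dataclass(frozen=True)
class CentromereMapEntry:
    locus_id: str
    n_het: int
    n_hom: int
    y: float
    distance_cM: float
    locus_class: LocusClass = LocusClass.INTERIOR


def heterozygote_frequency(calls) -> tuple[float, int, int]:
    """Progeny heterozygote frequency at one locus.

    Missing calls are excluded from both numerator and denominator.
    Returns ``(y, n_het, n_hom)``; raises if every call is missing.
    """
    n_het = n_hom = 0
    for gt in calls:
        if is_missing(gt):
            continue
        if is_het(gt):
            n_het += 1
        else:
            n_hom += 1
    if n_het + n_hom == 0:
        raise ValueError("no informative calls")
    return n_het / (n_het + n_hom), n_het, n_hom


def centromere_distance(y: float) -> float:
    """Marker-centromere distance 100*(y/2) cM under complete interference."""
    if not 0.0 <= y <= 1.0:
        raise ValueError("heterozygote frequency must be in [0, 1]")
    return 100.0 * (y / 2.0)


def kosambi_distance(r: float) -> float:
    """Kosambi map distance 25*ln((1+2r)/(1-2r)) cM for recombination fraction r."""
    if r < 0:
        raise ValueError("recombination fraction must be non-negative")
    if r >= 0.5:
        raise ValueError("unlinked: recombination fraction must be < 0.5")
    return 25.0 * float(np.log((1 + 2 * r) / (1 - 2 * r)))


#: default classification thresholds (strict inequalities)
DEFAULT_THRESHOLDS = {"telomeric": 0.9, "centromeric": 0.1, "interference": 2.0 / 3.0}


def classify_loci(
    entries: list[CentromereMapEntry],
    telomeric: float = DEFAULT_THRESHOLDS["telomeric"],
    centromeric: float = DEFAULT_THRESHOLDS["centromeric"],
    interference: float = DEFAULT_THRESHOLDS["interference"],
) -> tuple[list[CentromereMapEntry], dict]:
    """Assign each locus its highest-priority class and summarise.

    Priority: telomeric candidate (``y > telomeric``) > centromeric
    candidate (``y < centromeric``) > interference indicator
    (``y > interference``, the 2/3 no-interference ceiling) > interior.
    All inequalities are strict; boundary values fall through.

    The summary reports counts and fractions of loci at ``y == 1`` exactly
    (fully recombinant), ``y == 0`` exactly (fully centromeric), and past
    each threshold.
    """
    if not entries:
        raise ValueError("no map entries to classify")

    def one_class(y: float) -> LocusClass:
        if y > telomeric:
            return LocusClass.TELOMERIC_CANDIDATE
        if y < centromeric:
            return LocusClass.CENTROMERIC_CANDIDATE
        if y > interference:
            return LocusClass.INTERFERENCE_INDICATOR
        return LocusClass.INTERIOR

    classified = [
        CentromereMapEntry(e.locus_id, e.n_het, e.n_hom, e.y, e.distance_cM, one_class(e.y))
        for e in entries
    ]
    ys = np.array([e.y for e in entries])
    n = len(ys)
    summary = {
        "n_loci": n,
        "n_y_eq_1": int((ys == 1.0).sum()),
        "n_y_eq_0": int((ys == 0.0).sum()),
        "n_y_gt_telomeric": int((ys > telomeric).sum()),
        "n_y_lt_centromeric": int((ys < centromeric).sum()),
        "n_y_gt_interference": int((ys > interference).sum()),
    }
    summary.update(
        {
            "frac_y_eq_1": summary["n_y_eq_1"] / n,
            "frac_y_eq_0": summary["n_y_eq_0"] / n,
            "frac_y_gt_telomeric": summary["n_y_gt_telomeric"] / n,
            "frac_y_lt_centromeric": summary["n_y_lt_centromeric"] / n,
            "frac_y_gt_interference": summary["n_y_gt_interference"] / n,
        }
    )
    return classified, summary


def build_centromere_map(matrix: GenotypeMatrix, **thresholds) -> tuple[pd.DataFrame, dict]:
    """Per-locus gene-centromere table for a (filtered) genotype matrix.

    Columns: linkage group, physical position, het/hom counts, ``y``,
    ``distance_cM`` and the locus class. Loci with no informative progeny
    call are dropped with a count in the summary.
    """
    entries = []
    kept_meta = []
    n_uninformative = 0
    for locus_id in matrix.locus_ids:
        try:
            y, n_het, n_hom = heterozygote_frequency(matrix.offspring.loc[locus_id])
        except ValueError:
            n_uninformative += 1
            continue
        entries.append(
            CentromereMapEntry(str(locus_id), n_het, n_hom, y, centromere_distance(y))
        )
        kept_meta.append(locus_id)
    classified, summary = classify_loci(entries, **thresholds)
    summary["n_dropped_all_missing"] = n_uninformative
    table = pd.DataFrame(
        {
            "locus_id": [e.locus_id for e in classified],
            "linkage_group": matrix.loci.loc[kept_meta, "linkage_group"].values,
            "position": matrix.loci.loc[kept_meta, "position"].values,
            "n_het": [e.n_het for e in classified],
            "n_hom": [e.n_hom for e in classified],
            "y": [e.y for e in classified],
            "distance_cM": [e.distance_cM for e in classified],
            "class": [e.locus_class.value for e in classified],
        }
    )
    return table, summary


def write_candidate_bed(table: pd.DataFrame, path: str | Path, feature_length: int = 1) -> None:
    """BED track of telomeric/centromeric candidate markers.

    Physical positions are 1-based inclusive in the map table; BED is
    0-based half-open, so a 1 bp marker at position p becomes [p-1, p).
    """
    rows = table[table["class"].isin(["telomeric_candidate", "centromeric_candidate"])]
    with Path(path).open("w") as fh:
        for _, row in rows.iterrows():
            start = int(row["position"]) - 1
            fh.write(
                f"{row['linkage_group']}\t{start}\t{start + feature_length}\t"
                f"{row['locus_id']}|{row['class']}\t{row['y']:.4f}\t.\n"
            )
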