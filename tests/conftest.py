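"""Shared fixtures: small simulated families and a constructed QC candidate set."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from halftetrad.genotypes import MISSING, GenotypeMatrix
from halftetrad.meiosis_sim import LinkageGroupSpec, SimConfig, simulate_family


@pytest.fixture(scope="session")
def clean_family():
    """Default-design family: 79 offspring, 24 groups, obligate-one, no noise."""
    return simulate_family(SimConfig(seed=101))


@pytest.fixture(scope="session")
def small_family():
    """Quick 3-group family for cheap per-test use."""
    config = SimConfig(
        n_offspring=40,
        linkage_groups=[
            LinkageGroupSpec("chrA", (1.0,)),
            LinkageGroupSpec("chrB", (0.8,)),
            LinkageGroupSpec("chrC", (0.5, 0.6)),
        ],
        markers_per_group=20,
        seed=7,
    )
    return simulate_family(config)


def make_matrix(rows: list[dict], n_offspring: int) -> GenotypeMatrix:
    """Build a GenotypeMatrix from explicit per-locus dicts.

    Each row dict needs ``dam``, ``sire`` and ``offspring`` (a list of
    genotype strings, padded/truncated to ``n_offspring``); optional
    ``linkage_group``, ``position``, ``n_snps_in_tag``.
    """
    loci_rows, dam, sire, off = [], [], [], []
    for i, row in enumerate(rows):
        loci_rows.append(
            {
                "locus_id": row.get("locus_id", f"M{i + 1:05d}"),
                "linkage_group": row.get("linkage_group", "LG1"),
                "position": row.get("position", (i + 1) * 1000),
                "n_snps_in_tag": row.get("n_snps_in_tag", 1),
            }
        )
        dam.append(row["dam"])
        sire.append(row["sire"])
        calls = list(row["offspring"])
        if len(calls) < n_offspring:
            calls = calls + [calls[-1]] * (n_offspring - len(calls))
        off.append(calls[:n_offspring])
    loci = pd.DataFrame(loci_rows).set_index("locus_id")
    return GenotypeMatrix(
        loci=loci,
        dam=pd.Series(dam, index=loci.index),
        sire=pd.Series(sire, index=loci.index),
        offspring=pd.DataFrame(
            off, index=loci.index, columns=[f"off{j + 1:03d}" for j in range(n_offspring)]
        ),
    )


def published_style_candidate_set(n_offspring: int = 79) -> GenotypeMatrix:
    """1551-locus candidate set with the canonical removal structure.

    804 clean dam-informative loci, 687 dam-homozygous, 8 with progeny
    MAF < 0.4, and 52 with both parental genotypes missing.
    """
    rows = []
    # 804 female-informative loci passing everything (MAF ~ 0.49)
    passing = ["AB"] * 40 + ["AA"] * 20 + ["BB"] * 19
    for _ in range(804):
        rows.append({"dam": "AB", "sire": "AA", "offspring": passing})
    # 687 dam-homozygous loci
    for _ in range(687):
        rows.append({"dam": "AA", "sire": "AB", "offspring": ["AA"] * n_offspring})
    # 8 loci failing the progeny MAF < 0.4 cut
    skewed = ["AB"] * 5 + ["AA"] * 74
    for _ in range(8):
        rows.append({"dam": "AB", "sire": "AA", "offspring": skewed})
    # 52 loci with both parental genotypes missing
    for _ in range(52):
        rows.append({"dam": MISSING, "sire": MISSING, "offspring": ["AB"] * n_offspring})
    rng = np.random.default_rng(2024)
    order = rng.permutation(len(rows))
    return make_matrix([rows[i] for i in order], n_offspring)


@pytest.fixture(scope="session")
def candidate_set():
    return published_style_candidate_set()
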