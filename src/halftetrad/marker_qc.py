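"""Parental-informativeness classification and the marker filter cascade.

For gene-centromere mapping only dam-heterozygous ("female-informative")
loci are usable, while the paternal-contamination screen relies on loci
where the sire carries alleles the dam lacks. Both classifications are
assigned here, together with the fixed QC cascade that reduces a raw
candidate SNP set to the female-informative mapping panel:

1. drop loci from ddRAD tags with more than ``max_snps_per_tag`` SNPs;
2. drop loci missing either parental genotype;
3. drop loci typed in fewer than ``min_offspring_presence`` of offspring
   (threshold inclusive: exactly 75% presence is retained);
4. drop dam-homozygous loci (non-informative for the female map);
5. drop loci whose progeny minor-allele frequency is below ``min_maf``
   (strict: exactly 0.4 is retained).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from halftetrad.genotypes import MISSING, GenotypeMatrix, alleles, is_het, is_missing


class Informativeness(str, Enum):
    DAM_INFORMATIVE = "dam_informative"
    SIRE_ONE_ALLELE = "sire_one_allele"
    SIRE_BOTH_ALLELES = "sire_both_alleles"
    UNINFORMATIVE = "uninformative"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class InformativenessFlags:
    """Dam and sire informativeness assigned independently.

    A locus can be informative for both parents at once (dam heterozygous
    AND sire carrying private alleles); the female map consumes the dam
    flag, the paternal screen the sire class.
    """

    dam_informative: bool
    sire_class: Informativeness  # SIRE_ONE/BOTH or UNINFORMATIVE/UNCLASSIFIABLE
    unclassifiable: bool = False

    @property
    def primary(self) -> Informativeness:
        """Single-label summary, dam taking precedence over sire."""
        if self.unclassifiable:
            return Informativeness.UNCLASSIFIABLE
        if self.dam_informative:
            return Informativeness.DAM_INFORMATIVE
        if self.sire_class in (Informativeness.SIRE_ONE_ALLELE, Informativeness.SIRE_BOTH_ALLELES):
            return self.sire_class
        return Informativeness.UNINFORMATIVE


def classify_informativeness(dam_gt: str, sire_gt: str) -> InformativenessFlags:
    """Classify a locus by which parent's alleles make it informative.

    The sire class counts sire allele *copies* absent from the dam
    genotype: one copy private -> ``sire_one_allele``; both copies private
    -> ``sire_both_alleles``. A missing dam genotype makes the locus
    unclassifiable (neither flag can be evaluated); a missing sire with a
    typed dam still yields the dam flag.
    """
    if is_missing(dam_gt) and is_missing(sire_gt):
        return InformativenessFlags(False, Informativeness.UNCLASSIFIABLE, unclassifiable=True)
    if is_missing(dam_gt):
        return InformativenessFlags(False, Informativeness.UNCLASSIFIABLE, unclassifiable=True)
    dam_alleles = set(alleles(dam_gt))
    dam_flag = is_het(dam_gt)
    if is_missing(sire_gt):
        sire_class = Informativeness.UNCLASSIFIABLE
    else:
        n_private = sum(a not in dam_alleles for a in alleles(sire_gt))
        sire_class = {
            0: Informativeness.UNINFORMATIVE,
            1: Informativeness.SIRE_ONE_ALLELE,
            2: Informativeness.SIRE_BOTH_ALLELES,
        }[n_private]
    return InformativenessFlags(dam_flag, sire_class)


def classify_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus informativeness table (dam flag, sire class, primary)."""
    rows = []
    for locus_id in matrix.locus_ids:
        flags = classify_informativeness(matrix.dam[locus_id], matrix.sire[locus_id])
        rows.append(
            {
                "locus_id": locus_id,
                "dam_informative": flags.dam_informative,
                "sire_class": flags.sire_class.value,
                "primary": flags.primary.value,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def progeny_maf(calls: Iterable[str]) -> float:
    """Minor-allele frequency over non-missing progeny calls.

    The second-most-frequent allele's frequency (0.0 if monomorphic); by
    construction always in [0, 0.5]. Raises if every call is missing.
    """
    counts: Counter[str] = Counter()
    for gt in calls:
        if is_missing(gt):
            continue
        a, b = alleles(gt)
        counts[a] += 1
        counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no non-missing progeny calls")
    ranked = counts.most_common()
    if len(ranked) < 2:
        return 0.0
    return ranked[1][1] / total


@dataclass
class FilterReport:
    """Ordered per-step removal accounting for the QC cascade."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (name, removed, remaining)

    def add(self, name: str, removed: int) -> None:
        remaining = (self.steps[-1][2] if self.steps else self.initial) - removed
        self.steps.append((name, removed, remaining))

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    @property
    def total_removed(self) -> int:
        return sum(r for _, r, _ in self.steps)

    def removed(self, name: str) -> int:
        for step, n, _ in self.steps:
            if step == name:
                return n
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = [f"initial loci\t{self.initial}"]
        lines += [f"{name}\t-{removed}\t{remaining}" for name, removed, remaining in self.steps]
        return "\n".join(lines)


#: cascade step names in their fixed order
CASCADE_STEPS = (
    "snps_per_tag",
    "parent_missing",
    "offspring_presence",
    "dam_homozygous",
    "low_maf",
)


def apply_filter_cascade(
    matrix: GenotypeMatrix,
    max_snps_per_tag: int = 3,
    min_offspring_presence: float = 0.75,
    min_maf: float = 0.4,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the fixed five-step QC cascade and account for every removal.

    Returns the surviving female-informative matrix and a
    :class:`FilterReport` whose per-step counts always satisfy
    ``initial == final + sum(removed)``.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    if not 0.0 <= min_offspring_presence <= 1.0:
        raise ValueError("min_offspring_presence must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")

    report = FilterReport(initial=matrix.n_loci)
    current = matrix

    # 1. tag complexity
    keep = current.loci["n_snps_in_tag"] <= max_snps_per_tag
    report.add("snps_per_tag", int((~keep).sum()))
    current = current.subset(current.locus_ids[keep])

    # 2. parental genotypes present
    keep = ~(current.dam.eq(MISSING) | current.sire.eq(MISSING))
    report.add("parent_missing", int((~keep).sum()))
    current = current.subset(current.locus_ids[keep])

    # 3. offspring presence (inclusive threshold)
    present = current.offspring.ne(MISSING).sum(axis=1) / current.n_offspring
    keep = present >= min_offspring_presence
    report.add("offspring_presence", int((~keep).sum()))
    current = current.subset(current.locus_ids[keep])

    # 4. dam heterozygous only
    keep = current.dam.map(lambda gt: is_het(gt))
    report.add("dam_homozygous", int((~keep).sum()))
    current = current.subset(current.locus_ids[keep])

    # 5. progeny minor-allele frequency (strict cut below threshold);
    # a locus with no scorable progeny call cannot pass
    def _maf(row: pd.Series) -> float:
        try:
            return progeny_maf(row)
        except ValueError:
            return -1.0

    mafs = current.offspring.apply(_maf, axis=1)
    keep = mafs >= min_maf
    report.add("low_maf", int((~keep).sum()))
    current = current.subset(current.locus_ids[keep])

    return current, report
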