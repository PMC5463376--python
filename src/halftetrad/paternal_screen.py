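"""Paternal-contamination screen via male-specific alleles.

In a true gynogenetic family the irradiated sperm contributes no genome,
so any allele carried by the sire but absent from the dam ("male-specific")
must never appear in an offspring. The screen enumerates such alleles at
every sire-informative locus and counts, per offspring, the loci at which
a male-specific allele is observed; a single whole-genome paternal
chromatid lights up essentially every male-informative locus, while
genotyping artefacts produce isolated hits that a configurable threshold
can tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from halftetrad.genotypes import GenotypeMatrix, alleles, is_missing
from halftetrad.marker_qc import Informativeness, classify_informativeness


@dataclass(frozen=True)
class MaleSpecificLocus:
    locus_id: str
    private_alleles: frozenset[str]
    sire_class: Informativeness  # SIRE_ONE_ALLELE or SIRE_BOTH_ALLELES


@dataclass
class PaternalScreenResult:
    """Family-level verdict plus per-offspring evidence.

    ``counts`` maps offspring id to the number of male-informative loci at
    which it carries a male-specific allele; ``tested`` to the number of
    male-informative loci with a non-missing call. Offspring with no
    testable locus are listed ``untestable`` rather than counted clean.
    """

    male_informative: list[MaleSpecificLocus]
    n_skipped_missing_parent: int
    counts: dict[str, int]
    tested: dict[str, int]
    flag_threshold: int
    flagged: list[str] = field(default_factory=list)
    untestable: list[str] = field(default_factory=list)
    warning: str | None = None

    @property
    def verdict(self) -> str:
        return "contaminated" if self.flagged else "clean"

    @property
    def n_one_allele(self) -> int:
        return sum(m.sire_class is Informativeness.SIRE_ONE_ALLELE for m in self.male_informative)

    @property
    def n_both_alleles(self) -> int:
        return sum(m.sire_class is Informativeness.SIRE_BOTH_ALLELES for m in self.male_informative)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "offspring": off,
                "male_specific_hits": self.counts.get(off, 0),
                "loci_tested": self.tested.get(off, 0),
                "status": "untestable"
                if off in self.untestable
                else ("flagged" if off in self.flagged else "clean"),
            }
            for off in self.counts
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# male_informative_loci={len(self.male_informative)}\n")
            fh.write(f"# one_allele={self.n_one_allele}\tboth_alleles={self.n_both_alleles}\n")
            fh.write(f"# skipped_missing_parent={self.n_skipped_missing_parent}\n")
            fh.write(f"# flag_threshold={self.flag_threshold}\n")
            fh.write(f"# verdict={self.verdict}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def find_male_specific_alleles(matrix: GenotypeMatrix) -> tuple[list[MaleSpecificLocus], int]:
    """Enumerate sire-private alleles per locus.

    Returns the male-informative loci (allele sets present in the sire and
    absent from the dam) and the number of loci skipped because a parental
    genotype was missing.
    """
    found: list[MaleSpecificLocus] = []
    skipped = 0
    for locus_id in matrix.locus_ids:
        dam_gt, sire_gt = matrix.dam[locus_id], matrix.sire[locus_id]
        if is_missing(dam_gt) or is_missing(sire_gt):
            skipped += 1
            continue
        flags = classify_informativeness(dam_gt, sire_gt)
        if flags.sire_class in (Informativeness.SIRE_ONE_ALLELE, Informativeness.SIRE_BOTH_ALLELES):
            dam_set = set(alleles(dam_gt))
            private = frozenset(a for a in alleles(sire_gt) if a not in dam_set)
            found.append(MaleSpecificLocus(str(locus_id), private, flags.sire_class))
    return found, skipped


def screen_offspring(
    matrix: GenotypeMatrix,
    male_specific: list[MaleSpecificLocus] | None = None,
    flag_threshold: int = 1,
) -> PaternalScreenResult:
    """Count male-specific alleles per offspring and call the family verdict.

    An offspring is flagged when it carries male-specific alleles at
    ``flag_threshold`` or more loci (default 1: any hit is reportable;
    raise it to tolerate known genotyping-error rates). With no
    male-informative loci at all the verdict is vacuously clean and a
    warning is attached.
    """
    if flag_threshold < 1:
        raise ValueError("flag_threshold must be >= 1")
    skipped = 0
    if male_specific is None:
        male_specific, skipped = find_male_specific_alleles(matrix)

    counts = {off: 0 for off in matrix.offspring_ids}
    tested = {off: 0 for off in matrix.offspring_ids}
    for locus in male_specific:
        if locus.locus_id not in matrix.offspring.index:
            continue
        row = matrix.offspring.loc[locus.locus_id]
        for off, gt in row.items():
            if is_missing(gt):
                continue
            tested[off] += 1
            if any(a in locus.private_alleles for a in alleles(gt)):
                counts[off] += 1

    untestable = [off for off in matrix.offspring_ids if male_specific and tested[off] == 0]
    flagged = [off for off in matrix.offspring_ids if counts[off] >= flag_threshold]
    warning = None
    if not male_specific:
        warning = "no male-informative loci: verdict is vacuously clean"
        untestable = list(matrix.offspring_ids)
    return PaternalScreenResult(
        male_informative=male_specific,
        n_skipped_missing_parent=skipped,
        counts=counts,
        tested=tested,
        flag_threshold=flag_threshold,
        flagged=flagged,
        untestable=untestable,
        warning=warning,
    )
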