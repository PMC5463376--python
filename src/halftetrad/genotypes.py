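"""Genotype matrix container and TSV/VCF input-output.

A :class:`GenotypeMatrix` holds biallelic (occasionally tri-/tetra-allelic)
genotype calls for one dam, one sire and N offspring at physically
positioned loci. It is the currency passed between every pipeline stage.

Genotype calls are two-character strings of single-letter alleles in sorted
order (``"AB"`` not ``"BA"``); missing calls are the string ``"NA"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = "NA"

#: metadata columns preceding the genotype columns in the TSV dialect
META_COLUMNS = ["locus_id", "linkage_group", "position", "n_snps_in_tag"]


def genotype(a: str, b: str) -> str:
    """Build a normalised (allele-sorted) genotype string."""
    return a + b if a <= b else b + a


def alleles(gt: str) -> tuple[str, str]:
    """Return the two allele characters of a non-missing call."""
    if gt == MISSING:
        raise ValueError("missing genotype has no alleles")
    if len(gt) != 2:
        raise ValueError(f"malformed genotype {gt!r}")
    return gt[0], gt[1]


def is_missing(gt: str) -> bool:
    return gt == MISSING


def is_het(gt: str) -> bool:
    """True for a heterozygous call; raises on missing."""
    a, b = alleles(gt)
    return a != b


@dataclass
class GenotypeMatrix:
    """Loci x individuals genotype table with locus metadata.

    Parameters
    ----------
    loci
        Frame indexed by ``locus_id`` with columns ``linkage_group``,
        ``position`` (1-based int) and ``n_snps_in_tag``.
    dam, sire
        Parental genotype calls per locus (``MISSING`` allowed).
    offspring
        Frame indexed by ``locus_id``, one column per offspring.
    meta
        Free-form provenance (seed, generator parameters), echoed to file
        headers.
    """

    loci: pd.DataFrame
    dam: pd.Series
    sire: pd.Series
    offspring: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.loci.index
        for name, obj in (("dam", self.dam), ("sire", self.sire), ("offspring", self.offspring)):
            if not obj.index.equals(idx):
                raise ValueError(f"{name} index does not match loci index")
        missing_cols = set(("linkage_group", "position")) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci frame lacks columns: {sorted(missing_cols)}")
        if "n_snps_in_tag" not in self.loci.columns:
            self.loci = self.loci.assign(n_snps_in_tag=1)

    # -- basic accessors ---------------------------------------------------
    @property
    def locus_ids(self) -> pd.Index:
        return self.loci.index

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.offspring.columns)

    @property
    def n_offspring(self) -> int:
        return self.offspring.shape[1]

    def subset(self, locus_ids: Sequence[str] | pd.Index) -> "GenotypeMatrix":
        """Restrict to the given loci (order preserved as given)."""
        return GenotypeMatrix(
            loci=self.loci.loc[locus_ids],
            dam=self.dam.loc[locus_ids],
            sire=self.sire.loc[locus_ids],
            offspring=self.offspring.loc[locus_ids],
            meta=dict(self.meta),
        )

    def groups(self) -> list[str]:
        """Linkage groups in order of first appearance."""
        return list(dict.fromkeys(self.loci["linkage_group"]))

    def group_view(self, group: str) -> "GenotypeMatrix":
        """Loci of one linkage group, sorted by physical position."""
        ids = (
            self.loci[self.loci["linkage_group"] == group]
            .sort_values("position")
            .index
        )
        return self.subset(ids)

    def het_status(self) -> pd.DataFrame:
        """Offspring call status: 1 het, 0 hom, -1 missing."""
        def code(gt: str) -> int:
            if is_missing(gt):
                return -1
            return 1 if is_het(gt) else 0

        return self.offspring.map(code)

    # -- TSV dialect -------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the tab-separated matrix dialect.

        Header ``#`` lines echo the provenance metadata (seed included),
        then one header row and one row per locus.
        """
        path = Path(path)
        with path.open("w") as fh:
            for key, value in self.meta.items():
                fh.write(f"# {key}={value}\n")
            table = self.to_frame()
            table.to_csv(fh, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: metadata columns, dam, sire, offspring columns."""
        out = self.loci.reset_index()
        if "index" in out.columns:
            out = out.rename(columns={"index": "locus_id"})
        out = out[[c for c in META_COLUMNS if c in out.columns]]
        out["dam"] = self.dam.values
        out["sire"] = self.sire.values
        for col in self.offspring.columns:
            out[col] = self.offspring[col].values
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        path = Path(path)
        meta: dict = {}
        lines = []
        with path.open() as fh:
            for line in fh:
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if "=" in body:
                        key, _, value = body.partition("=")
                        meta[key.strip()] = value.strip()
                else:
                    lines.append(line)
        table = pd.read_csv(
            io.StringIO("".join(lines)), sep="\t", dtype=str, keep_default_na=False
        )
        return cls.from_frame(table, meta=meta)

    @classmethod
    def from_frame(cls, table: pd.DataFrame, meta: dict | None = None) -> "GenotypeMatrix":
        table = table.copy()
        if "locus_id" not in table.columns:
            raise ValueError("genotype table lacks a locus_id column")
        table = table.set_index("locus_id")
        loci_cols = [c for c in ("linkage_group", "position", "n_snps_in_tag") if c in table.columns]
        loci = table[loci_cols].copy()
        loci["position"] = loci["position"].astype(int)
        if "n_snps_in_tag" in loci.columns:
            loci["n_snps_in_tag"] = loci["n_snps_in_tag"].astype(int)
        off_cols = [c for c in table.columns if c not in loci_cols + ["dam", "sire"]]
        return cls(
            loci=loci,
            dam=table["dam"].astype(str),
            sire=table["sire"].astype(str),
            offspring=table[off_cols].astype(str),
            meta=meta or {},
        )

    # -- VCF ---------------------------------------------------------------
    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with GT fields and contig headers.

        Sample order: DAM, SIRE, then offspring. Loci whose alleles are not
        plain bases cannot be represented and raise.
        """
        path = Path(path)
        contigs: dict[str, int] = {}
        for group, pos in zip(self.loci["linkage_group"], self.loci["position"]):
            contigs[group] = max(contigs.get(group, 0), int(pos))
        with path.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=halftetrad\n")
            for key, value in self.meta.items():
                fh.write(f"##halftetrad_{key}={value}\n")
            fh.write('##INFO=<ID=NSNP,Number=1,Type=Integer,Description="SNPs in source ddRAD tag">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length + 1}>\n")
            samples = ["DAM", "SIRE"] + self.offspring_ids
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for locus_id, row in self.loci.iterrows():
                calls = [self.dam[locus_id], self.sire[locus_id]] + list(self.offspring.loc[locus_id])
                allele_order: list[str] = []
                for gt in calls:
                    if is_missing(gt):
                        continue
                    for a in alleles(gt):
                        if a not in allele_order:
                            allele_order.append(a)
                if not allele_order:
                    allele_order = ["N"]
                for a in allele_order:
                    if a not in "ACGTN":
                        raise ValueError(f"allele {a!r} at {locus_id} is not a nucleotide; use the TSV dialect")
                ref = allele_order[0]
                alt = ",".join(allele_order[1:]) if len(allele_order) > 1 else "."
                index = {a: i for i, a in enumerate(allele_order)}

                def vcf_gt(gt: str) -> str:
                    if is_missing(gt):
                        return "./."
                    a, b = alleles(gt)
                    i, j = sorted((index[a], index[b]))
                    return f"{i}/{j}"

                fields = [
                    str(row["linkage_group"]),
                    str(int(row["position"])),
                    str(locus_id),
                    ref,
                    alt,
                    ".",
                    "PASS",
                    f"NSNP={int(row.get('n_snps_in_tag', 1))}",
                    "GT",
                ] + [vcf_gt(gt) for gt in calls]
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a VCF 4.2 whose first two samples are dam then sire."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        if len(samples) < 3:
            raise ValueError("VCF must contain dam, sire and at least one offspring sample")
        rows = []
        dam_calls, sire_calls, off_calls = [], [], []
        for variant in vcf:
            site_alleles = [variant.REF] + list(variant.ALT)

            def decode(gt_idx: Sequence[int]) -> str:
                i, j = gt_idx[0], gt_idx[1]
                if i < 0 or j < 0:
                    return MISSING
                return genotype(site_alleles[i], site_alleles[j])

            calls = [decode(g) for g in variant.genotypes]
            nsnp = variant.INFO.get("NSNP")
            rows.append(
                {
                    "locus_id": variant.ID or f"{variant.CHROM}_{variant.POS}",
                    "linkage_group": variant.CHROM,
                    "position": variant.POS,
                    "n_snps_in_tag": int(nsnp) if nsnp is not None else 1,
                }
            )
            dam_calls.append(calls[0])
            sire_calls.append(calls[1])
            off_calls.append(calls[2:])
        vcf.close()
        loci = pd.DataFrame(rows).set_index("locus_id")
        return cls(
            loci=loci,
            dam=pd.Series(dam_calls, index=loci.index, name="dam"),
            sire=pd.Series(sire_calls, index=loci.index, name="sire"),
            offspring=pd.DataFrame(off_calls, index=loci.index, columns=samples[2:]),
        )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (``.vcf``/``.vcf.gz``) or TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return GenotypeMatrix.from_vcf(path)
    return GenotypeMatrix.from_tsv(path)
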