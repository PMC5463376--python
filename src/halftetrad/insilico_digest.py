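"""In-silico double-digest RAD fragment prediction.

Predicts the fragments a ddRAD library would sample from a reference
sequence: cut the sequence with a rare and a common restriction enzyme,
keep fragments flanked by exactly one rare and one common cut, and apply
the size-selection window (insert length between cut positions, adaptors
excluded). Defaults are the SbfI (CCTGCA^GG) / SphI (GCATG^C) pair with a
320-590 bp window.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

RARE, COMMON, CONTIG_END = "rare", "common", "contig_end"


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition motif (IUPAC) and cut offset.

    ``cut_offset`` is the number of motif bases left of the cut on the
    forward strand (SbfI CCTGCA^GG -> offset 6).
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        if not motif or any(b not in IUPAC for b in motif):
            raise ValueError(f"invalid IUPAC motif {self.motif!r}")
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError("cut offset outside motif")
        object.__setattr__(self, "motif", motif)

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.motif).reverse_complement()) == self.motif

    def _regex(self, motif: str) -> re.Pattern:
        # literal N in the sequence never matches: classes contain ACGT only.
        # Lookahead so overlapping occurrences (e.g. GCATGCATGC) all count.
        body = "".join(f"[{IUPAC[b]}]" for b in motif)
        return re.compile(f"(?={body})")

    def cut_positions(self, sequence: str) -> list[int]:
        """0-based between-base cut coordinates on the forward sequence.

        Palindromic motifs are scanned on the forward strand only; other
        motifs are scanned on both strands, reverse-strand cuts mapped
        back to forward coordinates.
        """
        sequence = sequence.upper()
        pattern = self._regex(self.motif)
        cuts = {m.start() + self.cut_offset for m in pattern.finditer(sequence)}
        if not self.is_palindromic:
            rc = str(Seq(self.motif).reverse_complement())
            rc_pattern = self._regex(rc)
            offset_rc = len(self.motif) - self.cut_offset
            cuts.update(m.start() + offset_rc for m in rc_pattern.finditer(sequence))
        return sorted(cuts)


SBFI = Enzyme("SbfI", "CCTGCAGG", 6)
SPHI = Enzyme("SphI", "GCATGC", 5)


@dataclass(frozen=True)
class DigestConfig:
    rare: Enzyme = SBFI
    common: Enzyme = SPHI
    min_bp: int = 320
    max_bp: int = 590

    def __post_init__(self) -> None:
        if self.min_bp > self.max_bp:
            raise ValueError("size window min exceeds max")


@dataclass(frozen=True)
class Fragment:
    """One digestion fragment, 0-based half-open [start, end)."""

    contig: str
    start: int
    end: int
    left_type: str   # rare | common | contig_end (plus "rare+common" on co-cut)
    right_type: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_rare_common(self) -> bool:
        left = set(self.left_type.split("+"))
        right = set(self.right_type.split("+"))
        if CONTIG_END in left or CONTIG_END in right:
            return False
        return (RARE in left and COMMON in right) or (COMMON in left and RARE in right)


def digest_sequence(
    sequence: str, config: DigestConfig = DigestConfig(), contig: str = "seq"
) -> list[Fragment]:
    """Cut one contig with both enzymes and tile it into fragments.

    Fragments are the intervals between consecutive cut positions (contig
    ends included, labelled ``contig_end``); their lengths always sum to
    the contig length.
    """
    rare_cuts = config.rare.cut_positions(sequence)
    common_cuts = config.common.cut_positions(sequence)
    labelled: dict[int, set[str]] = {0: {CONTIG_END}, len(sequence): {CONTIG_END}}
    for cut in rare_cuts:
        labelled.setdefault(cut, set()).add(RARE)
    for cut in common_cuts:
        labelled.setdefault(cut, set()).add(COMMON)
    # a cut exactly at a contig end is still an enzyme end
    for end in (0, len(sequence)):
        if len(labelled[end]) > 1:
            labelled[end].discard(CONTIG_END)
    positions = sorted(labelled)
    fragments = []
    for a, b in zip(positions, positions[1:]):
        fragments.append(
            Fragment(
                contig=contig,
                start=a,
                end=b,
                left_type="+".join(sorted(labelled[a])),
                right_type="+".join(sorted(labelled[b])),
            )
        )
    return fragments


def select_fragments(
    fragments: Iterable[Fragment], config: DigestConfig = DigestConfig()
) -> tuple[list[Fragment], dict]:
    """Apply the ddRAD selection: one rare + one common end, length in window.

    Returns the selected fragments and a summary with the total fragment
    count, the rare/common-ended count, and the post-size-selection count.
    """
    fragments = list(fragments)
    rare_common = [f for f in fragments if f.is_rare_common]
    selected = [f for f in rare_common if config.min_bp <= f.length <= config.max_bp]
    summary = {
        "n_fragments": len(fragments),
        "n_rare_common": len(rare_common),
        "n_selected": len(selected),
        "min_bp": config.min_bp,
        "max_bp": config.max_bp,
    }
    return selected, summary


def digest_fasta(
    path: str | Path, config: DigestConfig = DigestConfig()
) -> Iterator[Fragment]:
    """Digest every contig of a (optionally gzipped) FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            yield from digest_sequence(str(record.seq), config, contig=record.id)


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Fragment table with 1-based inclusive coordinates."""
    return pd.DataFrame(
        [
            {
                "contig": f.contig,
                "start": f.start + 1,
                "end": f.end,
                "length": f.length,
                "left_type": f.left_type,
                "right_type": f.right_type,
            }
            for f in fragments
        ],
        columns=["contig", "start", "end", "length", "left_type", "right_type"],
    )


def write_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Selected-fragment BED (0-based half-open, as BED requires)."""
    with Path(path).open("w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\tfrag{i + 1}\t{f.length}\t.\n")
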