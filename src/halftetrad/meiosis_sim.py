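"""Meiotic-gynogenesis simulator with tetrad ground truth.

Models one female meiosis per offspring and chromosome: a bivalent of four
chromatids (two sisters per homolog) receives chiasmata along each arm,
each chiasma exchanging the segments distal to its position between one
chromatid of each homolog (non-sister pair chosen uniformly and
independently per chiasma — no chromatid interference). Diploidy is then
restored by second-polar-body retention: one meiosis-I product (a sister
pair sharing a centromere) is kept whole, so the offspring is heterozygous
at a marker exactly when the two retained chromatids disagree there.

Two chiasma models are provided: ``obligate_one`` (exactly one chiasma per
arm, the complete-interference limit in which marker-centromere distance is
``100*(y/2)`` cM and a telomeric marker approaches 100% heterozygosity) and
``poisson`` (Poisson-many chiasmata at rate ``chiasma_rate`` per arm, the
no-interference null whose telomeric heterozygote frequency converges to
2/3). A mitotic-gynogenetic control mode retains a single doubled
chromatid and is homozygous everywhere.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from halftetrad.genotypes import MISSING, GenotypeMatrix, genotype

ChiasmaModel = Literal["obligate_one", "poisson"]
Retention = Literal["second_polar_body", "mitotic"]


# ---------------------------------------------------------------------------
# tetrad mechanics
# ---------------------------------------------------------------------------

@dataclass
class Chromatid:
    """One chromatid as its centromere phase plus distal switch points.

    The maternal allele phase at physical position ``x`` (distance from the
    centromere) is the centromere phase toggled once per switch point at or
    proximal to ``x``.
    """

    centromere_phase: int
    switches: list[float] = field(default_factory=list)

    def phase_at(self, x: float) -> int:
        return self.centromere_phase ^ (bisect_right(self.switches, x) & 1)

    def phases_at(self, xs: Sequence[float]) -> np.ndarray:
        return np.array([self.phase_at(x) for x in xs], dtype=np.int8)


@dataclass
class Tetrad:
    """Four chromatids of a bivalent; sisters are (0,1) and (2,3).

    ``chiasmata`` records ``(position, chromatid_of_homolog_0,
    chromatid_of_homolog_1)`` in the order applied (proximal to distal).
    """

    chromatids: list[Chromatid]
    arm_length: float
    chiasmata: list[tuple[float, int, int]] = field(default_factory=list)

    def sister_pair(self, k: int) -> tuple[Chromatid, Chromatid]:
        return self.chromatids[2 * k], self.chromatids[2 * k + 1]


def _exchange(a: Chromatid, b: Chromatid, x: float) -> None:
    """Swap the segments distal to ``x`` between chromatids ``a`` and ``b``."""
    pa, pb = a.phase_at(x), b.phase_at(x)
    a_low = [s for s in a.switches if s <= x]
    b_low = [s for s in b.switches if s <= x]
    a_high = [s for s in a.switches if s > x]
    b_high = [s for s in b.switches if s > x]
    joint = [x] if pa != pb else []
    a.switches = a_low + joint + b_high
    b.switches = b_low + joint + a_high


def simulate_tetrad(
    arm_length: float,
    chiasma_model: ChiasmaModel = "obligate_one",
    rng: np.random.Generator | None = None,
    chiasma_rate: float = 1.0,
) -> Tetrad:
    """Simulate chiasma formation along one arm of a four-chromatid bivalent.

    Chiasma positions are uniform on ``(0, arm_length)``; each chiasma
    exchanges distal segments between a uniformly chosen chromatid of each
    homolog, independently per chiasma (no chromatid interference).

    Parameters
    ----------
    arm_length
        Physical arm length in arbitrary units; must be positive.
    chiasma_model
        ``"obligate_one"`` for exactly one chiasma per arm, ``"poisson"``
        for a Poisson(``chiasma_rate``) number.
    rng
        NumPy generator; a fresh default generator if omitted.
    chiasma_rate
        Expected chiasmata per arm (poisson model only); must be positive.
    """
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if chiasma_model == "obligate_one":
        n_chiasmata = 1
    elif chiasma_model == "poisson":
        if chiasma_rate <= 0:
            raise ValueError("chiasma_rate must be positive for the poisson model")
        n_chiasmata = int(rng.poisson(chiasma_rate))
    else:
        raise ValueError(f"unknown chiasma model {chiasma_model!r}")

    tetrad = Tetrad(
        chromatids=[Chromatid(0), Chromatid(0), Chromatid(1), Chromatid(1)],
        arm_length=arm_length,
    )
    positions = np.sort(rng.uniform(0.0, arm_length, size=n_chiasmata))
    for x in positions:
        i = int(rng.integers(2))        # chromatid of homolog 0
        j = int(rng.integers(2)) + 2    # chromatid of homolog 1
        _exchange(tetrad.chromatids[i], tetrad.chromatids[j], float(x))
        tetrad.chiasmata.append((float(x), i, j))
    return tetrad


def retain_second_polar_body(
    tetrad: Tetrad, rng: np.random.Generator | None = None
) -> tuple[Chromatid, Chromatid]:
    """Pick one meiosis-I product uniformly and keep both of its chromatids.

    This is the MII-restitution event of meiotic gynogenesis: the secondary
    oocyte and its second polar body stay together, so the offspring
    genotype at a marker is heterozygous iff the two retained chromatids
    carry different maternal phases there.
    """
    if rng is None:
        rng = np.random.default_rng()
    return tetrad.sister_pair(int(rng.integers(2)))


def distal_het_frequency(
    n_meioses: int,
    chiasma_model: ChiasmaModel = "poisson",
    chiasma_rate: float = 5.0,
    marker_fraction: float = 1.0,
    arm_length: float = 1.0,
    seed: int | None = None,
) -> float:
    """Heterozygote frequency at one marker over many simulated meioses.

    The marker sits at ``marker_fraction`` of the arm measured from the
    centromere (1.0 = arm tip). Runs the full tetrad + polar-body-retention
    mechanism per meiosis.
    """
    rng = np.random.default_rng(seed)
    x = marker_fraction * arm_length
    het = 0
    for _ in range(n_meioses):
        tetrad = simulate_tetrad(arm_length, chiasma_model, rng, chiasma_rate)
        a, b = retain_second_polar_body(tetrad, rng)
        het += a.phase_at(x) != b.phase_at(x)
    return het / n_meioses


def expected_sds_probability(
    marker_fraction: float, chiasma_model: ChiasmaModel, chiasma_rate: float = 1.0
) -> float:
    """Second-division-segregation (heterozygote) probability at a marker.

    Under ``obligate_one`` with a uniform chiasma position the probability
    equals the marker's fractional position ``m``: the single chiasma lands
    proximal to the marker with probability ``m`` and any proximal chiasma
    makes the retained pair heterozygous distally. Under the poisson model
    with no chromatid interference the closed form is
    ``(2/3) * (1 - exp(-3*mu/2))`` with ``mu = rate * m`` the mean number of
    proximal chiasmata, saturating at the classical 2/3 telomeric limit.
    """
    if not 0.0 <= marker_fraction <= 1.0:
        raise ValueError("marker_fraction must be in [0, 1]")
    if chiasma_model == "obligate_one":
        return marker_fraction
    if chiasma_model == "poisson":
        mu = chiasma_rate * marker_fraction
        return (2.0 / 3.0) * (1.0 - np.exp(-1.5 * mu))
    raise ValueError(f"unknown chiasma model {chiasma_model!r}")


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageGroupSpec:
    """One chromosome: a name and one or two arm lengths (physical units).

    One-armed groups put the centromere at group coordinate 0 and the
    telomere at the far end. Two-armed groups place the centromere at the
    junction of the two arms (coordinate ``arm_lengths[0]``), so the group
    coordinate runs telomere -> centromere -> telomere.
    """

    name: str
    arm_lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.arm_lengths) <= 2:
            raise ValueError("a linkage group has one or two arms")
        if any(length <= 0 for length in self.arm_lengths):
            raise ValueError("arm lengths must be positive")

    @property
    def span(self) -> float:
        return float(sum(self.arm_lengths))

    @property
    def centromere_coord(self) -> float:
        """Centromere position in group coordinates (0 for one-armed)."""
        return 0.0 if len(self.arm_lengths) == 1 else float(self.arm_lengths[0])


def default_linkage_groups() -> list[LinkageGroupSpec]:
    """24 chromosomes (2n = 48), three of them bi-armed.

    Mirrors the karyotype of the European seabass family this analysis was
    designed around: mostly acrocentric chromosomes plus a small number of
    clearly metacentric ones.
    """
    groups = []
    for i in range(1, 25):
        name = f"LG{i:02d}"
        if i in (14, 17, 24):
            groups.append(LinkageGroupSpec(name, (0.45, 0.65)))
        else:
            groups.append(LinkageGroupSpec(name, (1.0,)))
    return groups


@dataclass
class SimConfig:
    """Study design for one simulated gynogenetic family.

    Defaults reproduce the mapping-family design the package targets: 79
    meiotic-gynogenetic offspring, 24 linkage groups, a few tens of
    dam-heterozygous markers per group, exactly one chiasma per arm
    (complete interference) and clean genotyping.

    Parameters
    ----------
    n_offspring
        Family size (>= 1).
    linkage_groups
        Chromosome specs; default 24 groups, three bi-armed.
    markers_per_group
        Markers per linkage group (>= 2).
    chiasma_model, chiasma_rate
        ``obligate_one`` (default) or ``poisson`` with ``chiasma_rate``
        expected chiasmata per arm.
    genotyping_error_rate, missing_rate
        Per-offspring-call probabilities of a symmetric het<->hom flip and
        of a missing call; applied after segregation.
    sire_contamination_fraction
        Fraction of offspring that receive one paternal chromatid (one sire
        allele per locus) overriding one maternal chromatid.
    sire_one_allele_fraction, sire_both_alleles_fraction
        Fractions of loci where the sire carries one, or two, allele copies
        absent from the dam — the male-informative marker classes.
    marker_placement
        ``"even"`` spacing along each group or ``"uniform"`` random.
    retention
        ``"second_polar_body"`` (meiotic gynogenesis) or ``"mitotic"``
        (doubled single chromatid; fully homozygous control).
    seed
        Seed for all randomness; same seed, same matrix, bit for bit.
    """

    n_offspring: int = 79
    linkage_groups: list[LinkageGroupSpec] = field(default_factory=default_linkage_groups)
    markers_per_group: int = 34
    chiasma_model: ChiasmaModel = "obligate_one"
    chiasma_rate: float = 1.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    sire_contamination_fraction: float = 0.0
    sire_one_allele_fraction: float = 0.14
    sire_both_alleles_fraction: float = 0.08
    marker_placement: Literal["even", "uniform"] = "even"
    retention: Retention = "second_polar_body"
    seed: int = 0

    def validate(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.markers_per_group < 2:
            raise ValueError("every group needs at least 2 markers")
        if not self.linkage_groups:
            raise ValueError("at least one linkage group required")
        for rate_name in (
            "genotyping_error_rate",
            "missing_rate",
            "sire_contamination_fraction",
            "sire_one_allele_fraction",
            "sire_both_alleles_fraction",
        ):
            value = getattr(self, rate_name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1]")
        if self.sire_one_allele_fraction + self.sire_both_alleles_fraction > 1.0:
            raise ValueError("sire-informative fractions sum to more than 1")
        if self.chiasma_model == "poisson" and self.chiasma_rate <= 0:
            raise ValueError("chiasma_rate must be positive for the poisson model")
        if self.chiasma_model not in ("obligate_one", "poisson"):
            raise ValueError(f"unknown chiasma model {self.chiasma_model!r}")
        if self.retention not in ("second_polar_body", "mitotic"):
            raise ValueError(f"unknown retention mode {self.retention!r}")


@dataclass
class TetradTruth:
    """Ground truth of a simulated family.

    ``markers`` has one row per locus: arm index, physical distance from
    the centromere, fractional arm position, true second-division
    segregation probability and true marker-centromere distance (cM).
    ``chiasmata`` lists every chiasma (offspring, group, arm, position and
    the exchanged non-sister chromatid pair); ``retained`` gives the
    retained meiosis-I product per offspring and group; ``contaminated``
    names offspring that received a paternal chromatid.
    """

    markers: pd.DataFrame
    chiasmata: pd.DataFrame
    retained: pd.DataFrame
    contaminated: list[str]
    config: SimConfig

    def crossover_counts(self) -> pd.DataFrame:
        """True chiasma count per (offspring, group, arm)."""
        counts = (
            self.chiasmata.groupby(["offspring", "group", "arm"], sort=False)
            .size()
            .rename("n_chiasmata")
            .reset_index()
        )
        return counts

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# seed={self.config.seed}\n")
            fh.write(f"# chiasma_model={self.config.chiasma_model}\n")
            self.markers.to_csv(fh, sep="\t", index=False)


_BASES = np.array(list("ACGT"))


def _marker_coords(spec: LinkageGroupSpec, m: int, placement: str, rng: np.random.Generator) -> np.ndarray:
    if placement == "even":
        return np.linspace(0.0, spec.span, m)
    if placement == "uniform":
        return np.sort(rng.uniform(0.0, spec.span, size=m))
    raise ValueError(f"unknown marker placement {placement!r}")


def simulate_family(config: SimConfig) -> tuple[GenotypeMatrix, TetradTruth]:
    """Simulate a gynogenetic family and return genotypes plus ground truth.

    The dam is heterozygous at every locus. Offspring are produced arm by
    arm through :func:`simulate_tetrad` and (per chromosome, shared across
    both arms) :func:`retain_second_polar_body`; genotyping error and
    missingness are overlaid afterwards, and contaminated offspring — if
    requested — get one sire allele per locus in place of one maternal
    chromatid. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    offspring_ids = [f"off{i + 1:03d}" for i in range(config.n_offspring)]

    loci_rows = []
    truth_rows = []
    dam_calls: list[str] = []
    sire_calls: list[str] = []
    locus_allele_pairs: list[tuple[str, str]] = []  # (ref, alt) maternal alleles
    group_marker_ids: dict[str, list[int]] = {}
    group_marker_arm: dict[str, np.ndarray] = {}
    group_marker_dist: dict[str, np.ndarray] = {}

    locus_counter = 0
    for spec in config.linkage_groups:
        coords = _marker_coords(spec, config.markers_per_group, config.marker_placement, rng)
        cen = spec.centromere_coord
        arm_idx = (coords > cen).astype(int) if len(spec.arm_lengths) == 2 else np.zeros(len(coords), dtype=int)
        dist = np.abs(coords - cen)
        ids = []
        for coord, arm, d in zip(coords, arm_idx, dist):
            locus_counter += 1
            locus_id = f"L{locus_counter:05d}"
            ids.append(locus_counter - 1)
            position = int(round(coord * 1_000_000)) + 1
            # maternal ref/alt alleles; sire may draw from the other bases
            ref, alt = rng.choice(4, size=2, replace=False)
            others = [b for b in range(4) if b not in (ref, alt)]
            ref_a, alt_a = _BASES[ref], _BASES[alt]
            u = rng.random()
            if u < config.sire_both_alleles_fraction:
                sire_gt = genotype(_BASES[rng.choice(others)], _BASES[rng.choice(others)])
            elif u < config.sire_both_alleles_fraction + config.sire_one_allele_fraction:
                sire_gt = genotype(str(rng.choice([ref_a, alt_a])), _BASES[rng.choice(others)])
            else:
                shared = rng.choice([ref_a, alt_a], size=2)
                sire_gt = genotype(str(shared[0]), str(shared[1]))
            arm_length = spec.arm_lengths[arm]
            frac = min(1.0, d / arm_length)  # guard float overshoot at the tip
            loci_rows.append(
                {
                    "locus_id": locus_id,
                    "linkage_group": spec.name,
                    "position": position,
                    "n_snps_in_tag": 1,
                }
            )
            truth_rows.append(
                {
                    "locus_id": locus_id,
                    "linkage_group": spec.name,
                    "arm": int(arm),
                    "position": position,
                    "dist_from_centromere": float(d),
                    "arm_fraction": float(frac),
                    "true_sds_prob": 0.0
                    if config.retention == "mitotic"
                    else expected_sds_probability(frac, config.chiasma_model, config.chiasma_rate),
                    "true_distance_cM": 50.0 * frac
                    if config.chiasma_model == "obligate_one"
                    else 50.0 * config.chiasma_rate * frac,
                }
            )
            dam_calls.append(genotype(ref_a, alt_a))
            sire_calls.append(sire_gt)
            locus_allele_pairs.append((ref_a, alt_a))
        group_marker_ids[spec.name] = ids
        group_marker_arm[spec.name] = arm_idx
        group_marker_dist[spec.name] = dist

    n_loci = locus_counter
    # phases of the two transmitted chromatids at every locus x offspring
    phase_a = np.zeros((n_loci, config.n_offspring), dtype=np.int8)
    phase_b = np.zeros((n_loci, config.n_offspring), dtype=np.int8)
    chiasma_rows = []
    retained_idx = np.zeros((config.n_offspring, len(config.linkage_groups)), dtype=np.int8)

    for g, spec in enumerate(config.linkage_groups):
        ids = np.array(group_marker_ids[spec.name])
        arms = group_marker_arm[spec.name]
        dists = group_marker_dist[spec.name]
        for o, off in enumerate(offspring_ids):
            k = int(rng.integers(2))
            retained_idx[o, g] = k
            for arm in range(len(spec.arm_lengths)):
                sel = arms == arm
                if not sel.any():
                    # still run the meiosis so the chiasma record is complete
                    pass
                tetrad = simulate_tetrad(
                    spec.arm_lengths[arm], config.chiasma_model, rng, config.chiasma_rate
                )
                for x, i, j in tetrad.chiasmata:
                    chiasma_rows.append(
                        {"offspring": off, "group": spec.name, "arm": arm,
                         "position": x, "chromatid_i": i, "chromatid_j": j}
                    )
                if config.retention == "mitotic":
                    # one chromatid of the retained pair, doubled
                    c = tetrad.chromatids[2 * k + int(rng.integers(2))]
                    ph = c.phases_at(dists[sel])
                    phase_a[ids[sel], o] = ph
                    phase_b[ids[sel], o] = ph
                else:
                    ca, cb = tetrad.sister_pair(k)
                    phase_a[ids[sel], o] = ca.phases_at(dists[sel])
                    phase_b[ids[sel], o] = cb.phases_at(dists[sel])

    # assemble genotype strings
    ref_alleles = np.array([p[0] for p in locus_allele_pairs])
    alt_alleles = np.array([p[1] for p in locus_allele_pairs])

    # paternal contamination: one sire chromatid replaces one maternal one
    n_contam = int(round(config.sire_contamination_fraction * config.n_offspring))
    contam_cols = sorted(rng.choice(config.n_offspring, size=n_contam, replace=False).tolist())
    sire_allele_choice = {}
    for o in contam_cols:
        picks = rng.integers(2, size=n_loci)
        sire_allele_choice[o] = np.array([sire_calls[l][picks[l]] for l in range(n_loci)])

    calls = np.empty((n_loci, config.n_offspring), dtype=object)
    for o in range(config.n_offspring):
        a_alleles = np.where(phase_a[:, o] == 0, ref_alleles, alt_alleles)
        if o in sire_allele_choice:
            b_alleles = sire_allele_choice[o]
        else:
            b_alleles = np.where(phase_b[:, o] == 0, ref_alleles, alt_alleles)
        for l in range(n_loci):
            calls[l, o] = genotype(str(a_alleles[l]), str(b_alleles[l]))

    # genotyping error: symmetric het<->hom flip
    if config.genotyping_error_rate > 0:
        flips = rng.random(calls.shape) < config.genotyping_error_rate
        for l, o in zip(*np.nonzero(flips)):
            gt = calls[l, o]
            if gt[0] != gt[1]:
                keep = gt[int(rng.integers(2))]
                calls[l, o] = keep + keep
            else:
                ref_a, alt_a = locus_allele_pairs[l]
                other = alt_a if gt[0] == ref_a else ref_a
                calls[l, o] = genotype(gt[0], other)

    # missingness
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    loci = pd.DataFrame(loci_rows).set_index("locus_id")
    matrix = GenotypeMatrix(
        loci=loci,
        dam=pd.Series(dam_calls, index=loci.index, name="dam"),
        sire=pd.Series(sire_calls, index=loci.index, name="sire"),
        offspring=pd.DataFrame(calls, index=loci.index, columns=offspring_ids),
        meta={
            "seed": config.seed,
            "chiasma_model": config.chiasma_model,
            "retention": config.retention,
            "n_offspring": config.n_offspring,
        },
    )
    truth = TetradTruth(
        markers=pd.DataFrame(truth_rows),
        chiasmata=pd.DataFrame(
            chiasma_rows,
            columns=["offspring", "group", "arm", "position", "chromatid_i", "chromatid_j"],
        ),
        retained=pd.DataFrame(
            retained_idx, index=offspring_ids, columns=[s.name for s in config.linkage_groups]
        ),
        contaminated=[offspring_ids[o] for o in contam_cols],
        config=replace(config),
    )
    return matrix, truth
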