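# Methods

## Meiosis model

Each chromosome of a simulated dam enters meiosis as a bivalent of four
chromatids: two sisters of maternal phase 0 and two of phase 1, sharing a
centromere per homolog. Chiasmata are placed along each arm independently:

- **obligate_one** — exactly one chiasma per arm, position uniform on the
  arm. This is the complete-interference limit in which the
  marker-centromere estimator 100·(y/2) is exactly unbiased: a marker at
  fraction *m* of the arm is heterozygous precisely when the single
  chiasma lands proximal to it, so E[y] = m and the true distance is
  50·m cM.
- **poisson** — a Poisson(λ) number of chiasmata per arm (λ =
  `chiasma_rate`, default 1.0), positions uniform. Each chiasma exchanges
  the segments distal to its position between one chromatid of each
  homolog, the non-sister pair drawn uniformly and independently per
  chiasma (no chromatid interference). Under this null the
  second-division-segregation probability of a marker with mean proximal
  chiasma count μ = λ·m is (2/3)·(1 − e^(−3μ/2)), saturating at the
  classical 2/3 telomeric ceiling; the simulator reproduces this closed
  form (checked in the tests by direct simulation).

Chromatids are represented exactly as centromere phase plus a sorted list
of phase-switch points; exchanges splice switch lists, so marker phases
are evaluated without discretising the arm. Chiasma positions are
continuous uniforms and almost surely never coincide with marker
positions; exchanges are applied proximal-to-distal.

Second-polar-body retention picks one meiosis-I product (one homolog's
sister-chromatid pair) uniformly and keeps both chromatids; for a
two-armed chromosome the same retained product supplies both arms. The
mitotic-gynogenetic control mode instead doubles a single chromatid,
giving y = 0 everywhere — the observable that separates the two
gynogenesis classes.

Retention is assumed 100% efficient: every offspring is a successful
second-polar-body retainee (or, in control mode, a doubled haploid).
Stochastic retention failure and spontaneous diploidisation are not
modelled.

## Simulated families

`SimConfig` defaults define the study design the package targets: 79
offspring; 24 linkage groups of which three (LG14, LG17, LG24) are
bi-armed (arm lengths 0.45/0.65 in arbitrary physical units, mono arms
1.0, one unit rendered as 1 Mbp of coordinate); 34 markers per group
evenly spaced along the group (uniform-random placement available),
giving ~800 dam-heterozygous SNPs genome-wide. The dam is heterozygous at
every locus with nucleotide ref/alt alleles; the sire carries one private
allele copy at 14% of loci and two at 8%, approximating the
male-informative marker share of a ddRAD panel scored in both parents.
Genotyping error is a symmetric het↔hom flip applied per offspring call
after segregation (default 0); missingness likewise (default 0);
contamination replaces one maternal chromatid with one sire allele per
locus in a `sire_contamination_fraction` of offspring. Everything is
driven by one seed; the same seed reproduces the matrix bit for bit.

What the generator does **not** emulate: read-level noise and
allele-dropout structure of real ddRAD genotyping (error is i.i.d. per
call), linkage between error and coverage, segregation distortion,
structural variation, and assembly misplacement of markers (marker order
is always correct by construction). Passing tests therefore demonstrate
correctness of the estimators under the stated meiotic model, not
robustness to assembly error — the aspect of real data most likely to
produce ambiguous arm calls.

## Marker QC

Cascade order is fixed: tag complexity (> 3 SNPs per tag), parental
genotype missing (either parent), offspring presence (< 75%,
threshold inclusive — exactly 75% is retained), dam homozygous, progeny
minor-allele frequency (< 0.4, strict — exactly 0.4 is retained). MAF is
the second-most-frequent allele's frequency over 2 × (non-missing progeny
calls), hence always in [0, 0.5]. The report guarantees
initial = final + Σ removed, and the cascade is idempotent.

Informativeness is assigned per parent independently: the dam flag is dam
heterozygosity; the sire class counts sire allele *copies* absent from
the dam genotype (one → `sire_one_allele`, two → `sire_both_alleles`), so
a dam-AB/sire-CC locus is "both". Dual-informative loci keep both flags;
the female map consumes the dam flag and the paternal screen the sire
class.

## Paternal screen

Male-specific alleles are the sire alleles absent from the dam at each
sire-informative locus. An offspring is flagged at `flag_threshold`
(default 1) or more loci carrying such an allele; the threshold exists
because real data contain genotyping errors, while a whole-genome
paternal contribution hits essentially every male-informative locus
typed in that offspring (detection probability 1 given at least one such
locus). Offspring with no scorable male-informative call are reported
`untestable`, never silently clean. Both the raw count of
male-informative loci and the per-offspring tested-locus counts are
reported, so coverage-adjusted rates can be recomputed downstream.

## Gene-centromere map

y is computed over non-missing progeny calls only; loci with no
informative call are dropped and counted. Distance is 100·(y/2) with no
small-sample or continuity correction, capped at 50 cM by y ≤ 1. Locus
classes use strict inequalities with priority telomeric (y > 0.9) >
centromeric (y < 0.1) > interference indicator (y > 2/3) > interior;
boundary values fall through to the next class. The Kosambi utility
d = 25·ln((1+2r)/(1−2r)) rejects r ≥ 0.5 as unlinked; it is a standalone
converter, not used by the y-based map.

## Crossover scoring

A region is ≥ 2 consecutive markers with the same het/hom status
(`min_run_length`, configurable). Missing calls bridge regions; runs
shorter than the minimum are masked as presumed genotyping errors —
masking and re-merging repeat until every remaining run qualifies — and
masked indices are reported. A crossover is a status change between
adjacent regions, localised to the inter-marker interval between the
flanking regions (marker spacing is the resolution limit; no point
estimate is invented). The singleton-masking rule deliberately trades a
small sensitivity loss for robustness: an exchange with fewer than two
markers on one side is invisible, so the observed per-arm crossover rate
under the obligate-one model sits slightly below 1.0 (≈ 0.91 at 34
evenly spaced markers per group), and the tests verify the observed count
equals the model's prediction exchange by exchange.

Per-arm statistics report the mean of per-arm mean crossover counts with
its standard error across arms, and the multiple-crossover fraction
(meioses with ≥ 2 exchanges on an arm) under both conventions — pooled
over all meioses and as the mean of per-arm fractions — because the
half-tetrad literature is ambiguous about which is meant.

## Arm-structure classification

Profiles of (position, y) are smoothed with a centred moving median
(window 5 markers, shrinking at the edges; implemented in-module because
library median filters pad edges by replication, which biases the
endpoint medians this rule depends on). Up to `outlier_tolerance`
(default 1) markers whose residual from the smoothed profile exceeds
`outlier_z` (default 3) robust SDs (1.4826·MAD, falling back to
1.2533·mean absolute deviation when the MAD degenerates to zero) are set
aside and reported. The smoothed minimum locates the centromere: within
the outer 15% of the physical span (`end_fraction`) and with the profile
rank-monotone away from it (|Spearman ρ| ≥ 0.7, `monotone_rho`) the call
is `mono_arm`; an interior minimum with both flanks monotone is `bi_arm`;
anything else — including fewer than four markers — is `ambiguous` with a
reason. The centromere interval spans the smoothing window around the
minimum (the resolution limit of the smoothed profile); on clean
bi-armed simulations at family size 79 this interval covers the true
centromere in ≥ 95% of groups. Historically this classification was done
by eye; these quantitative defaults are this package's own contract and
are echoed in every `ArmCall`. Classification is invariant to reversing
marker order (mono-arm ends swap accordingly). For bi-arm groups,
crossovers are assigned to the arm containing their interval; intervals
straddling the centromere estimate are reported unassigned rather than
guessed.

## In-silico double digest

Cut sites are found by IUPAC-degenerate scan with overlapping matches
counted; palindromic motifs (the SbfI CCTGCA^GG and SphI GCATG^C
defaults both are) are scanned on the forward strand only, others on
both strands with reverse-strand cuts mapped to forward coordinates. N
runs never match. Fragments tile each contig exactly; contig-end
fragments carry a `contig_end` end-type and are never selected. Selection
keeps fragments with exactly one rare and one common end and insert
length (cut position to cut position, adaptors excluded) inside the
inclusive 320–590 bp window. Fragment tables are 1-based inclusive; BED
output converts to 0-based half-open explicitly. Counts for a real
genome assembly are an optional external check, not part of the test
suite, since they require downloading the assembly.

## Map concordance

Spearman rank correlation (average ranks on ties) of marker positions
per shared linkage group; markers placed in different groups by the two
maps are emitted as a conflict table rather than dropped. The sign is
kept: orientation disagreement is informative for assembly QC. Groups
with fewer than two shared markers (or degenerate positions) get NaN.

## Validation problem sizes

The test suite exercises: 10⁵ meioses for the 2/3 no-interference
telomeric limit (within 3 binomial SEs) and 10⁴ for the obligate-one
100% limit; a 79-offspring, 816-marker clean family for parameter
recovery, where the mean |100·(y/2) − truth| stays inside the mean
3-SE binomial envelope 3·50·√(m(1−m)/79) and ≥ 99% of markers sit inside
their own per-marker 3-SE band (the per-marker bound is a statistical
envelope, so a ~0.3% exceedance rate is the expected behaviour, not a
defect); 10⁴ random status vectors against a brute-force region oracle;
and 100 kb random sequences against a position-by-position digest oracle.

## Known limitations

- The obligate-one model places its chiasma uniformly; real interference
  shapes positional distributions that are neither uniform nor Poisson.
  No counting-model (chi-square) interference is offered.
- Arm-structure defaults were chosen for evenly spaced, well-behaved
  panels; sparse or clustered markers may need a wider smoothing window.
- The paternal screen quantifies contribution only as per-offspring locus
  counts; it does not model aneuploid dosage.
- The Kosambi utility is not inverted into a pairwise map builder; marker
  order is taken from supplied physical positions throughout.
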