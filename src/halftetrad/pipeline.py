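"""End-to-end analysis pipeline and summary report.

Wires the stages together in the order a gynogenetic-family study runs
them: marker QC -> paternal screen -> gene-centromere map -> crossover
scoring and arm structure (-> map concordance when a second map is
supplied). Every number in the summary is recomputed from the emitted
per-locus tables; the report holds no state of its own.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from halftetrad.centromere_map import build_centromere_map, write_candidate_bed
from halftetrad.chromosome_structure import (
    arm_call_table,
    arm_recombination_stats,
    assign_crossovers_to_arms,
    call_arm_structures,
    score_crossovers,
)
from halftetrad.genotypes import GenotypeMatrix, read_genotypes
from halftetrad.map_concordance import concordance_table, order_correlation
from halftetrad.marker_qc import apply_filter_cascade
from halftetrad.paternal_screen import screen_offspring

log = logging.getLogger("halftetrad")


@dataclass
class PipelineConfig:
    """Parameters of the full analysis; defaults match the module contracts."""

    input_path: str | None = None
    output_dir: str = "halftetrad_out"
    second_map_path: str | None = None
    # marker_qc
    max_snps_per_tag: int = 3
    min_offspring_presence: float = 0.75
    min_maf: float = 0.4
    # paternal_screen
    flag_threshold: int = 1
    # centromere_map
    telomeric: float = 0.9
    centromeric: float = 0.1
    interference: float = 2.0 / 3.0
    # chromosome_structure
    min_run_length: int = 2
    smooth_window: int = 5
    end_fraction: float = 0.15
    monotone_rho: float = 0.7
    outlier_tolerance: int = 1
    outlier_z: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ReportBundle:
    filter_report: object
    screen: object
    centromere_table: pd.DataFrame
    centromere_summary: dict
    arm_calls: list
    crossovers: pd.DataFrame
    arm_stats: object
    concordance: pd.DataFrame | None
    output_dir: Path
    summary_text: str = ""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(
    config: PipelineConfig, matrix: GenotypeMatrix | None = None
) -> ReportBundle:
    """Run the full analysis and write all tables under ``output_dir``.

    ``matrix`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.input_path``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("seed=%d", config.seed)
    if matrix is None:
        if config.input_path is None:
            raise ValueError("no input: supply a genotype matrix or input_path")
        matrix = _stage("read")(read_genotypes)(config.input_path)

    filtered, report = _stage("marker_qc")(apply_filter_cascade)(
        matrix,
        max_snps_per_tag=config.max_snps_per_tag,
        min_offspring_presence=config.min_offspring_presence,
        min_maf=config.min_maf,
    )
    report.to_tsv(outdir / "filter_report.tsv")
    filtered.to_tsv(outdir / "filtered_genotypes.tsv")

    screen = _stage("paternal_screen")(screen_offspring)(
        matrix, flag_threshold=config.flag_threshold
    )
    screen.to_tsv(outdir / "paternal_screen.tsv")

    cmap, csummary = _stage("centromere_map")(build_centromere_map)(
        filtered,
        telomeric=config.telomeric,
        centromeric=config.centromeric,
        interference=config.interference,
    )
    cmap.to_csv(outdir / "centromere_map.tsv", sep="\t", index=False)
    write_candidate_bed(cmap, outdir / "candidate_markers.bed")

    arm_calls = _stage("arm_structure")(call_arm_structures)(
        filtered,
        smooth_window=config.smooth_window,
        end_fraction=config.end_fraction,
        monotone_rho=config.monotone_rho,
        outlier_tolerance=config.outlier_tolerance,
        outlier_z=config.outlier_z,
    )
    arm_call_table(arm_calls, filtered).to_csv(outdir / "arm_calls.tsv", sep="\t", index=False)

    crossovers = _stage("crossover_scan")(score_crossovers)(
        filtered, min_run_length=config.min_run_length
    )
    flat = crossovers.copy()
    flat["intervals"] = flat["intervals"].map(
        lambda iv: ";".join(f"{a}-{b}" for a, b in iv)
    )
    flat.to_csv(outdir / "crossovers.tsv", sep="\t", index=False)
    counts = assign_crossovers_to_arms(crossovers, arm_calls)
    arm_stats = arm_recombination_stats(counts) if counts else None
    if arm_stats is not None:
        arm_stats.per_arm.to_csv(outdir / "arm_recombination.tsv", sep="\t", index=False)

    concordance = None
    if config.second_map_path is not None:
        map_a = cmap.rename(
            columns={"locus_id": "marker", "linkage_group": "group"}
        )[["marker", "group", "position"]]
        map_b = pd.read_csv(config.second_map_path, sep="\t")
        records, conflicts = _stage("map_concordance")(order_correlation)(map_a, map_b)
        concordance = concordance_table(records)
        concordance.to_csv(outdir / "map_concordance.tsv", sep="\t", index=False)
        conflicts.to_csv(outdir / "map_conflicts.tsv", sep="\t", index=False)

    bundle = ReportBundle(
        filter_report=report,
        screen=screen,
        centromere_table=cmap,
        centromere_summary=csummary,
        arm_calls=arm_calls,
        crossovers=crossovers,
        arm_stats=arm_stats,
        concordance=concordance,
        output_dir=outdir,
    )
    bundle.summary_text = render_summary(bundle, config)
    (outdir / "summary.txt").write_text(bundle.summary_text)
    return bundle


def render_summary(bundle: ReportBundle, config: PipelineConfig) -> str:
    """Plain-text summary mirroring the structure of a study report."""
    lines = ["# halftetrad pipeline summary", f"seed\t{config.seed}", ""]
    lines.append("## Marker filter cascade")
    lines.append(str(bundle.filter_report))
    lines.append("")
    s = bundle.screen
    lines.append("## Paternal contribution screen")
    lines.append(f"male-informative loci\t{len(s.male_informative)}")
    lines.append(f"  one allele private\t{s.n_one_allele}")
    lines.append(f"  both alleles private\t{s.n_both_alleles}")
    lines.append(f"verdict\t{s.verdict}")
    if s.flagged:
        lines.append(f"flagged offspring\t{','.join(s.flagged)}")
    if s.untestable:
        lines.append(f"untestable offspring\t{len(s.untestable)}")
    lines.append("")
    c = bundle.centromere_summary
    lines.append("## Gene-centromere map (y distribution)")
    for key in ("n_loci", "n_y_eq_1", "n_y_eq_0", "n_y_gt_telomeric",
                "n_y_lt_centromeric", "n_y_gt_interference"):
        lines.append(f"{key}\t{c[key]}")
    lines.append(f"frac_y_eq_1\t{100 * c['frac_y_eq_1']:.2f}%")
    lines.append(f"frac_y_eq_0\t{100 * c['frac_y_eq_0']:.2f}%")
    lines.append(f"frac_y_gt_interference\t{100 * c['frac_y_gt_interference']:.2f}%")
    lines.append("")
    lines.append("## Arm structure")
    for call in bundle.arm_calls:
        lines.append(f"{call.group}\t{call.verdict}")
    lines.append("")
    if bundle.arm_stats is not None:
        st = bundle.arm_stats
        lines.append("## Per-arm recombination")
        lines.append(f"mean crossovers per arm\t{st.mean_per_arm:.3f} (S.E. {st.se:.3f})")
        lines.append(f"multiple-crossover fraction (pooled)\t{100 * st.frac_multiple_pooled:.2f}%")
        lines.append(f"multiple-crossover fraction (arm mean)\t{100 * st.frac_multiple_arm_mean:.2f}%")
        lines.append("")
    if bundle.concordance is not None:
        lines.append("## Map concordance")
        lines.append(bundle.concordance.to_string(index=False))
        lines.append("")
    return "\n".join(lines)
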