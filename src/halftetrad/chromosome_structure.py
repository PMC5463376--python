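"""Crossover scoring and chromosome arm-structure classification.

Along a physically ordered linkage group, each meiotic-gynogenetic
offspring shows blocks of homozygous markers (proximal to the last
exchange) and heterozygous markers (distal). A *region* is at least
``min_run_length`` consecutive markers with the same status; a change from
a homozygous region to a heterozygous one (or back) is scored as a
crossover, localised to the interval between the flanking markers.
Isolated single-marker interruptions are masked as presumed genotyping
errors rather than scored as two crossovers, and missing calls bridge
regions without breaking them.

Arm structure is read off the per-locus heterozygote-frequency profile:
a mono-armed (acrocentric-like) group rises from low ``y`` at one end to
high ``y`` at the other; a bi-armed (metacentric-like) group has an
interior minimum with rises on both flanks. The paper-of-record analyses
of this kind classified profiles by eye; here the decision rule is
quantitative and its parameters (smoothing window, monotonicity rank
correlation, end fraction, outlier tolerance) are part of the output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from halftetrad.genotypes import GenotypeMatrix

HET, HOM, MISSING_CODE = 1, 0, -1
_STATUS_NAME = {HET: "het", HOM: "hom"}


def _to_codes(statuses: Iterable) -> list[int]:
    codes = []
    for s in statuses:
        if s in (HET, HOM, MISSING_CODE):
            codes.append(int(s))
        elif s == "het":
            codes.append(HET)
        elif s == "hom":
            codes.append(HOM)
        elif s is None or s == "NA":
            codes.append(MISSING_CODE)
        else:
            raise ValueError(f"unknown status {s!r}")
    return codes


@dataclass(frozen=True)
class StatusRun:
    """Maximal same-status region of >= ``min_run_length`` markers."""

    status: str                      # "het" | "hom"
    start_index: int                 # original index of first member
    end_index: int                   # original index of last member
    member_indices: tuple[int, ...]  # unmasked, non-missing members

    @property
    def length(self) -> int:
        return len(self.member_indices)


def scan_status_runs(
    statuses: Sequence, min_run_length: int = 2
) -> tuple[list[StatusRun], list[int]]:
    """Segment an offspring's ordered marker statuses into regions.

    Statuses may be ``"het"``/``"hom"``/``None`` or codes ``1``/``0``/
    ``-1`` (missing). Missing calls bridge runs without breaking them.
    Runs shorter than ``min_run_length`` are masked (members reported in
    the second return value) and scanning repeats until every remaining
    run is long enough; same-status neighbours separated only by masked or
    missing markers merge.

    Raises on fewer than two non-missing statuses.
    """
    codes = _to_codes(statuses)
    observed = [(i, s) for i, s in enumerate(codes) if s != MISSING_CODE]
    if len(observed) < 2:
        raise ValueError("need at least 2 non-missing marker statuses")

    masked: set[int] = set()
    while True:
        seq = [(i, s) for i, s in observed if i not in masked]
        runs: list[list[tuple[int, int]]] = [
            list(grp) for _, grp in groupby(seq, key=lambda t: t[1])
        ]
        short = [run for run in runs if len(run) < min_run_length]
        if not short:
            break
        for run in short:
            masked.update(i for i, _ in run)
        if len(short) == len(runs):
            runs = []
            break

    result = [
        StatusRun(
            status=_STATUS_NAME[run[0][1]],
            start_index=run[0][0],
            end_index=run[-1][0],
            member_indices=tuple(i for i, _ in run),
        )
        for run in runs
    ]
    return result, sorted(masked)


@dataclass(frozen=True)
class Crossover:
    """One scored exchange, localised between two flanking markers."""

    left_index: int
    right_index: int
    from_status: str
    to_status: str


def count_crossovers(runs: list[StatusRun]) -> tuple[int, list[Crossover]]:
    """Count status changes between adjacent regions.

    Each crossover is localised to the inter-marker interval between the
    last marker of one run and the first marker of the next.
    """
    crossovers = []
    for left, right in zip(runs, runs[1:]):
        if left.status != right.status:
            crossovers.append(
                Crossover(left.end_index, right.start_index, left.status, right.status)
            )
    return len(crossovers), crossovers


# ---------------------------------------------------------------------------
# arm-level recombination statistics
# ---------------------------------------------------------------------------

@dataclass
class ArmRecombinationStats:
    """Crossover-rate summary across arms.

    ``mean_per_arm`` is the mean of per-arm mean crossover counts;
    ``se`` its standard error across arms. The multiple-crossover rate
    (fraction of meioses with >= 2 exchanges on an arm) is reported both
    pooled over all meioses and as the mean of per-arm fractions, since
    either convention is found in the half-tetrad literature.
    """

    per_arm: pd.DataFrame  # arm, n_meioses, mean_crossovers, frac_multiple
    mean_per_arm: float
    se: float
    sd: float
    frac_multiple_pooled: float
    frac_multiple_arm_mean: float


def arm_recombination_stats(counts_by_arm: dict[str, Sequence[int]]) -> ArmRecombinationStats:
    """Aggregate per-meiosis crossover counts into per-arm statistics."""
    if not counts_by_arm:
        raise ValueError("no arms supplied")
    rows = []
    total_meioses = 0
    total_multiple = 0
    for arm, counts in counts_by_arm.items():
        counts = np.asarray(list(counts))
        if counts.size == 0:
            raise ValueError(f"arm {arm!r} has no meioses")
        n_multi = int((counts >= 2).sum())
        rows.append(
            {
                "arm": arm,
                "n_meioses": counts.size,
                "mean_crossovers": counts.mean(),
                "frac_multiple": n_multi / counts.size,
            }
        )
        total_meioses += counts.size
        total_multiple += n_multi
    per_arm = pd.DataFrame(rows)
    means = per_arm["mean_crossovers"].to_numpy()
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return ArmRecombinationStats(
        per_arm=per_arm,
        mean_per_arm=float(means.mean()),
        se=sd / np.sqrt(len(means)) if len(means) > 1 else 0.0,
        sd=sd,
        frac_multiple_pooled=total_multiple / total_meioses,
        frac_multiple_arm_mean=float(per_arm["frac_multiple"].mean()),
    )


# ---------------------------------------------------------------------------
# arm-structure classification
# ---------------------------------------------------------------------------

@dataclass
class ArmCall:
    """Structure verdict for one linkage group."""

    group: str
    verdict: str                                   # mono_arm | bi_arm | ambiguous
    centromere_interval: tuple[float, float] | None
    centromere_end: str | None                     # "low" | "high" for mono_arm
    outliers: list[int]                            # marker indices excluded
    diagnostics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving median with shrinking windows at the edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_arm_structure(
    positions: Sequence[float],
    y_values: Sequence[float],
    group: str = "",
    smooth_window: int = 5,
    end_fraction: float = 0.15,
    monotone_rho: float = 0.7,
    outlier_tolerance: int = 1,
    outlier_z: float = 3.0,
) -> ArmCall:
    """Call mono-arm / bi-arm / ambiguous from a heterozygosity profile.

    The profile is smoothed by a centred moving median; up to
    ``outlier_tolerance`` markers whose residual from the smoothed profile
    exceeds ``outlier_z`` robust standard deviations are set aside (and
    reported) before the call. The smoothed minimum locates the
    centromere: within the outer ``end_fraction`` of the physical span
    plus rank-monotone rise away from it -> ``mono_arm``; interior minimum
    with both flanks rank-monotone (|Spearman rho| >= ``monotone_rho``)
    -> ``bi_arm``; anything else -> ``ambiguous``. The centromere interval
    spans the smoothing window around the minimum — the resolution limit
    of the smoothed profile.
    """
    params = {
        "smooth_window": smooth_window,
        "end_fraction": end_fraction,
        "monotone_rho": monotone_rho,
        "outlier_tolerance": outlier_tolerance,
        "outlier_z": outlier_z,
    }
    pos = np.asarray(positions, dtype=float)
    ys = np.asarray(y_values, dtype=float)
    if pos.ndim != 1 or pos.shape != ys.shape:
        raise ValueError("positions and y values must be 1-D and equal length")
    order = np.argsort(pos, kind="stable")
    pos, ys = pos[order], ys[order]
    n = len(pos)
    if n < 4:
        return ArmCall(group, "ambiguous", None, None, [],
                       {"reason": "insufficient markers"}, params)

    # outlier exclusion against the smoothed profile
    smoothed = _moving_median(ys, smooth_window)
    resid = ys - smoothed
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        # MAD degenerates when most residuals are exactly zero (e.g. a
        # single spike on an otherwise smooth profile): fall back to the
        # mean absolute deviation
        robust_sd = 1.2533 * float(np.mean(np.abs(resid - np.median(resid))))
    outliers: list[int] = []
    if robust_sd > 0 and outlier_tolerance > 0:
        flagged = np.flatnonzero(np.abs(resid) > outlier_z * robust_sd)
        flagged = flagged[np.argsort(-np.abs(resid[flagged]))][:outlier_tolerance]
        outliers = sorted(int(order[i]) for i in flagged)
        keep = np.setdiff1d(np.arange(n), flagged)
    else:
        keep = np.arange(n)
    kpos, kys = pos[keep], ys[keep]
    if len(kpos) < 4:
        return ArmCall(group, "ambiguous", None, None, outliers,
                       {"reason": "insufficient markers after outlier removal"}, params)
    ksmooth = _moving_median(kys, smooth_window)

    imin = int(np.argmin(ksmooth))
    span = kpos[-1] - kpos[0]
    min_pos = kpos[imin]
    half = smooth_window // 2
    lo_i, hi_i = max(0, imin - half), min(len(kpos) - 1, imin + half)
    diagnostics = {
        "min_position": float(min_pos),
        "y_low_end": float(ksmooth[0]),
        "y_high_end": float(ksmooth[-1]),
    }
    at_low_end = min_pos <= kpos[0] + end_fraction * span
    at_high_end = min_pos >= kpos[-1] - end_fraction * span

    if at_low_end or at_high_end:
        rho = _spearman(kpos, ksmooth)
        diagnostics["rho"] = rho
        rising = (rho >= monotone_rho) if at_low_end else (rho <= -monotone_rho)
        if not np.isnan(rho) and rising:
            if at_low_end:
                interval = (float(kpos[0]), float(kpos[hi_i]))
                end = "low"
            else:
                interval = (float(kpos[lo_i]), float(kpos[-1]))
                end = "high"
            return ArmCall(group, "mono_arm", interval, end, outliers, diagnostics, params)
        diagnostics["reason"] = "end minimum but profile not monotone"
        return ArmCall(group, "ambiguous", None, None, outliers, diagnostics, params)

    left = slice(0, imin + 1)
    right = slice(imin, len(kpos))
    rho_left = _spearman(kpos[left], ksmooth[left])
    rho_right = _spearman(kpos[right], ksmooth[right])
    diagnostics["rho_left"] = rho_left
    diagnostics["rho_right"] = rho_right
    if (
        not np.isnan(rho_left)
        and not np.isnan(rho_right)
        and rho_left <= -monotone_rho
        and rho_right >= monotone_rho
    ):
        interval = (float(kpos[lo_i]), float(kpos[hi_i]))
        return ArmCall(group, "bi_arm", interval, None, outliers, diagnostics, params)
    diagnostics["reason"] = "interior minimum but flanks not both monotone"
    return ArmCall(group, "ambiguous", None, None, outliers, diagnostics, params)


# ---------------------------------------------------------------------------
# whole-matrix drivers
# ---------------------------------------------------------------------------

def score_crossovers(
    matrix: GenotypeMatrix, min_run_length: int = 2
) -> pd.DataFrame:
    """Scan every offspring along every linkage group.

    Returns one row per (offspring, group): crossover count plus the
    physical interval of each exchange, and the masked-singleton count.
    Offspring with fewer than two informative calls on a group are
    recorded with count -1 (unscorable).
    """
    rows = []
    for group in matrix.groups():
        view = matrix.group_view(group)
        positions = view.loci["position"].to_numpy()
        status = view.het_status()
        for off in view.offspring_ids:
            codes = status[off].to_numpy()
            try:
                runs, masked = scan_status_runs(codes, min_run_length)
            except ValueError:
                rows.append(
                    {"offspring": off, "group": group, "n_crossovers": -1,
                     "n_masked": 0, "intervals": []}
                )
                continue
            n, crossovers = count_crossovers(runs)
            rows.append(
                {
                    "offspring": off,
                    "group": group,
                    "n_crossovers": n,
                    "n_masked": len(masked),
                    "intervals": [
                        (int(positions[c.left_index]), int(positions[c.right_index]))
                        for c in crossovers
                    ],
                }
            )
    return pd.DataFrame(rows)


def call_arm_structures(matrix: GenotypeMatrix, **kwargs) -> list[ArmCall]:
    """Heterozygosity-profile arm call for every linkage group."""
    from halftetrad.centromere_map import heterozygote_frequency

    calls = []
    for group in matrix.groups():
        view = matrix.group_view(group)
        positions, ys = [], []
        for locus_id in view.locus_ids:
            try:
                y, *_ = heterozygote_frequency(view.offspring.loc[locus_id])
            except ValueError:
                continue
            positions.append(view.loci.at[locus_id, "position"])
            ys.append(y)
        calls.append(classify_arm_structure(positions, ys, group=group, **kwargs))
    return calls


def assign_crossovers_to_arms(
    crossover_table: pd.DataFrame, arm_calls: list[ArmCall]
) -> dict[str, list[int]]:
    """Per-arm crossover counts for :func:`arm_recombination_stats`.

    Mono-arm groups contribute a single arm. For bi-arm groups each
    exchange goes to the arm containing its interval; intervals straddling
    the centromere estimate are counted under ``<group>.unassigned``.
    Ambiguous groups are skipped, as are unscorable offspring.
    """
    call_by_group = {c.group: c for c in arm_calls}
    counts: dict[str, list[int]] = {}
    for _, row in crossover_table.iterrows():
        call = call_by_group.get(row["group"])
        if call is None or call.verdict == "ambiguous" or row["n_crossovers"] < 0:
            continue
        if call.verdict == "mono_arm":
            counts.setdefault(row["group"], []).append(row["n_crossovers"])
            continue
        cen_lo, cen_hi = call.centromere_interval
        left = right = straddle = 0
        for a, b in row["intervals"]:
            if b <= cen_lo:
                left += 1
            elif a >= cen_hi:
                right += 1
            else:
                straddle += 1
        counts.setdefault(f"{row['group']}.L", []).append(left)
        counts.setdefault(f"{row['group']}.R", []).append(right)
        if straddle:
            counts.setdefault(f"{row['group']}.unassigned", []).append(straddle)
    return counts


def arm_call_table(calls: list[ArmCall], matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Tabular arm-call summary (group, marker count, span, verdict)."""
    rows = []
    for call in calls:
        row = {
            "group": call.group,
            "verdict": call.verdict,
            "centromere_lo": call.centromere_interval[0] if call.centromere_interval else np.nan,
            "centromere_hi": call.centromere_interval[1] if call.centromere_interval else np.nan,
            "centromere_end": call.centromere_end or "",
            "n_outliers": len(call.outliers),
            "reason": call.diagnostics.get("reason", ""),
        }
        if matrix is not None:
            view = matrix.group_view(call.group)
            row["n_markers"] = view.n_loci
            pos = view.loci["position"]
            row["span_bp"] = int(pos.max() - pos.min()) if len(pos) else 0
        rows.append(row)
    return pd.DataFrame(rows)


def plot_group_profile(
    matrix: GenotypeMatrix, group: str, call: ArmCall | None = None, ax=None
):
    """Optional heterozygosity-profile figure for one linkage group."""
    import matplotlib.pyplot as plt

    from halftetrad.centromere_map import heterozygote_frequency

    view = matrix.group_view(group)
    xs, ys = [], []
    for locus_id in view.locus_ids:
        try:
            y, *_ = heterozygote_frequency(view.offspring.loc[locus_id])
        except ValueError:
            continue
        xs.append(view.loci.at[locus_id, "position"])
        ys.append(y)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(xs, ys, "o-", ms=3, lw=0.8)
    ax.set_xlabel("physical position (bp)")
    ax.set_ylabel("heterozygote frequency y")
    title = group
    if call is not None:
        title += f" ({call.verdict})"
        if call.centromere_interval:
            ax.axvspan(*call.centromere_interval, color="0.85", zorder=0)
    ax.set_title(title)
    ax.set_ylim(-0.05, 1.05)
    return ax
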