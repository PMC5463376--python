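"""Run scanning, crossover counting, arm statistics and arm-structure calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halftetrad.chromosome_structure import (
    arm_recombination_stats,
    call_arm_structures,
    classify_arm_structure,
    count_crossovers,
    scan_status_runs,
    score_crossovers,
)
from halftetrad.meiosis_sim import LinkageGroupSpec, SimConfig, simulate_family


def brute_force_regions(codes, min_len=2):
    """Slow re-derivation of the >=2-consecutive-marker region rule.

    Repeatedly group the unmasked, non-missing statuses into maximal
    same-status blocks and mask every block shorter than ``min_len`` until
    all remaining blocks qualify (or nothing qualifies).
    """
    masked = set()
    while True:
        blocks = []
        for i, c in enumerate(codes):
            if c == -1 or i in masked:
                continue
            if blocks and blocks[-1][0] == c:
                blocks[-1][1].append(i)
            else:
                blocks.append([c, [i]])
        short = [b for b in blocks if len(b[1]) < min_len]
        if not short:
            return blocks, sorted(masked)
        if len(short) == len(blocks):
            for b in blocks:
                masked.update(b[1])
            return [], sorted(masked)
        for b in short:
            masked.update(b[1])


def transitions(blocks):
    return sum(1 for a, b in zip(blocks, blocks[1:]) if a[0] != b[0])


class TestScan:
    @pytest.mark.parametrize(
        "statuses,expected_runs,expected_masked",
        [
            (["hom", "hom", "hom", "het", "het"], [("hom", 0, 2), ("het", 3, 4)], []),
            (["hom", "hom", "het", "hom", "hom"], [("hom", 0, 4)], [2]),
            (
                ["het", "het", "hom", "hom", "het", "het"],
                [("het", 0, 1), ("hom", 2, 3), ("het", 4, 5)],
                [],
            ),
        ],
    )
    def test_worked_examples(self, statuses, expected_runs, expected_masked):
        runs, masked = scan_status_runs(statuses)
        assert [(r.status, r.start_index, r.end_index) for r in runs] == expected_runs
        assert masked == expected_masked

    def test_missing_bridges_runs(self):
        runs, masked = scan_status_runs([1, 1, -1, 1, 0, 0])
        assert [(r.status, r.start_index, r.end_index) for r in runs] == [
            ("het", 0, 3),
            ("hom", 4, 5),
        ]
        assert masked == []

    def test_too_few_informative_markers_rejected(self):
        with pytest.raises(ValueError):
            scan_status_runs([1, -1, -1])

    def test_every_unmasked_marker_in_exactly_one_run(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            codes = rng.choice([1, 0, -1], size=25, p=[0.45, 0.45, 0.1])
            if (codes != -1).sum() < 2:
                continue
            runs, masked = scan_status_runs(codes)
            members = [i for r in runs for i in r.member_indices]
            assert len(members) == len(set(members))
            informative = {i for i, c in enumerate(codes) if c != -1}
            assert set(members) | set(masked) == informative

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.sampled_from([1, 0, -1]), min_size=2, max_size=40).filter(
            lambda codes: sum(c != -1 for c in codes) >= 2
        )
    )
    def test_matches_brute_force_enumeration(self, codes):
        runs, masked = scan_status_runs(codes)
        blocks, bf_masked = brute_force_regions(codes)
        assert [(r.status == "het", list(r.member_indices)) for r in runs] == [
            (b[0] == 1, b[1]) for b in blocks
        ]
        assert masked == bf_masked
        assert count_crossovers(runs)[0] == transitions(blocks)


class TestCountCrossovers:
    def test_single_run_no_crossover(self):
        runs, _ = scan_status_runs(["hom"] * 6)
        assert count_crossovers(runs) == (0, [])

    def test_double_crossover_hom_het_hom(self):
        runs, _ = scan_status_runs(["hom", "hom", "het", "het", "hom", "hom"])
        n, crossovers = count_crossovers(runs)
        assert n == 2
        assert [(c.left_index, c.right_index) for c in crossovers] == [(1, 2), (3, 4)]

    def test_obligate_one_simulation_scanner_agrees_with_truth(self):
        """Scanner sees the single exchange whenever >=2 markers flank it."""
        cfg = SimConfig(
            n_offspring=30,
            linkage_groups=[LinkageGroupSpec(f"G{i}", (1.0,)) for i in range(4)],
            markers_per_group=25,
            seed=17,
        )
        matrix, truth = simulate_family(cfg)
        table = score_crossovers(matrix)
        chiasma = truth.chiasmata.set_index(["offspring", "group"]).sort_index()
        dists = {
            g: truth.markers.loc[truth.markers.linkage_group == g, "dist_from_centromere"].to_numpy()
            for g in matrix.groups()
        }
        for _, row in table.iterrows():
            x = float(chiasma.loc[(row["offspring"], row["group"]), "position"])
            k = int((dists[row["group"]] < x).sum())
            n_markers = len(dists[row["group"]])
            expected = 1 if 2 <= k <= n_markers - 2 else 0
            assert row["n_crossovers"] == expected


class TestArmStats:
    def test_all_single_crossovers(self):
        stats = arm_recombination_stats({"a": [1] * 10, "b": [1] * 10})
        assert stats.mean_per_arm == 1.0
        assert stats.se == 0.0
        assert stats.frac_multiple_pooled == 0.0

    def test_mixed_counts_arithmetic(self):
        stats = arm_recombination_stats({"a": [1, 1, 2, 0]})
        assert stats.mean_per_arm == 1.0
        assert stats.frac_multiple_pooled == 0.25
        assert stats.frac_multiple_arm_mean == 0.25

    def test_pooled_vs_arm_mean_conventions_differ(self):
        stats = arm_recombination_stats({"a": [2, 2], "b": [1, 1, 1, 1]})
        assert stats.frac_multiple_pooled == pytest.approx(2 / 6)
        assert stats.frac_multiple_arm_mean == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            arm_recombination_stats({})


class TestClassifyArmStructure:
    def test_monotone_rise_is_mono_arm_low_end(self):
        pos = np.arange(20, dtype=float)
        ys = np.linspace(0.05, 0.95, 20)
        call = classify_arm_structure(pos, ys)
        assert call.verdict == "mono_arm"
        assert call.centromere_end == "low"
        assert call.centromere_interval[0] == 0.0

    def test_v_shape_is_bi_arm_with_interior_centromere(self):
        pos = np.arange(21, dtype=float)
        ys = np.concatenate([np.linspace(1.0, 0.02, 11), np.linspace(0.1, 0.95, 10)])
        call = classify_arm_structure(pos, ys)
        assert call.verdict == "bi_arm"
        lo, hi = call.centromere_interval
        assert lo < 10 < hi

    def test_spiked_marker_listed_as_outlier_not_fatal(self):
        pos = np.arange(20, dtype=float)
        ys = np.linspace(0.05, 0.95, 20)
        ys[4] = 0.9  # one wild marker inside the low flank
        call = classify_arm_structure(pos, ys)
        assert call.verdict == "mono_arm"
        assert call.outliers == [4]

    def test_insufficient_markers_ambiguous(self):
        call = classify_arm_structure([1.0, 2.0, 3.0], [0.1, 0.5, 0.9])
        assert call.verdict == "ambiguous"
        assert call.diagnostics["reason"] == "insufficient markers"

    def test_noise_profile_is_ambiguous(self):
        rng = np.random.default_rng(5)
        pos = np.arange(30, dtype=float)
        ys = rng.uniform(0.2, 0.8, size=30)
        assert classify_arm_structure(pos, ys).verdict == "ambiguous"

    def test_reversal_swaps_mono_arm_end(self):
        pos = np.arange(20, dtype=float)
        ys = np.linspace(0.05, 0.95, 20)
        forward = classify_arm_structure(pos, ys)
        reverse = classify_arm_structure(pos, ys[::-1])
        assert forward.verdict == reverse.verdict == "mono_arm"
        assert forward.centromere_end == "low"
        assert reverse.centromere_end == "high"

    def test_reversal_invariance_of_bi_arm_call(self):
        pos = np.arange(21, dtype=float)
        ys = np.concatenate([np.linspace(0.9, 0.02, 9), np.linspace(0.05, 0.95, 12)])
        assert classify_arm_structure(pos, ys).verdict == "bi_arm"
        assert classify_arm_structure(pos, ys[::-1]).verdict == "bi_arm"

    def test_simulated_structures_recovered(self, clean_family):
        matrix, truth = clean_family
        by_name = {s.name: len(s.arm_lengths) for s in truth.config.linkage_groups}
        for call in call_arm_structures(matrix):
            expected = "bi_arm" if by_name[call.group] == 2 else "mono_arm"
            assert call.verdict == expected, (call.group, call.diagnostics)

    def test_bi_arm_centromere_interval_covers_truth(self):
        """At family size 79 with clean calls, the interval around the
        smoothed minimum contains the true centromere in >=95% of groups."""
        groups = [LinkageGroupSpec(f"G{i}", (0.45, 0.65)) for i in range(5)]
        covered = total = 0
        for seed in range(8):
            cfg = SimConfig(n_offspring=79, linkage_groups=groups,
                            markers_per_group=34, seed=seed)
            matrix, _ = simulate_family(cfg)
            for call in call_arm_structures(matrix):
                assert call.verdict == "bi_arm"
                total += 1
                lo, hi = call.centromere_interval
                covered += lo <= 0.45e6 + 1 <= hi
        assert covered / total >= 0.95
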