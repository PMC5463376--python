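"""Tetrad mechanics, polar-body retention and family simulation."""

import dataclasses

import numpy as np
import pytest

from halftetrad.genotypes import is_het, is_missing
from halftetrad.meiosis_sim import (
    LinkageGroupSpec,
    SimConfig,
    distal_het_frequency,
    expected_sds_probability,
    retain_second_polar_body,
    simulate_family,
    simulate_tetrad,
)


class TestTetrad:
    def test_zero_chiasmata_gives_unbroken_parental_chromatids(self):
        # Poisson with a vanishing rate: the draw is 0 chiasmata
        tetrad = simulate_tetrad(1.0, "poisson", np.random.default_rng(0), chiasma_rate=1e-12)
        assert tetrad.chiasmata == []
        assert [c.switches for c in tetrad.chromatids] == [[], [], [], []]
        assert [c.centromere_phase for c in tetrad.chromatids] == [0, 0, 1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_obligate_one_has_one_switch_in_one_nonsister_pair(self, seed):
        tetrad = simulate_tetrad(1.0, "obligate_one", np.random.default_rng(seed))
        assert len(tetrad.chiasmata) == 1
        x, i, j = tetrad.chiasmata[0]
        assert 0 < x < 1 and i in (0, 1) and j in (2, 3)
        switched = [k for k, c in enumerate(tetrad.chromatids) if c.switches]
        assert switched == sorted([i, j])
        assert all(tetrad.chromatids[k].switches == [x] for k in (i, j))

    @pytest.mark.parametrize("seed", range(5))
    def test_single_exchange_heterozygous_distal_for_both_products(self, seed):
        # A single exchange puts one recombinant and one parental chromatid
        # in each MI product, so both retained pairs disagree distal to it.
        tetrad = simulate_tetrad(1.0, "obligate_one", np.random.default_rng(seed))
        x = tetrad.chiasmata[0][0]
        proximal, distal = x / 2, (x + 1) / 2
        for k in (0, 1):
            a, b = tetrad.sister_pair(k)
            assert a.phase_at(proximal) == b.phase_at(proximal)
            assert a.phase_at(distal) != b.phase_at(distal)

    def test_poisson_chiasma_count_matches_rate(self):
        rng = np.random.default_rng(42)
        n = 20_000
        counts = [len(simulate_tetrad(1.0, "poisson", rng, 2.0).chiasmata) for _ in range(n)]
        se = np.sqrt(2.0 / n)
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_degenerate_arm_rejected(self):
        with pytest.raises(ValueError):
            simulate_tetrad(0.0)
        with pytest.raises(ValueError):
            simulate_tetrad(1.0, "poisson", chiasma_rate=0.0)


class TestRetention:
    def test_no_chiasma_retained_pair_fully_homozygous(self):
        tetrad = simulate_tetrad(1.0, "poisson", np.random.default_rng(1), chiasma_rate=1e-12)
        a, b = retain_second_polar_body(tetrad, np.random.default_rng(1))
        for x in np.linspace(0.01, 0.99, 9):
            assert a.phase_at(x) == b.phase_at(x)

    def test_obligate_one_telomeric_marker_always_heterozygous(self):
        # complete interference: the single exchange is always proximal to
        # the arm tip, so a fully distal marker is heterozygous in every
        # meiosis
        assert distal_het_frequency(2000, "obligate_one", marker_fraction=1.0, seed=3) == 1.0

    def test_no_interference_telomeric_limit_two_thirds(self):
        n = 20_000
        freq = distal_het_frequency(n, "poisson", chiasma_rate=5.0, seed=4)
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(freq - 2 / 3) < 3 * se

    def test_simulation_matches_closed_form_sds_probability(self):
        n = 20_000
        freq = distal_het_frequency(n, "poisson", chiasma_rate=2.0, marker_fraction=0.5, seed=5)
        expected = expected_sds_probability(0.5, "poisson", 2.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < 3 * se


class TestFamily:
    def test_same_seed_reproduces_matrix_bit_for_bit(self):
        cfg = SimConfig(n_offspring=20, markers_per_group=10, seed=9,
                        genotyping_error_rate=0.01, missing_rate=0.05)
        m1, t1 = simulate_family(cfg)
        m2, t2 = simulate_family(dataclasses.replace(cfg))
        assert m1.to_frame().equals(m2.to_frame())
        assert t1.markers.equals(t2.markers)
        assert t1.chiasmata.equals(t2.chiasmata)

    def test_dam_heterozygous_everywhere(self, small_family):
        matrix, _ = small_family
        assert all(is_het(gt) for gt in matrix.dam)

    def test_obligate_one_truth_has_exactly_one_chiasma_per_arm(self, small_family):
        _, truth = small_family
        counts = truth.crossover_counts()
        n_arms = sum(len(s.arm_lengths) for s in truth.config.linkage_groups)
        assert (counts["n_chiasmata"] == 1).all()
        assert len(counts) == truth.config.n_offspring * n_arms

    def test_heterozygosity_rises_with_distance_from_centromere(self, clean_family):
        matrix, truth = clean_family
        status = matrix.het_status()
        y = ((status == 1).sum(axis=1) / (status >= 0).sum(axis=1)).to_numpy()
        frac = truth.markers["arm_fraction"].to_numpy()
        # split markers at the arm midpoint: distal half must be more
        # heterozygous on average, and y must track the true E[y]=m closely
        assert y[frac > 0.5].mean() > y[frac < 0.5].mean()
        assert np.corrcoef(y, frac)[0, 1] > 0.9

    def test_mitotic_control_is_fully_homozygous(self):
        cfg = SimConfig(n_offspring=15, markers_per_group=8, retention="mitotic", seed=2)
        matrix, truth = simulate_family(cfg)
        for col in matrix.offspring_ids:
            assert not any(is_het(gt) for gt in matrix.offspring[col])
        assert (truth.markers["true_sds_prob"] == 0).all()

    def test_missingness_and_error_rates_apply(self):
        cfg = SimConfig(n_offspring=50, markers_per_group=20, seed=6,
                        missing_rate=0.2, genotyping_error_rate=0.0)
        matrix, _ = simulate_family(cfg)
        frac_missing = matrix.offspring.map(is_missing).to_numpy().mean()
        assert 0.15 < frac_missing < 0.25

    def test_contamination_marks_chosen_offspring(self):
        cfg = SimConfig(n_offspring=30, markers_per_group=10,
                        sire_contamination_fraction=0.2, seed=8)
        _, truth = simulate_family(cfg)
        assert len(truth.contaminated) == 6

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_offspring": 0},
            {"markers_per_group": 1},
            {"missing_rate": 1.5},
            {"genotyping_error_rate": -0.1},
            {"chiasma_model": "poisson", "chiasma_rate": -1.0},
            {"retention": "androgenesis"},
            {"linkage_groups": []},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_family(SimConfig(**bad))

    def test_invalid_linkage_group_spec_rejected(self):
        with pytest.raises(ValueError):
            LinkageGroupSpec("bad", (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            LinkageGroupSpec("bad", (-1.0,))
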