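"""The synthetic screen generator: integration model, selection, noise."""

import numpy as np
import pytest
from scipy.stats import kstest

from gtscreen.mapping import InsertionSite, dedupe_sites, derive_insertion_sites
from gtscreen.sim import (
    SimGene,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    emit_alignment_reports,
    load_sim_config,
    make_screen_config,
    random_genome,
    save_sim_config,
    simulate_integration,
    simulate_sorting,
)


def whole_genome_gene(effect_class="null", strength=1.0, L=100_000):
    return SimGene("G1", "chr1", "+", 0, L,
                   ((0, 200), (L - 200, L)), effect_class, strength)


class TestSimGene:
    def test_null_gene_must_have_unit_strength(self):
        with pytest.raises(ValueError):
            SimGene("G", "chr1", "+", 0, 1000, ((0, 100),), "null", 2.0)
        with pytest.raises(ValueError):
            SimGene("G", "chr1", "+", 0, 1000, ((0, 100),), "lof_positive_regulator", 1.0)

    def test_exons_must_fit_span(self):
        with pytest.raises(ValueError):
            SimGene("G", "chr1", "+", 0, 500, ((0, 100), (400, 600)))

    def test_last_intron_is_three_prime_terminal(self):
        plus = SimGene("G", "chr1", "+", 0, 1000, ((0, 100), (400, 500), (900, 1000)))
        assert plus.last_intron == (500, 900)
        minus = SimGene("G", "chr1", "-", 0, 1000, ((0, 100), (400, 500), (900, 1000)),
                        "three_prime_sense_dominant", 50.0)
        assert minus.last_intron == (100, 400)


class TestSimulationConfig:
    def test_bad_genome_length(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0, genes=[])

    def test_overlapping_genes_rejected(self):
        genes = [
            SimGene("A", "chr1", "+", 0, 1000, ((0, 100),)),
            SimGene("B", "chr1", "+", 500, 1500, ((500, 600),)),
        ]
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=10_000, genes=genes)

    def test_gate_must_yield_at_least_one_cell(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=1000, genes=[], gate_fraction=0.001,
                             n_cells_sorted_pool=100)

    def test_yaml_round_trip(self, tmp_path):
        cfg = make_screen_config(seed=5, n_genes=4, n_cells_control=100,
                                 n_cells_sorted_pool=100)
        path = tmp_path / "sim.yaml"
        save_sim_config(cfg, path)
        back = load_sim_config(path)
        assert config_to_dict(back) == config_to_dict(cfg)
        assert back.genes == cfg.genes


class TestSimulateIntegration:
    def test_zero_cells_empty_list(self):
        cfg = SimulationConfig(genome_length=1000, genes=[], seed=1)
        assert simulate_integration(cfg, 0) == []

    def test_fixed_seed_bit_identical(self):
        cfg = make_screen_config(seed=9, n_genes=10, n_cells_control=500,
                                 n_cells_sorted_pool=500)
        assert simulate_integration(cfg, 200) == simulate_integration(cfg, 200)
        assert simulate_sorting(cfg) == simulate_sorting(cfg)

    def test_unbiased_positions_are_uniform(self):
        cfg = SimulationConfig(genome_length=100_000, genes=[whole_genome_gene()],
                               tss_bias_weight=0.0, seed=2)
        sites = simulate_integration(cfg, 10_000)
        pos = np.array([s.position for s in sites])
        assert kstest(pos / cfg.genome_length, "uniform").pvalue > 0.01

    def test_strands_balanced(self):
        cfg = SimulationConfig(genome_length=100_000, genes=[], seed=3)
        sites = simulate_integration(cfg, 10_000)
        frac_plus = np.mean([s.strand == "+" for s in sites])
        assert 0.45 < frac_plus < 0.55

    def test_tss_bias_concentrates_near_gene_starts(self):
        genes, L = random_genome(n_genes=20, seed=4)
        cfg = SimulationConfig(genome_length=L, genes=genes,
                               tss_bias_weight=0.8, tss_window=500, seed=4)
        sites = simulate_integration(cfg, 10_000)
        by_start = {g.start: g for g in genes}
        starts = np.array(sorted(g.start for g in genes))
        ends = np.array([by_start[s].end for s in starts])
        n_intragenic = n_near_tss = 0
        for s in sites:
            gi = np.searchsorted(starts, s.position, side="right") - 1
            if gi < 0 or s.position >= ends[gi]:
                continue
            n_intragenic += 1
            g = by_start[starts[gi]]
            tss_dist = s.position - g.start if g.strand == "+" else g.end - 1 - s.position
            if tss_dist < 500:
                n_near_tss += 1
        assert n_near_tss / n_intragenic >= 0.70

    def test_intergenic_rate_reweights_uniform_component(self):
        genes, L = random_genome(n_genes=10, seed=6)
        genic = sum(g.end - g.start for g in genes)
        cfg = SimulationConfig(genome_length=L, genes=genes, tss_bias_weight=0.0,
                               intergenic_rate=0.0, seed=6)
        sites = simulate_integration(cfg, 2_000)
        starts = np.array([g.start for g in sorted(genes, key=lambda g: g.start)])
        ends = np.array([g.end for g in sorted(genes, key=lambda g: g.start)])
        for s in sites:
            gi = np.searchsorted(starts, s.position, side="right") - 1
            assert gi >= 0 and s.position < ends[gi], "all insertions must be genic"
        assert genic < L  # the constraint is non-trivial for this layout


class TestSimulateSorting:
    def test_null_screen_sorted_set_is_thinned_control_like_sample(self):
        cfg = make_screen_config(seed=7, n_genes=20, n_cells_control=20_000,
                                 n_cells_sorted_pool=20_000, gate_fraction=0.1)
        control, sorted_ = simulate_sorting(cfg)
        assert len(control) == 20_000
        # Binomial(20000, 0.1) 99.9% envelope
        assert 1800 <= len(sorted_) <= 2200

    def test_lof_gene_enriched_in_sorted_set(self):
        cfg = make_screen_config(
            seed=8, n_genes=20, effects={5: ("lof_positive_regulator", 50.0)},
            n_cells_control=20_000, n_cells_sorted_pool=20_000,
        )
        control, sorted_ = simulate_sorting(cfg)
        g = cfg.genes[5]

        def frac_in_gene(sites):
            return np.mean([g.start <= s.position < g.end for s in sites])

        assert frac_in_gene(sorted_) > 5 * frac_in_gene(control)

    def test_three_prime_sense_dominant_signature(self):
        # tight suppressor-screen gate (top 2%) so the 50x effect saturates;
        # TSS bias off to isolate the qualification rule itself
        cfg = make_screen_config(
            seed=10, n_genes=20, effects={3: ("three_prime_sense_dominant", 50.0)},
            n_cells_control=20_000, n_cells_sorted_pool=20_000, gate_fraction=0.02,
            tss_bias_weight=0.0,
        )
        _, sorted_ = simulate_sorting(cfg)
        g = cfg.genes[3]
        li = g.last_intron
        in_gene = [s for s in sorted_ if g.start <= s.position < g.end]
        qualifying = [
            s for s in in_gene
            if s.strand == g.strand and li[0] <= s.position < li[1]
        ]
        assert len(in_gene) >= 20
        assert len(qualifying) / len(in_gene) >= 0.90


class TestEmitAlignmentReports:
    def test_round_trip_identity_at_zero_noise(self):
        sites = [
            InsertionSite("chr1", 100, "+", 3),
            InsertionSite("chr1", 5_000, "-", 1),
            InsertionSite("chr1", 70_000, "+", 2),
        ]
        reports = emit_alignment_reports(sites, seed=1)
        assert sum(len(r.placements) for r in reports) == 6  # one per read
        assert derive_insertion_sites(reports) == sites

    def test_multimap_rate_excludes_binomial_fraction(self):
        sites = [InsertionSite("chr1", 1000 * i, "+") for i in range(1, 1001)]
        reports = emit_alignment_reports(sites, multimap_rate=0.5, seed=2,
                                         genome_length=10_000_000)
        n_excluded = sum(1 for r in reports if len(r.placements) > 1)
        # Binomial(1000, 0.5) 99% interval
        assert 459 <= n_excluded <= 541
        recovered = derive_insertion_sites(reports)
        flagged = {r.placements[0].position for r in reports if len(r.placements) > 1}
        assert len(recovered) == 1000 - n_excluded
        assert all(s.position not in flagged for s in recovered)

    def test_full_near_duplication_still_collapses_to_one_site(self):
        src = [InsertionSite("chr1", 500, "+", 30)]
        reports = emit_alignment_reports(src, near_dup_rate=0.999999, seed=3)
        out = derive_insertion_sites(reports)
        assert len(out) == 1
        assert out[0].read_support == 30
        assert abs(out[0].position - 500) <= 2

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            emit_alignment_reports([], multimap_rate=1.0)
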