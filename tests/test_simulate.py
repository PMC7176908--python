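import dataclasses

import numpy as np
import pandas as pd
import pytest

import introscan as isc
from introscan.calls import HET, NON_TRANSFORMABLE, TRANSFORMABLE
from introscan.simulate import (
    DONOR,
    RECURRENT,
    _self_with_screen,
    genotype_population,
    simulate_gamete,
)


def n_crossovers(haplotype):
    return len(haplotype.origins) - 1


class TestMeiosis:
    def test_homozygous_parent_gives_uniform_gamete(self, small_map, rng):
        parent = isc.DiploidGenome.pure(small_map, DONOR)
        gamete = simulate_gamete(parent, small_map, rng)
        hap = gamete["1H"]
        assert list(hap.origins) == [DONOR]
        hap.validate(150.0)

    def test_zero_cm_chromosome_has_no_crossover(self, rng):
        gmap = isc.GeneticMap(
            [isc.ChromosomeSpec("1H", 1_000, 0.0)], pd.DataFrame(columns=["chrom", "bp", "cM"])
        )
        f1 = isc.make_offspring(
            isc.DiploidGenome.pure(gmap, DONOR), isc.DiploidGenome.pure(gmap, RECURRENT), gmap, rng
        )
        for _ in range(20):
            hap = simulate_gamete(f1, gmap, rng)["1H"]
            assert len(hap.origins) == 1

    def test_crossover_count_matches_poisson_mean(self, small_map, rng):
        f1 = isc.make_offspring(
            isc.DiploidGenome.pure(small_map, DONOR),
            isc.DiploidGenome.pure(small_map, RECURRENT),
            small_map,
            rng,
        )
        n = 10_000
        counts = [n_crossovers(simulate_gamete(f1, small_map, rng)["1H"]) for _ in range(n)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(n)
        assert abs(mean - 1.5) < 3 * se

    def test_gametes_tile_chromosome(self, small_map, rng):
        # a few generations deep, every haplotype still tiles [0, L] exactly
        plant = isc.make_offspring(
            isc.DiploidGenome.pure(small_map, DONOR),
            isc.DiploidGenome.pure(small_map, RECURRENT),
            small_map,
            rng,
        )
        for _ in range(25):
            plant = isc.make_offspring(plant, plant, small_map, rng)
            plant.validate(small_map)


class TestOffspring:
    def test_f1_heterozygous_everywhere(self, small_map, rng):
        f1 = isc.make_offspring(
            isc.DiploidGenome.pure(small_map, DONOR),
            isc.DiploidGenome.pure(small_map, RECURRENT),
            small_map,
            rng,
        )
        pos = rng.uniform(0, 150.0, size=50)
        assert (f1.donor_dosage("1H", pos) == 1).all()

    def test_self_of_pure_line_is_pure(self, small_map, rng):
        rec = isc.DiploidGenome.pure(small_map, RECURRENT)
        child = isc.make_offspring(rec, rec, small_map, rng)
        assert child.donor_fraction(small_map) == 0.0

    def test_bc1_donor_fraction_near_quarter(self, small_map, rng):
        recurrent = isc.DiploidGenome.pure(small_map, RECURRENT)
        f1 = isc.make_offspring(isc.DiploidGenome.pure(small_map, DONOR), recurrent, small_map, rng)
        fracs = [
            isc.make_offspring(f1, recurrent, small_map, rng).donor_fraction(small_map)
            for _ in range(1_000)
        ]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.25) < 3 * se

    def test_mismatched_parents_rejected(self, small_map, rng):
        other = isc.GeneticMap(
            [isc.ChromosomeSpec("2H", 1_000, 10.0)], pd.DataFrame(columns=["chrom", "bp", "cM"])
        )
        with pytest.raises(ValueError, match="chromosome sets"):
            isc.make_offspring(
                isc.DiploidGenome.pure(small_map, DONOR),
                isc.DiploidGenome.pure(other, DONOR),
                small_map,
                rng,
            )


class TestBreedingScheme:
    def small_config(self, **kw):
        defaults = dict(
            n_backcrosses=1,
            selfing_generations_after_last_cross=1,
            selection_locus=("1H", 75.0),
            selection_misclassification_rate=0.0,
            causal_locus=("1H", 10.0),
        )
        defaults.update(kw)
        return isc.BreedingConfig(**defaults)

    def test_perfect_screen_forces_homozygous_selection_locus(self, small_map, rng):
        cfg = self.small_config()
        lines = isc.run_breeding_scheme(cfg, small_map, 20, rng)
        for line in lines:
            assert int(line.genome.donor_dosage("1H", 75.0)[0]) == 2
        assert all(line.generation == "BC1F2" for line in lines)

    def test_imperfect_screen_lets_heterozygotes_through(self, small_map, rng):
        cfg = self.small_config(selection_misclassification_rate=0.5)
        lines = isc.run_breeding_scheme(cfg, small_map, 60, rng)
        dosages = {int(line.genome.donor_dosage("1H", 75.0)[0]) for line in lines}
        assert 1 in dosages  # some survivors heterozygous
        assert 0 not in dosages  # recurrent homozygotes never pass

    def test_extinct_lineage_error_names_generation(self, small_map, rng):
        cfg = self.small_config()
        hopeless = isc.DiploidGenome.pure(small_map, RECURRENT)
        with pytest.raises(isc.ExtinctLineageError, match="BC1F2"):
            _self_with_screen(hopeless, cfg, small_map, rng, "BC1F2", max_candidates=10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            isc.BreedingConfig(selection_misclassification_rate=1.5)
        with pytest.raises(ValueError):
            isc.BreedingConfig(dominance_mode="codominant")
        with pytest.raises(ValueError):
            self.small_config(selection_locus=("1H", 999.0)).validate_loci(
                isc.GeneticMap(
                    [isc.ChromosomeSpec("1H", 1_000, 100.0)],
                    pd.DataFrame(columns=["chrom", "bp", "cM"]),
                )
            )


class TestPhenotypeModel:
    @pytest.mark.parametrize(
        "dosage,mode,expected",
        [
            (2, "dominant", TRANSFORMABLE),
            (2, "recessive", TRANSFORMABLE),
            (1, "dominant", TRANSFORMABLE),
            (1, "recessive", NON_TRANSFORMABLE),
            (0, "dominant", NON_TRANSFORMABLE),
            (0, "recessive", NON_TRANSFORMABLE),
        ],
    )
    def test_dominance_truth_table(self, small_map, rng, dosage, mode, expected):
        cfg = isc.BreedingConfig(causal_locus=("1H", 10.0), dominance_mode=mode)
        donor = isc.DiploidGenome.pure(small_map, DONOR)
        recurrent = isc.DiploidGenome.pure(small_map, RECURRENT)
        genome = {
            2: donor,
            1: isc.make_offspring(donor, recurrent, small_map, rng),
            0: recurrent,
        }[dosage]
        assert isc.assign_transformability(genome, cfg) == expected

    def test_assay_counts(self, rng):
        cfg = isc.BreedingConfig(n_embryos_per_line=50, te_if_carrier=1.0)
        zero = isc.simulate_assay(NON_TRANSFORMABLE, cfg, rng)
        assert (zero.n_transgenic, zero.te_percent) == (0, 0.0)
        full = isc.simulate_assay(TRANSFORMABLE, cfg, rng)
        assert (full.n_transgenic, full.te_percent) == (50, 100.0)

    def test_assay_te_near_binomial_mean(self, rng):
        cfg = isc.BreedingConfig(n_embryos_per_line=10_000, te_if_carrier=0.13)
        r = isc.simulate_assay(TRANSFORMABLE, cfg, rng)
        se = 100 * np.sqrt(0.13 * 0.87 / 10_000)
        assert abs(r.te_percent - 13.0) < 3 * se


class TestMarkerPanel:
    def test_informative_only_panel(self, small_map, rng):
        cfg = isc.PanelConfig(
            n_informative=10, n_monomorphic=0, n_single_parent=0, n_unmapped=0, n_parent_het=0
        )
        panel = isc.build_marker_panel(cfg, small_map, rng)
        assert len(panel) == 10
        assert (panel["true_category"] == "retained").all()

    def test_triage_recovers_construction_categories(self, rng):
        gmap = isc.build_map([isc.ChromosomeSpec("1H", 10_000_000, 50.0)], 300, rng)
        cfg = isc.PanelConfig(
            n_informative=80, n_monomorphic=150, n_single_parent=40, n_unmapped=12, n_parent_het=18
        )
        panel = isc.build_marker_panel(cfg, gmap, rng)
        assert len(panel) == cfg.total
        _, report = isc.triage_panel(panel, gmap)
        truth = panel["true_category"].value_counts().to_dict()
        assert report.counts == {cat: truth.get(cat, 0) for cat in report.counts}

    def test_panel_exceeding_map_capacity_rejected(self, small_map, rng):
        cfg = isc.PanelConfig(
            n_informative=50, n_monomorphic=0, n_single_parent=0, n_unmapped=0, n_parent_het=0
        )
        with pytest.raises(ValueError, match="map has"):
            isc.build_marker_panel(cfg, small_map, rng)


class TestGenotyping:
    def informative_panel(self, gmap, rng, **noise):
        cfg = isc.PanelConfig(
            n_informative=len(gmap.mapped_markers),
            n_monomorphic=0,
            n_single_parent=0,
            n_unmapped=0,
            n_parent_het=0,
            **noise,
        )
        return cfg, isc.build_marker_panel(cfg, gmap, rng)

    def test_error_free_calls_match_genome_origins(self, small_map, rng):
        cfg, panel = self.informative_panel(small_map, rng)
        donor = isc.DiploidGenome.pure(small_map, DONOR)
        recurrent = isc.DiploidGenome.pure(small_map, RECURRENT)
        f1 = isc.make_offspring(donor, recurrent, small_map, rng)
        bc1 = isc.make_offspring(f1, recurrent, small_map, rng)
        pop = [isc.Sample("bc1", bc1, "BC1F1", 1)]
        calls = genotype_population(pop, panel, small_map, cfg, rng)
        for marker, row in panel.iterrows():
            dosage = int(bc1.donor_dosage("1H", row["cM"])[0])
            expected = {2: row["call_donor"], 1: HET, 0: row["call_recurrent"]}[dosage]
            assert calls.loc["bc1", marker] == expected

    def test_f1_heterozygous_at_every_informative_marker(self, small_map, rng):
        cfg, panel = self.informative_panel(small_map, rng)
        f1 = isc.make_offspring(
            isc.DiploidGenome.pure(small_map, DONOR),
            isc.DiploidGenome.pure(small_map, RECURRENT),
            small_map,
            rng,
        )
        calls = genotype_population([isc.Sample("f1", f1, "F1", 0)], panel, small_map, cfg, rng)
        assert (calls.loc["f1"] == HET).all()

    def test_error_rate_recovered_from_discordance(self, rng):
        gmap = isc.build_map([isc.ChromosomeSpec("1H", 50_000_000, 100.0)], 1_000, rng)
        cfg_clean, panel = self.informative_panel(gmap, rng)
        donor = isc.DiploidGenome.pure(gmap, DONOR)
        pop = [isc.Sample(f"s{i}", donor, "P", 0) for i in range(100)]
        truth = genotype_population(pop, panel, gmap, cfg_clean, rng)
        noisy_cfg = dataclasses.replace(cfg_clean, genotyping_error_rate=0.01)
        noisy = genotype_population(pop, panel, gmap, noisy_cfg, rng)
        n = truth.size
        rate = (truth.to_numpy() != noisy.to_numpy()).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(rate - 0.01) < 3 * se


class TestStudyDeterminism:
    def test_same_seed_bitwise_identical(self):
        kw = dict(n_markers_per_chromosome=60, n_transformable=4, n_non_transformable=2)
        a = isc.simulate_mapping_study(99, **kw)
        b = isc.simulate_mapping_study(99, **kw)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.assays, b.assays)
        for sa, sb in zip(a.samples, b.samples):
            for chrom in a.genetic_map.chromosome_names:
                for ha, hb in zip(sa.genome.haplotypes[chrom], sb.genome.haplotypes[chrom]):
                    np.testing.assert_array_equal(ha.breaks, hb.breaks)
                    np.testing.assert_array_equal(ha.origins, hb.origins)

    def test_cohort_composition(self, tiny_study):
        counts = tiny_study.phenotypes["phenotype"].value_counts()
        assert counts[TRANSFORMABLE] == 8
        assert counts[NON_TRANSFORMABLE] == 3
        # every transformable line carries donor at the causal locus, no
        # non-transformable line does (dominant model)
        chrom, cm = tiny_study.breeding.causal_locus
        for line in tiny_study.samples:
            dosage = int(line.genome.donor_dosage(chrom, cm)[0])
            cls = tiny_study.phenotypes.loc[line.sample_id, "phenotype"]
            assert (dosage >= 1) == (cls == TRANSFORMABLE)
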