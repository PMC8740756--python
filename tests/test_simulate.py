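"""Synthetic-data generator: determinism, damage model, layouts, truth."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sedadna import simulate as sim
from sedadna.types import BlockLayout, SamplingSpot


def identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestPanel:
    def test_degenerate_single_species(self):
        cfg = sim.SimulationConfig(seed=1, n_families=1, species_per_family=1,
                                   mitogenome_length=500)
        panel = sim.generate_panel(cfg)
        assert panel.species == ["fam01_sp01"]
        assert panel.families == ["fam01"]
        assert len(panel.genomes["fam01_sp01"]) == 500

    def test_within_family_identity_exceeds_between(self):
        cfg = sim.SimulationConfig(seed=2, n_families=2, species_per_family=2,
                                   mitogenome_length=4000,
                                   divergence_within=0.01,
                                   divergence_between=0.10)
        panel = sim.generate_panel(cfg)
        within, between = [], []
        for a, b in itertools.combinations(panel.species, 2):
            ident = identity(panel.genomes[a], panel.genomes[b])
            (within if panel.family_of(a) == panel.family_of(b)
             else between).append(ident)
        assert np.mean(within) > np.mean(between)
        assert min(within) > max(between)

    def test_same_seed_identical_panel(self):
        cfg = sim.SimulationConfig(seed=3, mitogenome_length=800)
        assert sim.generate_panel(cfg).genomes == sim.generate_panel(cfg).genomes

    def test_rejects_inverted_divergence(self):
        cfg = sim.SimulationConfig(seed=1, mitogenome_length=500,
                                   divergence_within=0.2,
                                   divergence_between=0.1)
        with pytest.raises(ValueError, match="divergence"):
            sim.generate_panel(cfg)


class TestApplyDamage:
    def test_no_damage_no_error_is_identity(self, rng):
        seq = "ACGTCCGTAACG"
        assert sim.apply_damage(seq, rng, 0.0, 0.3, 0.0) == seq

    def test_no_cytosine_unchanged(self, rng):
        assert sim.apply_damage("GGGG", rng, 0.9, 0.0, 0.0) == "GGGG"

    def test_only_c_to_t_changes_when_error_free(self, rng):
        seq = "CCCCACGTCCCC"
        for _ in range(50):
            out = sim.apply_damage(seq, rng, 0.5, 0.1, 0.0)
            for a, b in zip(seq, out):
                assert (a == b) or (a == "C" and b == "T")

    def test_terminal_rate_matches_p0(self):
        """Monte-Carlo marginal: C at position 1 converts at rate p0."""
        rng = np.random.default_rng(7)
        n, hits = 10_000, 0
        for _ in range(n):
            out = sim.apply_damage("C" + "A" * 30, rng, 0.3, 0.3, 0.0)
            hits += out[0] == "T"
        # 99% binomial band around 0.3 for n=10,000
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(hits / n - 0.3) < 2.58 * se

    def test_decay_with_distance(self):
        """Empirical C→T rate at inner positions follows p0·exp(−λd)."""
        rng = np.random.default_rng(8)
        n = 8000
        counts = np.zeros(4)
        for _ in range(n):
            out = sim.apply_damage("CCCC" + "A" * 30, rng, 0.4, 0.5, 0.0)
            for d in range(4):
                counts[d] += out[d] == "T"
        expected = 0.4 * np.exp(-0.5 * np.arange(4))
        assert np.allclose(counts / n, expected, atol=0.02)


class TestBlock:
    def test_conservation_fragments_equal_truth(self, small_block):
        _, frags, truth = small_block
        total = sum(len(v) for v in frags.values())
        assert total == len(truth.fragment_origin)
        for spot_id, fs in frags.items():
            for fid, _ in fs:
                assert truth.fragment_origin[fid].spot_id == spot_id

    def test_composition_sums_to_one(self, small_block):
        _, _, truth = small_block
        truth.validate()
        assert any(truth.spot_composition.values())

    def test_full_contamination_flags_nothing_ancient(self, small_config,
                                                      small_panel):
        cfg = sim.SimulationConfig(**{**small_config.__dict__,
                                      "contaminant_fraction": 1.0})
        _, _, truth = sim.generate_block(cfg, small_panel)
        assert truth.fragment_origin
        assert not any(o.ancient for o in truth.fragment_origin.values())

    def test_counts_scale_with_mass(self, small_panel):
        """12 heavy vs 12 light spots: fragment totals follow the mass ratio."""
        heavy = [SamplingSpot(f"H{i}", i * 8.0, 0.0, 30.0) for i in range(12)]
        light = [SamplingSpot(f"L{i}", i * 8.0, 8.0, 3.4) for i in range(12)]
        cfg = sim.SimulationConfig(
            seed=5, n_families=3, species_per_family=2,
            mitogenome_length=3000, spots=heavy + light,
            taxa_layouts={"fam01_sp01": sim.TaxonLayout("random",
                                                        presence_prob=1.0)},
            fragments_per_mg=10.0,
        )
        _, frags, _ = sim.generate_block(cfg, small_panel)
        n_heavy = sum(len(frags[s.spot_id]) for s in heavy)
        n_light = sum(len(frags[s.spot_id]) for s in light)
        assert n_heavy / n_light == pytest.approx(30.0 / 3.4, rel=0.15)

    def test_uniform_layout_is_alternating_subgrid(self):
        spots = sim.alternating_grid_spots(n_cols=6, n_rows=4)
        layout = BlockLayout(spots=spots, area_cm2=14.0)
        present = sim.taxon_presence(
            layout, "T", sim.TaxonLayout("uniform"), seed=0
        )
        parities = set()
        for s in spots:
            col, row = round(s.x_mm / 8.0), round(s.y_mm / 8.0)
            if s.spot_id in present:
                parities.add((col + row) % 2)
        assert len(parities) == 1       # exactly one checkerboard colour
        assert len(present) == 12

    def test_errors_on_bad_config(self, small_config, small_panel):
        no_spots = sim.SimulationConfig(**{**small_config.__dict__, "spots": []})
        with pytest.raises(ValueError, match="spots"):
            sim.generate_block(no_spots, small_panel)
        no_layout = sim.SimulationConfig(
            **{**small_config.__dict__, "taxa_layouts": {}}
        )
        with pytest.raises(ValueError, match="layouts"):
            sim.generate_block(no_layout, small_panel)
        unknown = sim.SimulationConfig(
            **{**small_config.__dict__,
               "taxa_layouts": {"nope": sim.TaxonLayout("random")}}
        )
        with pytest.raises(ValueError, match="not in panel"):
            sim.generate_block(unknown, small_panel)

    def test_dataset_determinism(self, tmp_path, small_config):
        m1 = sim.write_dataset(small_config, tmp_path / "a")
        m2 = sim.write_dataset(small_config, tmp_path / "b")
        assert m1 == m2

    def test_adding_spot_does_not_perturb_others(self, small_config,
                                                 small_panel):
        cfg1 = small_config
        extra = cfg1.spots + [SamplingSpot("EXTRA", 99.0, 99.0, 10.0)]
        cfg2 = sim.SimulationConfig(**{**cfg1.__dict__, "spots": extra})
        _, f1, _ = sim.generate_block(cfg1, small_panel)
        _, f2, _ = sim.generate_block(cfg2, small_panel)
        for spot_id in f1:
            assert f1[spot_id] == f2[spot_id]


class TestNuclearSimulation:
    @pytest.mark.parametrize("sex,expected", [("male", 1 / 3),
                                              ("female", 1 / 2)])
    def test_x_fraction_matches_copy_number(self, sex, expected):
        panel = sim.generate_site_panel(1000, 1000, seed=1)
        frags, truth = sim.generate_nuclear_fragments(panel, sex, 4000, seed=2)
        assert truth["p_x_expected"] == pytest.approx(expected)
        x_frac = sum(f.is_x for f in frags) / len(frags)
        assert x_frac == pytest.approx(expected, abs=0.03)

    def test_zero_mismapping_emits_no_faunal_alleles(self):
        panel = sim.generate_site_panel(50, 50, seed=3)
        frags, _ = sim.generate_nuclear_fragments(
            panel, "male", 500, seed=4, mismapping_fraction=0.0
        )
        by_pos = {(s.chromosome, s.position): s for s in panel.sites}
        assert all(
            f.allele == by_pos[(f.chromosome, f.position)].hominin_allele
            for f in frags
        )
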