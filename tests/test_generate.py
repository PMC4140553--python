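import numpy as np
import pytest
from pydantic import ValidationError

from conftest import GUX1GUX2_COMPOSITION
from xylopat.chain import Glca
from xylopat.generate import (
    SubstitutionSpec,
    add_glca,
    apply_migration,
    generate_chain,
    generate_ensemble,
)


class TestSpecValidation:
    def test_invalid_probability_names_the_field(self):
        with pytest.raises(ValidationError, match="p_ac"):
            SubstitutionSpec(mode="bernoulli", p_ac=1.5)

    def test_dp_must_be_positive(self):
        with pytest.raises(ValidationError, match="dp"):
            SubstitutionSpec(dp=0)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="composition"):
            SubstitutionSpec(mode="composition", composition=(0.5, 0.5, 0.5, 0.5))

    def test_acetyl_partition_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="o2_fraction"):
            SubstitutionSpec(o2_fraction=0.9, o3_fraction=0.9, di_fraction=0.0)


class TestGenerateChain:
    def test_alternating_even_phase_acetylates_even_positions_only(self):
        spec = SubstitutionSpec(
            mode="alternating", dp=8, phase="even",
            o2_fraction=0.0, o3_fraction=1.0, di_fraction=0.0,
        )
        chain = generate_chain(spec)
        assert [r.index for r in chain if r.ac3] == [2, 4, 6, 8]
        assert not any(r.ac2 for r in chain)

    def test_alternating_odd_phase(self):
        spec = SubstitutionSpec(mode="alternating", dp=7, phase="odd")
        chain = generate_chain(spec)
        assert [r.index for r in chain if r.acetylated] == [1, 3, 5, 7]

    def test_bernoulli_zero_rate_gives_undecorated_chain(self):
        spec = SubstitutionSpec(mode="bernoulli", dp=40, p_ac=0.0)
        assert all(r.residue_type == "X" for r in generate_chain(spec))

    def test_composition_mode_recovers_type_fractions(self):
        spec = SubstitutionSpec(
            mode="composition", dp=10_000, composition=GUX1GUX2_COMPOSITION, seed=11
        )
        chain = generate_chain(spec)
        frac_x = sum(r.residue_type == "X" for r in chain) / chain.dp
        assert frac_x == pytest.approx(0.556, abs=0.010)

    def test_alternation_invariant_no_adjacent_same_state(self):
        spec = SubstitutionSpec(mode="alternating", dp=30, seed=3)
        chain = generate_chain(spec)
        for a, b in zip(chain.residues, chain.residues[1:]):
            assert a.acetylated != b.acetylated

    def test_same_seed_same_ensemble(self):
        spec = SubstitutionSpec(mode="bernoulli", dp=25, p_ac=0.5, seed=9)
        assert generate_ensemble(spec, 5) == generate_ensemble(spec, 5)


class TestAddGlca:
    def test_even_spaced_dp12_spacing6_places_two_glca_six_apart(self):
        spec = SubstitutionSpec(
            mode="bernoulli", dp=12, p_ac=0.0, glca_mode="even_spaced", glca_spacing=6, seed=2
        )
        chain = add_glca(generate_chain(spec), spec)
        pos = [r.index for r in chain if r.glca is not Glca.NONE]
        assert len(pos) == 2 and pos[1] - pos[0] == 6

    def test_random_zero_probability_leaves_chain_unchanged(self):
        spec = SubstitutionSpec(
            mode="alternating", dp=20, glca_mode="random", glca_p=0.0, seed=4
        )
        chain = generate_chain(spec)
        assert add_glca(chain, spec) == chain

    def test_random_count_within_binomial_3_sigma(self):
        n, p = 10_000, 0.1
        spec = SubstitutionSpec(
            mode="bernoulli", dp=n, p_ac=0.0, glca_mode="random", glca_p=p, seed=5
        )
        chain = add_glca(generate_chain(spec), spec)
        count = sum(r.glca is not Glca.NONE for r in chain)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * sigma

    def test_never_placed_on_2_o_acetylated_residue(self):
        spec = SubstitutionSpec(
            mode="bernoulli", dp=500, p_ac=1.0,
            o2_fraction=1.0, o3_fraction=0.0, di_fraction=0.0,
            glca_mode="random", glca_p=0.5, seed=6,
        )
        chain = add_glca(generate_chain(spec), spec)
        assert all(r.glca is Glca.NONE for r in chain)

    def test_spacing_below_two_rejected(self):
        with pytest.raises(ValidationError, match="glca_spacing"):
            SubstitutionSpec(glca_mode="even_spaced", glca_spacing=1)


class TestMigration:
    def test_zero_probability_is_identity(self, alternating_ac3):
        chain = alternating_ac3(20)
        assert apply_migration(chain, 0.0, seed=1) == chain

    def test_certain_migration_swaps_all_singly_acetylated(self):
        spec = SubstitutionSpec(
            mode="bernoulli", dp=50, p_ac=1.0,
            o2_fraction=1.0, o3_fraction=0.0, di_fraction=0.0, seed=8,
        )
        chain = generate_chain(spec)  # all X2
        out = apply_migration(chain, 1.0, seed=8)
        assert all(r.residue_type == "X3" for r in out)

    def test_x_and_x23_untouched_and_acetyl_count_conserved(self):
        spec = SubstitutionSpec(mode="bernoulli", dp=2000, p_ac=0.6, seed=10)
        chain = generate_chain(spec)
        out = apply_migration(chain, 0.7, seed=10)
        assert out.n_acetyl == chain.n_acetyl
        for a, b in zip(chain, out):
            if a.residue_type in ("X", "X23"):
                assert b.residue_type == a.residue_type

    def test_half_migration_fraction_within_3_sigma(self):
        n = 10_000
        spec = SubstitutionSpec(
            mode="bernoulli", dp=n, p_ac=1.0,
            o2_fraction=1.0, o3_fraction=0.0, di_fraction=0.0, seed=12,
        )
        out = apply_migration(generate_chain(spec), 0.5, seed=12)
        frac_x3 = sum(r.residue_type == "X3" for r in out) / n
        assert frac_x3 == pytest.approx(0.5, abs=0.015)
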