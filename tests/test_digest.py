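import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_chain
from xylopat.digest import (
    CM_XYN10B,
    EC_XYN30,
    EC_XYN30_TOLERANT,
    EnzymeModel,
    SubsiteRule,
    digest,
    even_dp_null_test,
    get_enzyme,
    permissible_sites,
    product_summary,
)
from xylopat.generate import SubstitutionSpec, generate_ensemble


class TestEnzymeModel:
    def test_minus_one_subsite_always_required(self):
        with pytest.raises(ValueError, match="-1"):
            EnzymeModel("bad", {}, frozenset({+1}))

    def test_preset_lookup_case_insensitive(self):
        assert get_enzyme("cmxyn10b") is CM_XYN10B
        with pytest.raises(KeyError):
            get_enzyme("nope")

    def test_rules_are_total_over_residue_states(self):
        from xylopat.chain import Glca, ResidueState

        rule = SubsiteRule(allow_ac2=False, require_o2_decoration=True)
        for ac2 in (False, True):
            for ac3 in (False, True):
                for g in Glca:
                    if g is not Glca.NONE and ac2:
                        continue
                    assert rule.allows(ResidueState(1, ac2=ac2, ac3=ac3, glca=g)) in (True, False)


class TestPermissibleSites:
    def test_alternating_3_o_dp8_gives_bonds_2_4_6(self, alternating_ac3):
        # hand enumeration over the 7 bonds of the DP8 chain
        assert permissible_sites(alternating_ac3(8), CM_XYN10B) == [2, 4, 6]

    def test_undecorated_chain_uncuttable_by_glcA_requiring_enzyme(self):
        assert permissible_sites(make_chain(10), EC_XYN30) == []

    def test_dp2_has_no_site_when_minus2_required(self):
        assert permissible_sites(make_chain(2), CM_XYN10B) == []

    def test_2_o_acetyl_at_minus2_blocks_cmxyn10b(self, alternating_ac3):
        ac3_chain = alternating_ac3(12)
        ac2_chain = make_chain(12, ac2=range(2, 13, 2))
        assert len(permissible_sites(ac2_chain, CM_XYN10B)) < len(
            permissible_sites(ac3_chain, CM_XYN10B)
        )

    def test_acetyl_substitutes_for_glca_at_minus2_of_gh30(self, alternating_ac3):
        # the strict GH30 model accepts a 2-O-acetyl where GlcA would sit
        chain = make_chain(8, ac2=range(2, 9, 2))
        assert permissible_sites(chain, EC_XYN30) != []
        # tolerant variant also cuts undecorated xylan
        assert permissible_sites(make_chain(8), EC_XYN30_TOLERANT) != []


class TestDigest:
    def test_complete_digest_of_alternating_dp8_gives_four_xyl2ac1(self, alternating_ac3):
        res = digest(alternating_ac3(8), CM_XYN10B, mode="complete")
        assert len(res.products) == 4
        assert all(p.dp == 2 and p.n_ac == 1 for p in res.products)
        assert res.cut_bonds == (2, 4, 6)

    def test_partial_with_zero_site_prob_returns_parent(self, alternating_ac3):
        res = digest(alternating_ac3(10), CM_XYN10B, mode="partial", site_prob=0.0, seed=1)
        assert len(res.products) == 1 and res.products[0].dp == 10

    def test_partial_with_prob_one_equals_complete(self, alternating_ac3):
        chain = alternating_ac3(14)
        full = digest(chain, CM_XYN10B, mode="complete")
        part = digest(chain, CM_XYN10B, mode="partial", site_prob=1.0, seed=2)
        assert part.cut_bonds == full.cut_bonds

    def test_products_ordered_reducing_to_non_reducing(self, alternating_ac3):
        res = digest(alternating_ac3(8), CM_XYN10B)
        starts = [p.parent_start for p in res.products]
        assert starts == sorted(starts) and starts[0] == 1

    @given(
        dp=st.integers(min_value=2, max_value=40),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        prob=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_residue_conservation_all_modes(self, dp, seed, prob):
        spec = SubstitutionSpec(mode="bernoulli", dp=dp, p_ac=0.5, seed=seed)
        chain = generate_ensemble(spec, 1)[0]
        for enzyme in (CM_XYN10B, EC_XYN30):
            res = digest(chain, enzyme, mode="partial", site_prob=prob, seed=seed)
            assert sum(p.dp for p in res.products) == dp
            assert sum(p.n_ac for p in res.products) == chain.n_acetyl

    @pytest.mark.parametrize("dp", range(2, 13))
    def test_alternating_products_have_even_dp_and_half_acetyls(self, dp, alternating_ac3):
        # provable from the subsite mapping; exhaustive for dp <= 12.  An
        # odd-DP parent necessarily ends on a non-acetylated residue, so its
        # final (non-reducing-end) fragment is the one odd product.
        res = digest(alternating_ac3(dp), CM_XYN10B)
        interior = res.products if dp % 2 == 0 else res.products[:-1]
        for p in interior:
            assert p.dp % 2 == 0
            assert p.n_ac == p.dp // 2

    def test_complete_digestion_is_a_fixed_point(self, rng):
        # rules are local, so products expose no site absent from the parent
        for seed in range(10):
            spec = SubstitutionSpec(mode="bernoulli", dp=30, p_ac=0.5, seed=seed)
            chain = generate_ensemble(spec, 1)[0]
            res = digest(chain, CM_XYN10B)
            for p in res.products:
                if p.dp >= 2:
                    assert permissible_sites(p.to_chain(), CM_XYN10B) == []


class TestProductSummary:
    def test_counts_and_even_fraction(self, alternating_ac3):
        res = digest(alternating_ac3(8), CM_XYN10B)
        summ = product_summary([res])
        assert summ.even_dp_fraction == 1.0
        assert summ.modal_acetyl_count(2) == 1

    def test_odd_products_only_gives_zero_even_fraction(self):
        res = digest(make_chain(6, ac3=[2, 5]), CM_XYN10B, mode="partial", site_prob=0.0, seed=0)
        # fabricate odd products by cutting a DP6 chain manually at bond 3
        from xylopat.digest import DigestResult, Oligosaccharide

        chain = make_chain(6)
        prods = (
            Oligosaccharide(chain.residues[:3]),
            Oligosaccharide(chain.residues[3:]),
        )
        dr = DigestResult(prods, (3,), 6, "manual", "complete")
        assert product_summary([dr]).even_dp_fraction == 0.0

    def test_modal_tie_breaks_to_smaller_count(self):
        from xylopat.digest import DigestResult, Oligosaccharide

        a = Oligosaccharide(make_chain(2, ac3=[1]).residues)
        b = Oligosaccharide(make_chain(2, ac3=[1, 2]).residues)
        dr1 = DigestResult((a,), (), 2, "m", "complete")
        dr2 = DigestResult((b,), (), 2, "m", "complete")
        assert product_summary([dr1, dr2]).modal_acetyl_count(2) == 1

    def test_empty_product_set_is_an_error(self):
        with pytest.raises(ValueError, match="no products"):
            product_summary([])

    def test_partial_digest_modal_acetyl_counts_match_alternation(self, alternating_ac3):
        # DP4/DP6/DP8 products of alternately acetylated xylan most often
        # carry 2/3/4 acetyl groups
        results = []
        for k in range(200):
            rng = np.random.default_rng([42, k])
            results.append(
                digest(alternating_ac3(50), CM_XYN10B, mode="partial", site_prob=0.5, rng=rng)
            )
        summ = product_summary(results)
        assert summ.modal_acetyl_count(4) == 2
        assert summ.modal_acetyl_count(6) == 3
        assert summ.modal_acetyl_count(8) == 4


class TestEvenDpNullTest:
    def test_alternating_even_fraction_significant_vs_bernoulli_null(self, alternating_ac3):
        results = [digest(alternating_ac3(50), CM_XYN10B)]
        observed = product_summary(results).even_dp_fraction
        null = SubstitutionSpec(mode="bernoulli", dp=50, p_ac=0.5, seed=0)
        p = even_dp_null_test(observed, null, CM_XYN10B, n_sims=500, seed=3, n_chains=5)
        assert p <= 0.01

    def test_zero_observed_gives_p_one_within_resolution(self):
        null = SubstitutionSpec(mode="bernoulli", dp=40, p_ac=0.5, seed=0)
        p = even_dp_null_test(0.0, null, CM_XYN10B, n_sims=100, seed=4, n_chains=3)
        assert p == pytest.approx(1.0, abs=0.02)

    def test_requires_enough_simulations(self):
        null = SubstitutionSpec(mode="bernoulli", dp=40, seed=0)
        with pytest.raises(ValueError, match="n_sims"):
            even_dp_null_test(0.5, null, CM_XYN10B, n_sims=10, seed=0)

    def test_uncuttable_null_raises_helpful_error(self):
        null = SubstitutionSpec(mode="bernoulli", dp=30, p_ac=0.0, seed=0)
        with pytest.raises(ValueError, match="no products"):
            even_dp_null_test(0.5, null, EC_XYN30, n_sims=100, seed=0, n_chains=2)
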