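import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_chain
from xylopat.chain import Glca, ResidueState, XylanChain
from xylopat.digest import CM_XYN10B, Oligosaccharide, digest
from xylopat.generate import SubstitutionSpec, generate_ensemble
from xylopat.masses import (
    DEFAULT_MASS_TABLE as MT,
    GlycanComposition,
    adduct_mz,
    match_peaks,
    neutral_mass,
    nominal_mz,
    spectrum_from_products,
    y_ion_ladder,
)


class TestNeutralMass:
    def test_single_xylose(self):
        # anhydro-pentose + terminal water = free xylose, 150.053 Da
        assert neutral_mass(GlycanComposition(1)) == pytest.approx(150.053, abs=1e-3)

    def test_xyl4ac2_with_2aa_label(self):
        comp = GlycanComposition(4, n_acetyl=2, label="2AA")
        assert neutral_mass(comp) == pytest.approx(751.254, abs=1e-3)

    def test_zero_pentose_rejected(self):
        with pytest.raises(ValueError, match="pentose"):
            GlycanComposition(0)

    def test_methyl_requires_hexuronate(self):
        with pytest.raises(ValueError, match="n_methyl"):
            GlycanComposition(4, n_methyl=1)

    def test_label_increment_independent_of_dp(self):
        for dp in (1, 3, 8):
            plain = neutral_mass(GlycanComposition(dp))
            labelled = neutral_mass(GlycanComposition(dp, label="2AA"))
            assert labelled - plain == pytest.approx(MT.label_2aa, abs=1e-9)


class TestAdductMz:
    def test_sodiated_2aa_xyl4ac2_is_nominal_774(self):
        mz = adduct_mz(neutral_mass(GlycanComposition(4, 2, label="2AA")), "M+Na")
        assert nominal_mz(mz) == 774

    def test_sodiated_2aa_xyl4ac3_is_nominal_816(self):
        mz = adduct_mz(neutral_mass(GlycanComposition(4, 3, label="2AA")), "M+Na")
        assert nominal_mz(mz) == 816

    def test_protonated_increment(self):
        assert adduct_mz(100.0, "M+H") == pytest.approx(101.0073, abs=1e-3)

    def test_strictly_monotone_in_mass(self):
        masses = np.linspace(100, 2000, 25)
        mzs = [adduct_mz(m, "M+Na") for m in masses]
        assert all(a < b for a, b in zip(mzs, mzs[1:]))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(0.0)


class TestMassAdditivityUnderDigestion:
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_products_sum_to_parent_plus_water_per_cut(self, seed):
        spec = SubstitutionSpec(mode="bernoulli", dp=30, p_ac=0.5, seed=seed)
        chain = generate_ensemble(spec, 1)[0]
        res = digest(chain, CM_XYN10B)
        parent = neutral_mass(
            GlycanComposition(chain.dp, n_acetyl=chain.n_acetyl)
        )
        total = sum(
            neutral_mass(GlycanComposition(p.dp, n_acetyl=p.n_ac))
            for p in res.products
        )
        n_cuts = len(res.cut_bonds)
        assert total == pytest.approx(parent + n_cuts * MT.water, abs=1e-6)


class TestSpectrum:
    def test_identical_products_collapse_to_one_entry(self, alternating_ac3):
        products = digest(alternating_ac3(8), CM_XYN10B).products
        entries = spectrum_from_products(products)
        assert len(entries) == 1
        assert entries[0].relative_abundance == pytest.approx(1.0)

    def test_abundances_sum_to_one(self):
        spec = SubstitutionSpec(mode="alternating", dp=40, seed=1)
        chains = generate_ensemble(spec, 30)
        products = [p for c in chains for p in digest(c, CM_XYN10B).products]
        entries = spectrum_from_products(products)
        assert sum(e.relative_abundance for e in entries) == pytest.approx(1.0, abs=1e-12)
        assert [e.mz for e in entries] == sorted(e.mz for e in entries)

    def test_partial_digest_dominated_by_half_acetylated_even_dps(self, alternating_ac3):
        products = []
        for k in range(100):
            rng = np.random.default_rng([7, k])
            products.extend(
                digest(alternating_ac3(50), CM_XYN10B, mode="partial", site_prob=0.5, rng=rng).products
            )
        entries = spectrum_from_products(products, label="2AA")
        by_dp = {}
        for e in entries:
            c = e.composition
            if by_dp.get(c.n_pentose, (0,))[0] < e.relative_abundance:
                by_dp[c.n_pentose] = (e.relative_abundance, c.n_acetyl)
        assert by_dp[4][1] == 2 and by_dp[6][1] == 3 and by_dp[8][1] == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            spectrum_from_products([])

    def test_match_peaks_within_tolerance(self):
        entries = spectrum_from_products(
            digest(make_chain(8, ac3=range(2, 9, 2)), CM_XYN10B).products, label="2AA"
        )
        peak = entries[0].mz + 0.2
        matched = match_peaks(entries, [peak, 5000.0], tol=0.3)
        assert matched[0][1] is entries[0]
        assert matched[1][1] is None


class TestYIonLadder:
    def test_differences_locate_the_acetylated_residues(self):
        # Xyl4Ac2 with acetyls at positions 2 and 4 from the reducing end
        # (AcXyl-Xyl-AcXyl-Xyl written toward the reducing end)
        oligo = Oligosaccharide(make_chain(4, ac3=[2, 4]).residues)
        ladder = y_ion_ladder(oligo, label="2AA", adduct="M+Na")
        mzs = [mz for _, mz in ladder]
        d21 = mzs[1] - mzs[0]  # adds residue 2 (acetylated)
        d32 = mzs[2] - mzs[1]  # adds residue 3 (bare)
        assert d21 == pytest.approx(MT.pentose + MT.acetyl, abs=1e-6)
        assert d32 == pytest.approx(MT.pentose, abs=1e-6)
        # the step up to the intact labelled precursor adds residue 4 (acetylated)
        precursor = adduct_mz(
            neutral_mass(GlycanComposition(4, 2, label="2AA")), "M+Na"
        )
        assert precursor - mzs[2] == pytest.approx(MT.pentose + MT.acetyl, abs=1e-6)

    def test_unacetylated_ladder_steps_are_all_pentose(self):
        oligo = Oligosaccharide(make_chain(5).residues)
        mzs = [mz for _, mz in y_ion_ladder(oligo, label="none")]
        for a, b in zip(mzs, mzs[1:]):
            assert b - a == pytest.approx(MT.pentose, abs=1e-6)

    def test_dp1_rejected(self):
        with pytest.raises(ValueError, match="dp >= 2"):
            y_ion_ladder(Oligosaccharide(make_chain(1).residues))
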