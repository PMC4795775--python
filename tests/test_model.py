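"""Carbon-labeling model: precursor distributions, amino acids, fragments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isopop.model import (
    AIR,
    DEFAULT_AMINO_ACIDS,
    HEAVY,
    LIGHT,
    PRECURSOR_CARBONS,
    BiochemParams,
    ConfigurationError,
    PopulationModel,
    PopulationState,
    amino_acid_isotopomer_distribution,
    fragment_carbon_mass_distribution,
    iterate_precursor_fixed_point,
    solve_precursor_arrays,
    solve_precursor_distributions,
)

fractions = st.floats(0.0, 1.0, allow_nan=False)


def params_state(u, ap=0.9, rev=0.5, ppp=0.5, co2=0.1):
    return PopulationState(u, BiochemParams(ap=ap, rev=rev, ppp=ppp, co2=co2))


class TestParameterContainers:
    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_fractions_validated(self, bad):
        with pytest.raises(ValueError):
            BiochemParams(ap=bad)
        with pytest.raises(ValueError):
            PopulationState(bad)

    def test_two_state_canonical_order_descending_usage(self):
        m = PopulationModel.two_state(0.3, params_state(0.2), params_state(0.9))
        assert m.states[0][1].usage12c == 0.9
        assert m.states[0][0] == pytest.approx(0.7)

    def test_weights_must_sum_to_one_and_be_positive(self):
        with pytest.raises(ValueError):
            PopulationModel(((0.5, params_state(0.5)), (0.6, params_state(0.1))))
        with pytest.raises(ValueError):
            PopulationModel(((1.2, params_state(0.5)), (-0.2, params_state(0.1))))


class TestPrecursorDistributions:
    def test_pure_light_usage_has_no_heavy_label_anywhere(self):
        dists = solve_precursor_distributions(params_state(1.0, ap=0.3, rev=0.7, co2=0.4))
        for dist in dists.values():
            for pattern, p in dist.patterns.items():
                if p > 1e-12:
                    assert HEAVY not in pattern

    def test_anaplerotic_oaa_with_air_co2_is_point_mass(self):
        # usage12c=0, AP=1, CO2=1: three heavy triose carbons + one air carbon
        dists = solve_precursor_distributions(params_state(0.0, ap=1.0, co2=1.0))
        patterns = {k: v for k, v in dists["oxaloacetate"].patterns.items() if v > 1e-12}
        assert patterns == pytest.approx({(HEAVY, HEAVY, HEAVY, AIR): 1.0})

    def test_anaplerotic_oaa_mass_is_single_bernoulli_unit(self):
        dists = solve_precursor_distributions(params_state(0.5, ap=1.0, co2=1.0))
        mass = dists["oxaloacetate"].heavy_count_distribution()
        assert mass == pytest.approx([0.5, 0, 0, 0.5, 0], abs=1e-12)

    @given(
        u=fractions, ap=fractions, rev=fractions, ppp=fractions, co2=fractions
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distributions_normalized_and_carbon_counts(self, u, ap, rev, ppp, co2):
        arrays = solve_precursor_arrays(
            PopulationState(u, BiochemParams(ap, rev, ppp, co2))
        )
        for name, vec in arrays.items():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert (vec >= -1e-15).all()
            assert len(vec) == 3 ** PRECURSOR_CARBONS[name]

    def test_direct_solve_matches_truncated_history_iteration(self):
        for u, ap, rev in [(0.37, 0.55, 0.3), (0.8, 0.2, 0.9), (0.1, 0.95, 0.05)]:
            state = params_state(u, ap=ap, rev=rev, ppp=0.4, co2=0.2)
            direct = solve_precursor_arrays(state)["oxaloacetate"]
            iterated = iterate_precursor_fixed_point(state)
            assert np.abs(direct - iterated).max() < 1e-8

    @given(u=st.floats(0.0, 1.0), ap=fractions, rev=fractions, ppp=fractions)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_label_swap_mirror_symmetry_without_air(self, u, ap, rev, ppp):
        """With co2=0 the model is symmetric under swapping sugar roles:
        the heavy-count distribution at usage p is the reversal at 1-p."""
        bio = BiochemParams(ap=ap, rev=rev, ppp=ppp, co2=0.0)
        d1 = solve_precursor_distributions(PopulationState(u, bio))
        d2 = solve_precursor_distributions(PopulationState(1.0 - u, bio))
        for name in d1:
            m1 = d1[name].heavy_count_distribution()
            m2 = d2[name].heavy_count_distribution()
            assert m1 == pytest.approx(m2[::-1], abs=1e-8)

    def test_expected_heavy_count_monotone_in_usage(self, mm):
        """More light-sugar usage never increases any fragment's mean mass."""
        grid = np.linspace(0.0, 1.0, 9)
        bio = BiochemParams(ap=0.6, rev=0.3, ppp=0.7, co2=0.2)
        prev = None
        for u in grid:
            dists = mm.state_mass_distributions(PopulationState(u, bio))
            means = {
                fid: float(np.arange(len(d)) @ d) for fid, d in dists.items()
            }
            if prev is not None:
                for fid in means:
                    assert means[fid] <= prev[fid] + 1e-9
            prev = means


class TestAminoAcids:
    def test_leucine_has_exactly_eight_labeling_classes(self):
        """Three independent source units -> 2^3 labeled combinations."""
        dists = solve_precursor_distributions(params_state(0.5))
        leu = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Leu"], dists)
        assert sum(1 for p in leu.values() if p > 0) == 8

    def test_alanine_single_unit_two_classes(self):
        dists = solve_precursor_distributions(params_state(0.5))
        ala = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Ala"], dists)
        assert ala == pytest.approx(
            {(LIGHT,) * 3: 0.5, (HEAVY,) * 3: 0.5}, abs=1e-12
        )

    def test_phenylalanine_oxidative_ppp_at_most_eight_classes(self):
        """With PPP=1, E4P is one unit, so Phe draws from 3 source units."""
        dists = solve_precursor_distributions(params_state(0.4, ppp=1.0))
        phe = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Phe"], dists)
        assert sum(1 for p in phe.values() if p > 0) <= 8

    def test_probabilities_sum_to_one(self):
        dists = solve_precursor_distributions(params_state(0.3, ap=0.4, rev=0.6))
        for aa in DEFAULT_AMINO_ACIDS.values():
            joint = amino_acid_isotopomer_distribution(aa, dists)
            assert sum(joint.values()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_precursor_raises(self):
        dists = solve_precursor_distributions(params_state(0.5))
        del dists["e4p"]
        with pytest.raises(ConfigurationError):
            amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Phe"], dists)


class TestFragmentMassDistribution:
    def test_alanine_tail_carbons_co_inherited(self):
        """Carbons 2-3 come from one unit: 75% M+0, 25% M+2 at usage 0.75."""
        dists = solve_precursor_distributions(params_state(0.75))
        ala = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Ala"], dists)
        mass = fragment_carbon_mass_distribution([2, 3], ala)
        assert mass == pytest.approx([0.75, 0.0, 0.25], abs=1e-12)

    def test_glycine_no_intermediate_mass(self):
        dists = solve_precursor_distributions(params_state(0.5))
        gly = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Gly"], dists)
        mass = fragment_carbon_mass_distribution([1, 2], gly)
        assert mass == pytest.approx([0.5, 0.0, 0.5], abs=1e-12)

    def test_fully_heavy_recapture_is_point_mass_at_top(self):
        """usage 0 with all CO2 recaptured from heavy donors -> M+n."""
        dists = solve_precursor_distributions(params_state(0.0, co2=0.0))
        for aa in ("Asp", "Glu", "Leu", "Phe"):
            definition = DEFAULT_AMINO_ACIDS[aa]
            joint = amino_acid_isotopomer_distribution(definition, dists)
            mass = fragment_carbon_mass_distribution(
                list(range(1, definition.n_carbons + 1)), joint
            )
            assert mass[-1] == pytest.approx(1.0, abs=1e-9)

    def test_position_outside_amino_acid_rejected(self):
        dists = solve_precursor_distributions(params_state(0.5))
        gly = amino_acid_isotopomer_distribution(DEFAULT_AMINO_ACIDS["Gly"], dists)
        with pytest.raises(ConfigurationError):
            fragment_carbon_mass_distribution([3], gly)

    def test_generic_marginal_agrees_with_operator_fast_path(self, mm):
        """The dict-based marginalization and the compiled per-instance
        convolution are independent routes to the same distribution."""
        state = params_state(0.35, ap=0.7, rev=0.4, ppp=0.6, co2=0.15)
        dists = solve_precursor_distributions(state)
        fast = mm.state_mass_distributions(state)
        for frag in mm.panel.fragments:
            aa = DEFAULT_AMINO_ACIDS[frag.amino_acid]
            joint = amino_acid_isotopomer_distribution(aa, dists)
            slow = fragment_carbon_mass_distribution(frag.retained_positions, joint)
            assert fast[frag.fragment_id] == pytest.approx(slow, abs=1e-9)
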