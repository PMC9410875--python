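"""Two-site lattice thermodynamics: partition fractions, ligand depletion,
cooperativity estimation, model fitting, stoichiometry."""

import math

import numpy as np
import pytest

from foxcoop.binding_model import (
    EPSILON_F1,
    LaneUnusableError,
    SiteAffinities,
    SpeciesFractions,
    TitrationLane,
    duplex_mass,
    estimate_omega,
    fit_affinities,
    infer_stoichiometry,
    macroscopic_constants,
    omega_from_lane,
    partition_fractions,
    simulate_series,
    solve_free_protein,
)
from foxcoop.reference import (
    DEFAULT_D_TOTAL,
    DEFAULT_MOLAR_RATIOS,
    DEFAULT_WT_PARAMS,
    P53_DNA,
)
from foxcoop.sequence_motif import reverse_complement


def _lane(f0, f1, f2, p=1e-6, d=2.5e-6):
    return TitrationLane(p, d, SpeciesFractions(f0, f1, f2))


def _boltzmann_enumeration(params, p):
    """Independent oracle: explicit sum over the four microstates."""
    weights = {
        "empty": 1.0,
        "site1": params.k1 * p,
        "site2": params.k2 * p,
        "both": params.omega * params.k1 * params.k2 * p * p,
    }
    z = sum(weights.values())
    return (
        weights["empty"] / z,
        (weights["site1"] + weights["site2"]) / z,
        weights["both"] / z,
    )


class TestPartitionFractions:
    def test_no_protein_all_free(self):
        f = partition_fractions(DEFAULT_WT_PARAMS, 0.0)
        assert (f.f0, f.f1, f.f2) == (1.0, 0.0, 0.0)

    def test_equal_independent_sites_hand_value(self):
        f = partition_fractions(SiteAffinities(1e6, 1e6, 1.0), 1e-6)
        assert np.allclose([f.f0, f.f1, f.f2], [0.25, 0.50, 0.25], atol=1e-15)

    def test_cooperative_hand_value(self):
        f = partition_fractions(SiteAffinities(1e6, 1e6, 4.0), 1e-6)
        assert np.allclose([f.f0, f.f1, f.f2], [1 / 7, 2 / 7, 4 / 7], atol=1e-15)

    def test_matches_boltzmann_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            params = SiteAffinities(
                10 ** rng.uniform(3, 8),
                10 ** rng.uniform(3, 8),
                10 ** rng.uniform(-2, 2),
            )
            p = 10 ** rng.uniform(-9, -4)
            f = partition_fractions(params, p)
            assert np.allclose(
                [f.f0, f.f1, f.f2], _boltzmann_enumeration(params, p), atol=1e-12
            )

    def test_normalization(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            params = SiteAffinities(
                10 ** rng.uniform(3, 8), 10 ** rng.uniform(3, 8), rng.uniform(0, 30)
            )
            f = partition_fractions(params, 10 ** rng.uniform(-9, -4))
            assert abs(f.f0 + f.f1 + f.f2 - 1.0) < 1e-9

    def test_negative_protein_rejected(self):
        with pytest.raises(ValueError):
            partition_fractions(DEFAULT_WT_PARAMS, -1e-9)


class TestSolveFreeProtein:
    def test_no_dna_returns_total(self):
        assert solve_free_protein(DEFAULT_WT_PARAMS, 1e-6, 0.0) == 1e-6

    def test_no_protein_returns_zero(self):
        assert solve_free_protein(DEFAULT_WT_PARAMS, 0.0, 2.5e-6) == 0.0

    def test_quadratic_hand_solution(self):
        # Equal independent uM-scale sites: p^2 + 3.5 p - 2.5 = 0 in uM units.
        params = SiteAffinities(1e6, 1e6, 1.0)
        p_free = solve_free_protein(params, 2.5e-6, 2.5e-6)
        expected = (-3.5 + math.sqrt(22.25)) / 2 * 1e-6
        assert p_free == pytest.approx(expected, rel=1e-12)

    def test_conservation_residual(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            params = SiteAffinities(
                10 ** rng.uniform(4, 8), 10 ** rng.uniform(4, 8), rng.uniform(0, 25)
            )
            p_tot = 10 ** rng.uniform(-7, -4)
            d_tot = 10 ** rng.uniform(-7, -4)
            p_free = solve_free_protein(params, p_tot, d_tot)
            f = partition_fractions(params, p_free)
            residual = abs(p_tot - p_free - d_tot * (f.f1 + 2 * f.f2))
            assert residual / max(p_tot, d_tot) < 1e-10


class TestSimulateSeries:
    def test_saturation_limit(self):
        lanes = simulate_series(SiteAffinities(1e6, 1e6, 1.0), [1e-2], 2.5e-6)
        assert lanes[0].fractions.f2 > 0.999

    def test_free_dna_monotone_decreasing(self):
        lanes = simulate_series(
            DEFAULT_WT_PARAMS, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS],
            DEFAULT_D_TOTAL,
        )
        f0 = [ln.fractions.f0 for ln in lanes]
        assert all(a >= b for a, b in zip(f0, f0[1:]))


class TestOmegaEstimator:
    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ((0.25, 0.50, 0.25), 1.0),
            ((1 / 7, 2 / 7, 4 / 7), 4.0),
            ((0.5, 0.5, 0.0), 0.0),
        ],
    )
    def test_lane_values(self, fracs, expected):
        assert omega_from_lane(_lane(*fracs)) == pytest.approx(expected, abs=1e-12)

    def test_small_monomer_fraction_flagged(self):
        with pytest.raises(LaneUnusableError):
            omega_from_lane(_lane(0.48, 0.04, 0.48))

    def test_exact_on_noiseless_equal_site_series(self):
        for omega in (0.5, 1.0, 3.0, 21.0):
            params = SiteAffinities(1.27e6, 1.27e6, omega)
            lanes = simulate_series(
                params, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS],
                DEFAULT_D_TOTAL,
            )
            for lane in lanes:
                if lane.fractions.f1 > EPSILON_F1:
                    assert omega_from_lane(lane) == pytest.approx(omega, rel=1e-9)

    def test_unequal_sites_bias_closed_form(self):
        # 4 f0 f2 / f1^2 = omega * 4 K1 K2 / (K1+K2)^2 for any p_free.
        params = SiteAffinities(1e6, 1e5, 3.0)
        expected = 3.0 * 4 * 1e6 * 1e5 / (1.1e6) ** 2
        lanes = simulate_series(params, [1e-6, 3e-6, 1e-5], 2.5e-6)
        for lane in lanes:
            assert omega_from_lane(lane) == pytest.approx(expected, rel=1e-9)

    def test_series_estimate_and_classification(self):
        lanes = [_lane(0.25, 0.5, 0.25)] * 4
        est = estimate_omega(lanes)
        assert est.omega_hat == pytest.approx(1.0)
        assert est.se == 0.0
        assert est.classification == "none"

    def test_positive_classification_on_cooperative_series(self):
        lanes = simulate_series(
            DEFAULT_WT_PARAMS, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS],
            DEFAULT_D_TOTAL,
        )
        est = estimate_omega(lanes)
        assert est.omega_hat == pytest.approx(3.0, rel=1e-9)
        assert est.classification == "positive"

    def test_no_usable_lane_advises(self):
        with pytest.raises(LaneUnusableError, match="mid-titration"):
            estimate_omega([_lane(0.98, 0.01, 0.01)])


class TestFitAffinities:
    def test_round_trip_noiseless(self):
        truth = SiteAffinities(1.27e6, 1.27e6, 3.0)
        lanes = simulate_series(
            truth, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS], DEFAULT_D_TOTAL
        )
        fit = fit_affinities(lanes)
        assert fit.converged
        assert fit.params.k1 == pytest.approx(truth.k1, rel=1e-6)
        assert fit.params.k2 == pytest.approx(truth.k2, rel=1e-6)
        assert fit.params.omega == pytest.approx(truth.omega, rel=1e-6)

    def test_fix_mask_pins_parameter(self):
        truth = SiteAffinities(1.27e6, 1.27e6, 3.0)
        lanes = simulate_series(
            truth, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS], DEFAULT_D_TOTAL
        )
        fit = fit_affinities(lanes, fix={"omega": 3.0})
        assert fit.params.omega == 3.0
        assert fit.params.k1 == pytest.approx(truth.k1, rel=1e-6)

    def test_no_dimer_series_drives_omega_to_zero(self):
        truth = SiteAffinities(1.27e6, 1.27e6, 1e-12)
        lanes = simulate_series(
            truth, [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS], DEFAULT_D_TOTAL
        )
        fit = fit_affinities(lanes)
        assert fit.params.omega < 1e-6

    def test_canonical_orientation(self):
        truth = SiteAffinities(1e5, 1e6, 2.0)  # deliberately K1 < K2
        lanes = simulate_series(truth, [1e-6, 2e-6, 4e-6, 8e-6], 2.5e-6)
        fit = fit_affinities(lanes, tie_sites=False, fix={"k2": 1e6})
        assert fit.params.k1 >= fit.params.k2

    def test_too_few_lanes_rejected(self):
        lanes = simulate_series(DEFAULT_WT_PARAMS, [1e-6, 2e-6], 2.5e-6)
        with pytest.raises(ValueError, match="4 lanes"):
            fit_affinities(lanes)


class TestMacroscopicConstants:
    def test_statistical_factor_for_equal_independent_sites(self):
        ka1, ka2 = macroscopic_constants(SiteAffinities(1e6, 1e6, 1.0))
        assert (ka1, ka2) == (2e6, 0.5e6)
        assert ka1 / ka2 == pytest.approx(4.0)

    def test_unequal_sites_arithmetic(self):
        ka1, ka2 = macroscopic_constants(SiteAffinities(1e6, 1e4, 1.0))
        assert ka1 == pytest.approx(1.01e6)
        assert ka2 == pytest.approx(1e10 / 1.01e6, rel=1e-12)

    def test_zero_cooperativity_closes_second_step(self):
        _, ka2 = macroscopic_constants(SiteAffinities(1e6, 1e6, 0.0))
        assert ka2 == 0.0


class TestMassAndStoichiometry:
    def test_duplex_mass_of_printed_16mer(self):
        assert duplex_mass(P53_DNA) == pytest.approx(9.9164, abs=2e-3)

    def test_mass_symmetric_under_reverse_complement(self):
        assert duplex_mass(P53_DNA) == pytest.approx(
            duplex_mass(reverse_complement(P53_DNA)), rel=1e-12
        )

    def test_empty_and_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            duplex_mass("")
        with pytest.raises(ValueError):
            duplex_mass("ACGTN")

    def test_published_masses_give_2_to_1_and_1_to_1(self):
        dna = duplex_mass(P53_DNA)
        assert infer_stoichiometry(32.7, 12.4, dna).n_protein == 2
        assert infer_stoichiometry(20.1, 12.4, dna).n_protein == 1

    def test_bare_dna_is_zero_protomers(self):
        assert infer_stoichiometry(9.9, 12.4, 9.9).n_protein == 0

    def test_impossible_mass_rejected(self):
        with pytest.raises(ValueError):
            infer_stoichiometry(2.0, 12.4, 9.9)
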