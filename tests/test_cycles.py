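"""Cycle assembly, the ddpAct statistic, noise propagation and summaries."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from nadd import cycles, mmp, simulate
from nadd.cycles import (
    NoiseModel,
    assemble_cycles,
    assay_summary,
    classify,
    compare_distributions,
    compound_profiles,
    nonadditivity_value,
    simulate_noise_cycles,
    theoretical_noise_density,
)
from conftest import brute_force_cycles, random_toy_library


def library_cycles(spec, injections=()):
    mols = simulate.enumerate_library(spec, injections)
    pairs = mmp.index_pairs({m.compound_id: m.smiles for m in mols})
    return assemble_cycles(pairs, {m.compound_id: m.true_pact for m in mols})


class TestNonadditivityValue:
    @pytest.mark.parametrize("pacts,expected", [
        ((5.0, 6.0, 7.0, 6.0), 0.0),     # perfectly additive
        ((5.0, 6.0, 6.5, 5.0), -0.5),
        ((5.0, 5.0, 5.0, 5.0), 0.0),
    ])
    def test_direct_arithmetic(self, pacts, expected):
        assert nonadditivity_value(pacts) == pytest.approx(expected)

    def test_magnitude_invariant_over_all_orientations(self):
        """|ddpAct| is the same in all 8 orientations; sign flips on mirror."""
        p = {1: 5.1, 2: 6.3, 3: 7.9, 4: 6.0}
        ref = abs((p[2] - p[1]) - (p[3] - p[4]))
        # the 8 symmetries of the cycle square: rotations of (1,2,3,4) that
        # preserve adjacency, and the reflections
        orientations = [(1, 2, 3, 4), (2, 3, 4, 1), (3, 4, 1, 2), (4, 1, 2, 3),
                        (1, 4, 3, 2), (4, 3, 2, 1), (3, 2, 1, 4), (2, 1, 4, 3)]
        signs = set()
        for o in orientations:
            v = nonadditivity_value(tuple(p[i] for i in o))
            assert abs(v) == pytest.approx(ref)
            signs.add(np.sign(v))
        assert signs == {1.0, -1.0}


class TestClassify:
    @pytest.mark.parametrize("na,sigma,expected", [
        (0.9, 0.5, "additive"),
        (1.1, 0.5, "significant"),
        (2.5, 0.5, "strong"),
        (-2.5, 0.5, "strong"),
        (0.7, 0.3, "significant"),   # threshold 0.6 at sigma 0.3
        (0.5, 0.3, "additive"),
    ])
    def test_thresholds(self, na, sigma, expected):
        assert classify(na, NoiseModel(sigma)) == expected

    def test_strong_implies_significant(self):
        noise = NoiseModel(0.5)
        assert noise.t_strong >= noise.t_significant
        assert noise.t_significant == 2 * noise.sigma_exp


class TestAssembleCycles:
    def test_minimal_2x2_block_gives_one_cycle(self, block_2x2):
        out = library_cycles(block_2x2)
        assert len(out) == 1
        assert out[0].nonadditivity == pytest.approx(0.0, abs=1e-9)

    def test_2x3_block_gives_three_cycles(self, block_2x3):
        out = library_cycles(block_2x3)
        assert len(out) == 3  # C(2,2) * C(3,2)
        assert all(abs(c.nonadditivity) < 1e-9 for c in out)

    def test_no_shared_transformations_no_cycles(self):
        pairs = mmp.index_pairs({"tol": "Cc1ccccc1", "etb": "CCc1ccccc1"})
        assert assemble_cycles(pairs, {"tol": 5.0, "etb": 6.0}) == []

    def test_injected_interaction_recovered_exactly(self, block_2x2):
        inj = [simulate.NAInjection(1, "ethyl", 2, "ethyl", 1.5)]
        out = library_cycles(block_2x2, inj)
        assert len(out) == 1
        assert abs(out[0].nonadditivity) == pytest.approx(1.5, abs=1e-9)

    def test_matches_exhaustive_quadruple_oracle_on_random_libraries(self):
        """assemble_cycles equals brute-force quadruple enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            mols = random_toy_library(rng)
            assert len(mols) <= 30
            pairs = mmp.index_pairs({m.compound_id: m.smiles for m in mols})
            got = assemble_cycles(pairs, {m.compound_id: m.true_pact for m in mols})
            keys = {(c.transformation_a, c.transformation_b) + c.compounds for c in got}
            assert len(keys) == len(got)  # emitted exactly once
            assert keys == brute_force_cycles(pairs)

    def test_output_invariant_under_pair_ordering(self, block_2x3):
        mols = simulate.enumerate_library(block_2x3)
        pairs = mmp.index_pairs({m.compound_id: m.smiles for m in mols})
        pacts = {m.compound_id: m.true_pact for m in mols}
        assert assemble_cycles(pairs, pacts) == assemble_cycles(pairs[::-1], pacts)


class TestNoise:
    def test_theoretical_density_is_normal_with_doubled_sigma(self):
        grid = np.linspace(-4, 4, 201)
        for sigma in (0.3, 0.5):
            d = theoretical_noise_density(sigma, grid)
            assert np.allclose(d, norm.pdf(grid, 0, 2 * sigma))
            # implied std via numerical second moment
            var = np.trapezoid(grid ** 2 * d, grid)
            assert np.sqrt(var) == pytest.approx(2 * sigma, rel=1e-3)

    def test_monte_carlo_noise_cycles_have_std_two_sigma(self):
        rng = np.random.default_rng(3)
        na = simulate_noise_cycles(100_000, 0.5, rng)
        assert na.std() == pytest.approx(1.0, rel=0.01)
        assert na.mean() == pytest.approx(0.0, abs=0.02)

    def test_pure_noise_significant_fraction_matches_normal_tail(self):
        rng = np.random.default_rng(4)
        na = simulate_noise_cycles(50_000, 0.5, rng)
        frac = np.mean(np.abs(na) > 1.0)
        expected = 2 * (1 - norm.cdf(1.0))  # 0.3173
        assert frac == pytest.approx(expected, abs=0.01)


class TestCompoundProfiles:
    def test_single_cycle_band_and_mean(self):
        cyc = cycles.DoubleTransformationCycle(
            ("a", "b", "c", "d"), ("*C", "*CC"), ("*Cl", "*F"),
            (5.0, 5.7, 6.1, 5.0))
        # ddpAct = 0.7 - 1.1 = -0.4; c sits 0.4 above its additive expectation
        profs = {p.compound_id: p for p in compound_profiles([cyc], NoiseModel(0.5))}
        assert profs["c"].n_cycles == 1
        assert profs["c"].mean_shift == pytest.approx(0.4)
        assert profs["a"].mean_shift == pytest.approx(0.4)   # same diagonal
        assert profs["b"].mean_shift == pytest.approx(-0.4)
        assert profs["c"].ci_high == pytest.approx(1.96)
        assert not profs["c"].significant   # 0.4 < 1.0

    def test_four_identical_cycles_band_shrinks(self):
        cycs = [
            cycles.DoubleTransformationCycle(
                ("a", f"b{i}", "c", f"d{i}"), ("*C", "*CC"), (f"*{i}", f"*x{i}"),
                (5.0, 6.0, 7.2, 5.0))
            for i in range(4)
        ]  # each ddpAct = 1.0 - 2.2 = -1.2
        profs = {p.compound_id: p for p in compound_profiles(cycs, NoiseModel(0.5))}
        assert profs["c"].n_cycles == 4
        assert abs(profs["c"].mean_shift) == pytest.approx(1.2)
        assert profs["c"].ci_high == pytest.approx(1.96 / 2)
        assert profs["c"].significant
        assert abs(profs["c"].mean_shift) > profs["c"].ci_high

    def test_injected_compound_has_largest_shift(self, block_2x3):
        inj = [simulate.NAInjection(1, "ethyl", 2, "methoxy", 2.0)]
        out = library_cycles(block_2x3, inj)
        profs = compound_profiles(out, NoiseModel(0.3))
        top = max(profs, key=lambda p: abs(p.mean_shift))
        assert top.compound_id == "S0-ethyl_methoxy"

    def test_mean_outside_ci_rule(self, block_2x3):
        inj = [simulate.NAInjection(1, "ethyl", 2, "methoxy", 2.0)]
        out = library_cycles(block_2x3, inj)
        profs = compound_profiles(out, NoiseModel(0.3), "mean_outside_ci")
        flagged = {p.compound_id for p in profs if p.significant}
        assert "S0-ethyl_methoxy" in flagged


class TestAssaySummary:
    def test_all_additive_noiseless_assay(self, block_2x3):
        out = library_cycles(block_2x3)
        s = assay_summary("A", out, 6, NoiseModel(0.5))
        assert s.n_cycles == 3
        assert s.n_cycles_significant == 0
        assert s.n_cycles_strong == 0
        assert s.n_compounds_significant == 0

    def test_pure_noise_summary_fractions(self):
        rng = np.random.default_rng(5)
        na = simulate_noise_cycles(50_000, 0.5, rng)
        cycs = [
            cycles.DoubleTransformationCycle(
                (f"a{i}", f"b{i}", f"c{i}", f"d{i}"), ("*C", "*CC"), ("*Cl", "*F"),
                (0.0, 0.0, -v, 0.0))
            for i, v in enumerate(na[:50_000])
        ]
        s = assay_summary("A", cycs, 200_000, NoiseModel(0.5))
        expected = 2 * (1 - norm.cdf(1.0))
        assert s.frac_cycles_significant == pytest.approx(expected, abs=0.01)
        assert s.std == pytest.approx(1.0, rel=0.01)
        assert abs(s.skewness) < 0.05
        assert abs(s.kurtosis_excess) < 0.1  # excess convention: normal -> 0
        assert s.n_cycles_strong <= s.n_cycles_significant <= s.n_cycles

    def test_empty_cycle_list(self):
        s = assay_summary("A", [], 30, NoiseModel(0.5))
        assert s.n_cycles == 0 and s.n_cycles_significant == 0
        assert np.isnan(s.std) and np.isnan(s.normality_p)


class TestCompareDistributions:
    def test_identical_samples_give_p_one(self):
        a = np.linspace(-1, 1, 50)
        kw, mw = compare_distributions(a, a.copy())
        assert mw == pytest.approx(1.0, abs=1e-6)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a, b = rng.normal(0, 1, 300), rng.normal(0, 1, 300)
            _, mw = compare_distributions(a, b)
            rejections += mw < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.04)

    def test_shifted_samples_detected(self):
        rng = np.random.default_rng(7)
        detected = 0
        for _ in range(20):
            a = rng.normal(0, 1, 1000)
            b = rng.normal(0.5, 1, 1000)  # shift of 0.5 sigma
            kw, mw = compare_distributions(a, b)
            detected += (mw < 0.05) and (kw < 0.05)
        assert detected >= 19

    def test_degenerate_all_tied_flagged(self):
        kw, mw = compare_distributions([1.0, 1.0], [1.0, 1.0, 1.0])
        assert np.isnan(kw) and np.isnan(mw)
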