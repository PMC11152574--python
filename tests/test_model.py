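"""Forward-model unit and property tests.

The independent oracle is a high-precision evaluation of the induction
formula with ``decimal`` (50 significant digits, term by term, no log
tricks), against which the log-space implementation is compared.
"""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twodom as td
from twodom.model import DEAD_FC1000_THRESHOLD, FlatResponseError

getcontext().prec = 50


def fc_oracle(c, eps_d, eps_l, gamma, r_star=100.0, k=3.0):
    """Arbitrary-precision term-by-term evaluation of the fold change."""
    c, eps_d, eps_l, gamma = map(lambda v: Decimal(repr(v)), (c, eps_d, eps_l, gamma))
    r, k = Decimal(repr(r_star)), Decimal(repr(k))
    x = (c / k) ** 2
    num = 1 + (-eps_l - gamma).exp() * x
    den = 1 + (-eps_l).exp() * x
    return float(1 / (1 + r * (-eps_d).exp() * num / den))


CONSTANTS = td.SystemConstants()
WT = td.ModelParams(0.0, 6.61, 5.29)


class TestFoldChange:
    def test_zero_ligand_reduces_to_leakiness(self):
        # at c = 0 the ligand term vanishes and FC = 1/(1 + R*)
        p = td.ModelParams(0.0, 3.0, -2.0)
        assert td.fold_change(0.0, p, CONSTANTS) == pytest.approx(1 / 101, rel=1e-12)

    def test_zero_coupling_gives_flat_curve(self):
        p = td.ModelParams(0.0, 5.0, 0.0)
        fc0 = td.fold_change(0.0, p, CONSTANTS)
        assert td.fold_change(500.0, p, CONSTANTS) == pytest.approx(fc0, rel=1e-12)

    def test_wild_type_fc1000(self):
        assert td.fold_change(1000.0, WT, CONSTANTS) == pytest.approx(
            fc_oracle(1000.0, 0.0, 6.61, 5.29), rel=1e-10
        )
        assert td.fold_change(1000.0, WT, CONSTANTS) == pytest.approx(0.462, abs=5e-3)

    @pytest.mark.parametrize("bad", [-1.0, -1e-9])
    def test_negative_concentration_rejected(self, bad):
        with pytest.raises(ValueError):
            td.fold_change(bad, WT, CONSTANTS)

    @pytest.mark.parametrize("kwargs", [{"r_star": 0.0}, {"r_star": -5.0}, {"k": 0.0}])
    def test_invalid_constants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            td.SystemConstants(**kwargs)

    def test_agrees_with_decimal_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            eps_d = rng.uniform(-5, 8)
            eps_l = rng.uniform(-20, 30)
            gamma = rng.uniform(-20, 30)
            c = float(rng.choice([0.0, rng.uniform(0, 3e6)]))
            got = td.fold_change(c, td.ModelParams(eps_d, eps_l, gamma), CONSTANTS)
            want = fc_oracle(c, eps_d, eps_l, gamma)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_numerically_stable_at_extreme_arguments(self):
        # c/K up to 1e6 and energies at the edges of the supported range
        for eps_l, gamma in [(-20, 30), (30, -20), (-20, -20), (30, 30)]:
            v = td.fold_change(3e6, td.ModelParams(0.0, eps_l, gamma), CONSTANTS)
            assert 0.0 < v < 1.0 and np.isfinite(v)

    @given(
        st.floats(-5, 8),
        st.floats(-15, 20),
        st.floats(-15, 20),
        st.floats(0, 1e5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bounded_in_unit_interval(self, eps_d, eps_l, gamma, c):
        v = td.fold_change(c, td.ModelParams(eps_d, eps_l, gamma), CONSTANTS)
        assert 0.0 < v < 1.0

    def test_strictly_decreasing_in_repressor_number(self):
        v = [
            td.fold_change(100.0, WT, td.SystemConstants(r_star=r))
            for r in (10.0, 100.0, 1000.0)
        ]
        assert v[0] > v[1] > v[2]


class TestSaturation:
    def test_large_coupling_saturates_to_one(self):
        p = td.ModelParams(0.0, 5.0, 50.0)
        assert td.saturation(p, CONSTANTS) == pytest.approx(1.0, abs=1e-10)

    def test_wild_type_saturation(self):
        # (1 + 100 e^-5.29)^-1
        want = 1 / (1 + 100 * math.exp(-5.29))
        assert td.saturation(WT, CONSTANTS) == pytest.approx(want, rel=1e-12)
        assert td.saturation(WT, CONSTANTS) == pytest.approx(0.664, abs=1e-3)

    def test_matches_numeric_high_concentration_limit(self):
        v = td.fold_change(1e6 * CONSTANTS.k, WT, CONSTANTS)
        assert abs(td.saturation(WT, CONSTANTS) - v) < 1e-3

    def test_increasing_in_gamma_and_eps_d(self):
        base = td.saturation(WT, CONSTANTS)
        assert td.saturation(td.ModelParams(0.0, 6.61, 6.0), CONSTANTS) > base
        assert td.saturation(td.ModelParams(1.0, 6.61, 5.29), CONSTANTS) > base


class TestEpsilonDFromLeakiness:
    def test_wild_type_reference_is_zero(self):
        assert td.epsilon_d_from_leakiness(1 / 101, 100.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_half_leakiness_value(self):
        assert td.epsilon_d_from_leakiness(0.5, 100.0) == pytest.approx(
            math.log(100), rel=1e-12
        )

    @given(st.floats(-5, 8))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_roundtrip_identity(self, eps_d):
        p = td.ModelParams(eps_d, 4.0, 2.0)
        leak = td.leakiness(p, CONSTANTS)
        assert td.epsilon_d_from_leakiness(leak, 100.0) == pytest.approx(
            eps_d, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            td.epsilon_d_from_leakiness(bad, 100.0)


class TestEC50:
    def test_flat_curve_has_no_ec50(self):
        with pytest.raises(FlatResponseError):
            td.ec50(td.ModelParams(0.0, 5.0, 0.0), CONSTANTS)

    def test_matches_dense_grid_scan_oracle(self):
        target = 0.5 * (td.leakiness(WT, CONSTANTS) + td.saturation(WT, CONSTANTS))
        grid = np.linspace(1.0, 5000.0, 2_000_001)
        fc = td.induction_curve(grid, WT, CONSTANTS)
        scan = grid[int(np.argmin(np.abs(fc - target)))]
        assert td.ec50(WT, CONSTANTS) == pytest.approx(scan, rel=1e-3)

    def test_raising_eps_l_right_shifts_the_curve(self):
        lo = td.ec50(WT, CONSTANTS)
        hi = td.ec50(td.ModelParams(0.0, 8.61, 5.29), CONSTANTS)
        assert hi > lo

    def test_defined_for_corepressor_curves(self):
        # gamma < 0: FC decreases with c, midpoint crossing still unique
        p = td.ModelParams(4.0, 9.55, -2.96)
        c = td.ec50(p, CONSTANTS)
        mid = 0.5 * (td.leakiness(p, CONSTANTS) + td.saturation(p, CONSTANTS))
        assert td.fold_change(c, p, CONSTANTS) == pytest.approx(mid, rel=1e-6)


class TestPhenotype:
    @pytest.mark.parametrize(
        "fc, wt, want",
        [
            (0.05, 0.46, td.PhenotypeLabel.DEAD),
            (0.46, 0.46, td.PhenotypeLabel.NEUTRAL),
            (0.80, 0.46, td.PhenotypeLabel.ENHANCED),
            (0.099999, 0.46, td.PhenotypeLabel.DEAD),
            (0.1, 0.46, td.PhenotypeLabel.NEUTRAL),
        ],
    )
    def test_classification(self, fc, wt, want):
        assert td.classify_phenotype(fc, wt) is want

    def test_dead_takes_precedence_over_enhanced(self):
        assert td.classify_phenotype(0.05, 0.04) is td.PhenotypeLabel.DEAD

    @pytest.mark.parametrize("fc, wt", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (-0.1, 0.5)])
    def test_domain_errors(self, fc, wt):
        with pytest.raises(ValueError):
            td.classify_phenotype(fc, wt)

    def test_threshold_constant_exported(self):
        assert DEAD_FC1000_THRESHOLD == 0.1


class TestStateFreeEnergies:
    def test_all_zero_parameters(self):
        g = td.state_free_energies(td.ModelParams(0.0, 0.0, 0.0))
        assert all(v == 0.0 for v in g.values())

    def test_wild_type_doubly_active_state(self):
        g = td.state_free_energies(WT)
        assert g["LADA"] == pytest.approx(11.90, abs=1e-9)
        assert g["LIDI"] == 0.0

    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_coupling_identity(self, eps_d, eps_l, gamma):
        g = td.state_free_energies(td.ModelParams(eps_d, eps_l, gamma))
        assert g["LADA"] - g["LADI"] - g["LIDA"] + g["LIDI"] == pytest.approx(
            gamma, abs=1e-9
        )


class TestInductionCurve:
    def test_single_point_grid_returns_leakiness(self):
        out = td.induction_curve([0.0], WT, CONSTANTS)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(td.leakiness(WT, CONSTANTS), rel=1e-12)

    def test_standard_grid_endpoints(self):
        out = td.induction_curve(td.default_grid(), WT, CONSTANTS)
        assert len(out) == 12
        assert out[0] == pytest.approx(1 / 101, rel=1e-10)
        assert out[-1] == pytest.approx(fc_oracle(1000.0, 0.0, 6.61, 5.29), rel=1e-10)

    def test_elementwise_map_commutes_with_reversal(self):
        grid = td.default_grid()
        fwd = td.induction_curve(grid, WT, CONSTANTS)
        rev = td.induction_curve(grid[::-1], WT, CONSTANTS)
        np.testing.assert_array_equal(fwd, rev[::-1])

    def test_monotone_in_concentration_according_to_gamma_sign(self):
        grid = np.linspace(1.0, 2000.0, 50)
        up = td.induction_curve(grid, td.ModelParams(0.0, 5.0, 3.0), CONSTANTS)
        down = td.induction_curve(grid, td.ModelParams(0.0, 5.0, -3.0), CONSTANTS)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)


def test_monotonicity_sign_matches_coupling_sign_on_random_parameters():
    """The coupling's sign controls whether ligand induces or corepresses."""
    rng = np.random.default_rng(7)
    grid = np.geomspace(0.1, 1e5, 60)
    for _ in range(100):
        gamma = float(rng.uniform(-8, 8))
        if abs(gamma) < 1e-3:
            continue
        p = td.ModelParams(float(rng.uniform(-3, 5)), float(rng.uniform(-5, 15)), gamma)
        fc = td.induction_curve(grid, p, CONSTANTS)
        diffs = np.diff(fc)
        assert np.all(np.sign(diffs[np.abs(diffs) > 1e-15]) == np.sign(gamma))


def test_leakiness_invariant_to_eps_l_and_gamma():
    base = td.leakiness(td.ModelParams(1.3, 0.0, 0.0), CONSTANTS)
    for eps_l, gamma in [(-10, 5), (25, -8), (3, 3)]:
        assert td.leakiness(td.ModelParams(1.3, eps_l, gamma), CONSTANTS) == base


def test_saturation_invariant_to_eps_l():
    base = td.saturation(td.ModelParams(0.5, 0.0, 2.0), CONSTANTS)
    for eps_l in (-10.0, 4.0, 25.0):
        assert td.saturation(td.ModelParams(0.5, eps_l, 2.0), CONSTANTS) == base


def test_summarize_curve_collects_consistent_descriptors():
    s = td.summarize_curve(WT, CONSTANTS)
    assert s.leakiness == pytest.approx(1 / 101, rel=1e-10)
    assert s.saturation == pytest.approx(td.saturation(WT, CONSTANTS))
    assert s.fc1000 == pytest.approx(td.fold_change(1000.0, WT, CONSTANTS))
    assert s.ec50 is not None and 0 < s.ec50 < 1000
    flat = td.summarize_curve(td.ModelParams(0.0, 5.0, 0.0), CONSTANTS)
    assert flat.ec50 is None
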