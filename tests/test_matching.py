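import numpy as np
import pytest

from indivobs import (
    MatchSetup,
    ObserverSpec,
    SDTable,
    SpectralFunction,
    cone_fundamentals,
    generate_fixture_stimuli,
    generate_population,
    lms_to_rgb,
    match_to_cielab,
    rayleigh_match,
    reference_white,
    sample_observers,
    simulate_matches,
    solve_match,
)
from indivobs.matching import (
    SingularMatchError,
    lms_to_rgb_batch,
    observer_matrix,
    rayleigh_match_batch,
    xyz_to_lab,
)
from indivobs.spectral import STIMULUS_GRID_NM


def gaussian(grid, peak, sigma):
    return np.exp(-0.5 * ((grid - peak) / sigma) ** 2)


def toy_setup(white_rule="equal-energy"):
    grid = STIMULUS_GRID_NM
    primaries = np.column_stack([
        gaussian(grid, 610.0, 30.0), gaussian(grid, 545.0, 35.0), gaussian(grid, 455.0, 25.0),
    ])
    reference = SpectralFunction(grid, np.full_like(grid, 0.4), name="toy")
    return MatchSetup(reference=reference, primaries_max=primaries,
                      white_rule=white_rule, label="toy")


@pytest.fixture(scope="module")
def observer(basis):
    return cone_fundamentals(ObserverSpec(age=32.0, field_size=8.5), basis)


class TestSolveMatch:
    def test_consistent_system_recovers_weights(self, observer):
        setup = toy_setup()
        weights = np.array([0.2, 0.5, 0.3])
        reference = SpectralFunction(setup.grid, setup.primaries_max @ weights)
        consistent = MatchSetup(reference=reference, primaries_max=setup.primaries_max,
                                white_rule="equal-energy", label="consistent")
        np.testing.assert_allclose(solve_match(observer, consistent), weights, atol=1e-12)

    def test_reference_equal_to_first_primary(self, observer):
        setup = toy_setup()
        reference = SpectralFunction(setup.grid, setup.primaries_max[:, 0])
        consistent = MatchSetup(reference=reference, primaries_max=setup.primaries_max,
                                white_rule="equal-energy", label="first-primary")
        np.testing.assert_allclose(solve_match(observer, consistent), [1.0, 0.0, 0.0],
                                   atol=1e-12)

    def test_duplicate_primary_raises_singular_error(self, observer):
        setup = toy_setup()
        primaries = setup.primaries_max.copy()
        primaries[:, 1] = primaries[:, 0]
        degenerate = MatchSetup(reference=setup.reference, primaries_max=primaries,
                                white_rule="equal-energy", label="degenerate")
        with pytest.raises(SingularMatchError, match="degenerate"):
            solve_match(observer, degenerate)


class TestReferenceWhite:
    def test_luminance_ratio_puts_reference_at_lstar_50(self, basis, five_matches):
        for setup in five_matches:
            _, t_n = reference_white(setup, basis)
            y_ref = 683.0 * basis.cie1964_on(setup.grid)[1] @ setup.reference.values
            assert y_ref / t_n[1] == pytest.approx(((50.0 + 16.0) / 116.0) ** 3, rel=1e-12)

    def test_neutral_rule_preserves_reference_shape(self, basis, five_matches):
        setup = five_matches[0]
        assert setup.white_rule == "reference-shape"
        white, _ = reference_white(setup, basis)
        ratio = white.values / setup.reference.values
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_equal_energy_rule_is_flat(self, basis, five_matches):
        setup = five_matches[2]
        assert setup.white_rule == "equal-energy"
        white, _ = reference_white(setup, basis)
        np.testing.assert_allclose(white.values, white.values[0], rtol=1e-12)

    def test_zero_reference_rejected(self, basis):
        grid = STIMULUS_GRID_NM
        setup = MatchSetup(reference=SpectralFunction(grid, np.zeros_like(grid)),
                           primaries_max=np.ones((grid.size, 3)),
                           white_rule="equal-energy", label="dark")
        with pytest.raises(ValueError, match="zero"):
            reference_white(setup, basis)


class TestMatchToCielab:
    def test_white_maps_to_lab_origin(self, basis):
        setup = toy_setup(white_rule="reference-shape")
        _, t_n = reference_white(setup, basis)
        # a spectrum equal to the reference white sits at the CIELAB origin
        lab_white = xyz_to_lab(t_n, t_n)
        np.testing.assert_allclose(lab_white, [100.0, 0.0, 0.0], atol=1e-9)
        # and the all-zero match has L* = 0 through the linear toe
        result = match_to_cielab(np.array([0.0, 0.0, 0.0]), setup, t_n, basis)
        assert result.lab[0] == pytest.approx(0.0, abs=1e-9)

    def test_lab_against_brute_force_quadrature(self, basis, observer):
        """Lab of a solved toy match must agree with an independently coded
        tristimulus sum and CIELAB conversion."""
        setup = toy_setup()
        R = solve_match(observer, setup)
        _, t_n = reference_white(setup, basis)
        result = match_to_cielab(R, setup, t_n, basis)

        matched = setup.primaries_max @ R
        cmfs = basis.cie1964_on(setup.grid)
        xyz = np.array([683.0 * sum(c * s for c, s in zip(row, matched)) for row in cmfs])

        def f(t):
            return t ** (1.0 / 3.0) if t > (6.0 / 29.0) ** 3 else t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0

        fx, fy, fz = (f(v / n) for v, n in zip(xyz, t_n))
        expected = np.array([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)])
        np.testing.assert_allclose(result.lab, expected, atol=1e-9)
        np.testing.assert_allclose(result.tristimulus, xyz, rtol=1e-9)


class TestSimulateMatches:
    def test_identical_observers_have_zero_sd(self, basis, observer, five_matches):
        stats = simulate_matches([observer] * 10, five_matches, basis)
        for s in stats.values():
            assert s.sd_a == pytest.approx(0.0, abs=1e-9)
            assert s.sd_b == pytest.approx(0.0, abs=1e-9)

    def test_cie1964_observer_matches_reference_exactly(self, basis, five_matches):
        """If the matching observer *is* the CIE 1964 observer, the matched
        spectrum is metameric to the reference for that observer, so its Lab
        equals the reference's Lab."""
        setup = five_matches[2]
        cmfs64 = basis.cie1964_on(setup.grid)
        R = solve_match(cmfs64, setup)
        _, t_n = reference_white(setup, basis)
        result = match_to_cielab(R, setup, t_n, basis)
        ref_lab = xyz_to_lab(683.0 * cmfs64 @ setup.reference.values, t_n)
        np.testing.assert_allclose(result.lab, ref_lab, atol=1e-9)
        assert ref_lab[0] == pytest.approx(50.0, abs=1e-9)

    def test_metamer_contract(self, basis, five_matches, step2, uniform_ages):
        specs = sample_observers(20, uniform_ages, 8.5, step2, seed=21)
        population = generate_population(specs, basis)
        C = observer_matrix(population, five_matches[0].grid)
        stats = simulate_matches(population, five_matches, basis)
        for setup in five_matches:
            excitations_ref = C @ setup.reference.values
            for i in range(len(population)):
                R = solve_match(C[i], setup)
                excitations_match = C[i] @ (setup.primaries_max @ R)
                np.testing.assert_allclose(excitations_match, excitations_ref[i],
                                           rtol=1e-9)
        assert set(stats) == {s.label for s in five_matches}

    def test_lab_sds_invariant_to_common_rescaling(self, basis, five_matches, step2,
                                                   uniform_ages):
        """Scaling all primaries and the reference by one positive constant
        rescales R compensatorily and leaves the Lab SDs unchanged."""
        specs = sample_observers(30, uniform_ages, 8.5, step2, seed=33)
        population = generate_population(specs, basis)
        scaled_setups = [
            MatchSetup(reference=SpectralFunction(s.grid, 3.7 * s.reference.values),
                       primaries_max=3.7 * s.primaries_max,
                       white_rule=s.white_rule, label=s.label)
            for s in five_matches
        ]
        base = simulate_matches(population, five_matches, basis)
        scaled = simulate_matches(population, scaled_setups, basis)
        for label in base:
            assert scaled[label].sd_a == pytest.approx(base[label].sd_a, rel=1e-9)
            assert scaled[label].sd_b == pytest.approx(base[label].sd_b, rel=1e-9)


class TestRayleighMatch:
    def test_identical_observers_match_identically(self, basis):
        a = cone_fundamentals(ObserverSpec(age=30.0, field_size=2.0), basis)
        b = cone_fundamentals(ObserverSpec(age=30.0, field_size=2.0), basis)
        assert rayleigh_match(a) == rayleigh_match(b)

    def test_scale_invariance_of_observer_sensitivities(self, basis):
        cf = cone_fundamentals(ObserverSpec(age=30.0, field_size=2.0), basis)
        vals = rayleigh_match(cf)
        batch = (4.2 * cf.as_matrix())[None]  # common rescale of l and m
        scaled_val = rayleigh_match_batch(batch, cf.grid)[0]
        assert scaled_val == pytest.approx(vals, rel=1e-12)

    def test_agrees_with_brute_force_ratio_scan(self, basis):
        """The 2x2 solve must land on the red fraction where the mixture's
        L/M ratio crosses the yellow's, found by bisection on a dense scan."""
        for s_L in (0.0, 2.0):
            cf = cone_fundamentals(ObserverSpec(age=30.0, field_size=2.0, s_L=s_L), basis)
            lms = cf.on_grid(np.array([700.0, 550.0, 589.0]))
            target = lms[0, 2] / lms[1, 2]

            def ratio(t):
                L = t * lms[0, 0] + (1 - t) * lms[0, 1]
                M = t * lms[1, 0] + (1 - t) * lms[1, 1]
                return L / M - target

            ts = np.linspace(0.0, 1.0, 20001)
            vals = np.array([ratio(t) for t in ts])
            idx = int(np.flatnonzero(np.diff(np.sign(vals)))[0])
            lo, hi = ts[idx], ts[idx + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if ratio(lo) * ratio(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            assert rayleigh_match(cf) == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_lmax_shift_moves_match_monotonically(self, basis):
        fractions = [
            rayleigh_match(cone_fundamentals(ObserverSpec(age=30.0, field_size=2.0, s_L=s), basis))
            for s in (0.0, 1.0, 2.0, 3.0)
        ]
        diffs = np.diff(fractions)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_batch_path_matches_scalar_path(self, basis, step2, uniform_ages):
        specs = sample_observers(10, uniform_ages, 2.0, step2, seed=4)
        population = generate_population(specs, basis)
        batch = np.stack([cf.as_matrix() for cf in population])
        batched = rayleigh_match_batch(batch, basis.grid)
        singles = [rayleigh_match(cf) for cf in population]
        np.testing.assert_allclose(batched, singles, rtol=1e-12)


class TestLmsToRgb:
    def test_unit_vectors_at_primary_wavelengths(self, basis):
        cf = cone_fundamentals(ObserverSpec(age=32.0, field_size=10.0), basis)
        rgb = lms_to_rgb(cf)
        from indivobs.spectral import spline_resample_values

        at_primaries = spline_resample_values(rgb.grid, rgb.rgb,
                                              np.array([645.2, 526.3, 444.4]))
        np.testing.assert_allclose(at_primaries, np.eye(3), atol=1e-9)

    def test_transform_is_invertible(self, basis):
        cf = cone_fundamentals(ObserverSpec(age=32.0, field_size=10.0), basis)
        rgb = lms_to_rgb(cf)
        recovered = np.linalg.inv(rgb.matrix) @ rgb.rgb
        np.testing.assert_allclose(recovered, cf.as_matrix(), atol=1e-12)

    def test_batch_path_matches_scalar_path(self, basis, step2, uniform_ages):
        specs = sample_observers(5, uniform_ages, 10.0, step2, seed=9)
        population = generate_population(specs, basis)
        batch = np.stack([cf.as_matrix() for cf in population])
        batched = lms_to_rgb_batch(batch, basis.grid)
        for i, cf in enumerate(population):
            np.testing.assert_allclose(batched[i], lms_to_rgb(cf).rgb, rtol=1e-9, atol=1e-12)
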