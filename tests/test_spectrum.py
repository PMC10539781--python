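"""Synthetic spectrum rendering, integration and scenario generation."""

import numpy as np
import pytest

from cidnp_kit.correlation import (
    fit_through_origin,
    normalize_intensities,
    sign_adjust,
)
from cidnp_kit.spectrum import (
    PeakSpec,
    generate_recovery_suite,
    integrate_windows,
    render_spectrum,
    scenario_intensities,
)
from cidnp_kit.species import RadicalPairScenario


class TestRender:
    def test_unit_area_lineshape(self):
        spec = render_spectrum(
            [PeakSpec(center=5.0, area=1.0, fwhm=0.01)], (0.0, 10.0), 200001
        )
        total = np.trapezoid(spec.amplitude, spec.ppm_axis)
        assert total == pytest.approx(1.0, abs=0.01)

    def test_no_peaks_no_noise_is_flat_zero(self):
        spec = render_spectrum([], (0.0, 1.0), 100)
        assert np.all(spec.amplitude == 0.0)

    def test_superposition(self):
        """Two overlapping peaks render as the pointwise sum of each alone."""
        p1 = PeakSpec(2.0, 1.0, 0.05)
        p2 = PeakSpec(2.02, -0.5, 0.05)
        both = render_spectrum([p1, p2], (1.0, 3.0), 5000)
        single = (
            render_spectrum([p1], (1.0, 3.0), 5000).amplitude
            + render_spectrum([p2], (1.0, 3.0), 5000).amplitude
        )
        assert np.max(np.abs(both.amplitude - single)) < 1e-12

    def test_deterministic_given_seed(self):
        a = render_spectrum([PeakSpec(5, 1)], (0, 10), 1000, noise_sigma=0.1, seed=7)
        b = render_spectrum([PeakSpec(5, 1)], (0, 10), 1000, noise_sigma=0.1, seed=7)
        c = render_spectrum([PeakSpec(5, 1)], (0, 10), 1000, noise_sigma=0.1, seed=8)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert not np.array_equal(a.amplitude, c.amplitude)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            render_spectrum([], (1.0, 1.0), 100)
        with pytest.raises(ValueError):
            render_spectrum([], (0.0, 1.0), 1)
        with pytest.raises(ValueError):
            render_spectrum([], (0.0, 1.0), 100, noise_sigma=-0.1)
        with pytest.raises(ValueError):
            PeakSpec(center=1.0, area=1.0, fwhm=-0.01)


class TestIntegrate:
    def test_unit_peak_in_window(self):
        spec = render_spectrum([PeakSpec(5.0, 1.0, 0.01)], (0, 10), 100001)
        (area,) = integrate_windows(spec, [(4.0, 6.0)])
        assert area == pytest.approx(1.0, abs=0.01)

    def test_flat_region_integrates_to_zero(self):
        spec = render_spectrum([PeakSpec(1.0, 1.0, 0.01)], (0, 10), 10001)
        (area,) = integrate_windows(spec, [(8.0, 9.0)])
        assert abs(area) < 1e-3

    def test_additive_under_trace_addition(self):
        s1 = render_spectrum([PeakSpec(2.0, 1.0)], (0, 10), 5001)
        s2 = render_spectrum([PeakSpec(8.0, -0.5)], (0, 10), 5001)
        both = render_spectrum([PeakSpec(2.0, 1.0), PeakSpec(8.0, -0.5)], (0, 10), 5001)
        windows = [(1.5, 2.5), (7.5, 8.5)]
        a = np.array(integrate_windows(both, windows))
        b = np.array(integrate_windows(s1, windows)) + np.array(
            integrate_windows(s2, windows)
        )
        assert a == pytest.approx(b, abs=1e-12)

    def test_bad_windows_rejected(self):
        spec = render_spectrum([], (0, 10), 1001)
        with pytest.raises(ValueError):
            integrate_windows(spec, [(6.0, 4.0)])
        with pytest.raises(ValueError):
            integrate_windows(spec, [(9.0, 11.0)])

    def test_fixture_round_trip(self, tml_species, tml_observations):
        """Render the four TML resonances, integrate, normalize: the signed
        relative intensities come back within +-0.02 at 1% noise."""
        expected = {
            (o.species_name, o.nucleus): o.rel_intensity for o in tml_observations
        }
        shifts = {(o.species_name, o.nucleus): o.shift for o in tml_observations}
        peaks = [
            PeakSpec(center=shifts[k], area=expected[k], fwhm=0.01) for k in expected
        ]
        clean = render_spectrum(peaks, (1.0, 5.0), 40001)
        sigma = 0.01 * float(np.max(np.abs(clean.amplitude)))
        spec = render_spectrum(peaks, (1.0, 5.0), 40001, noise_sigma=sigma, seed=202)
        keys = list(expected)
        windows = [(shifts[k] - 0.05, shifts[k] + 0.05) for k in keys]
        areas = integrate_windows(spec, windows)
        recovered = normalize_intensities(dict(zip(keys, areas)))
        for k in keys:
            assert recovered[k] == pytest.approx(expected[k], abs=0.02)


class TestScenarioIntensities:
    @pytest.fixture
    def pair(self, tml_species):
        return RadicalPairScenario(
            ox=tml_species["TMLox"], red=tml_species["TMLH2red(H5)"], mu=+1, epsilon=+1
        )

    def test_mixture_zeroes_constrained_nucleus(self, tml_species):
        # build the mixture solution directly from the exact algebra
        from cidnp_kit.deconvolution import mix_tables, solve_two_species
        from cidnp_kit.species import MixtureSolution

        pair = RadicalPairScenario(
            ox=tml_species["TMLox"], red=tml_species["TMLH2red(H5)"]
        )
        p = solve_two_species(+1.57, -5.31, 0.0)
        mixed = mix_tables(
            {"TMLH2red(H5)": p, "TMLHred": 1 - p},
            [tml_species["TMLH2red(H5)"], tml_species["TMLHred"]],
        )
        solution = MixtureSolution(
            fractions={"TMLH2red(H5)": p, "TMLHred": 1 - p},
            mixed=mixed,
            constraint_nucleus="H(6a)",
            residual=0.0,
        )
        obs = scenario_intensities(
            pair, "TMLH2red(H5)", true_slope=0.03, mixture=solution
        )
        by_nucleus = {o.nucleus: o for o in obs}
        assert by_nucleus["H(6a)"].rel_intensity == pytest.approx(0.0, abs=1e-12)
        assert by_nucleus["H(8a)"].rel_intensity == 1.0  # absorptive, strongest

    def test_singlet_precursor_flips_every_phase(self, tml_species):
        triplet = RadicalPairScenario(
            ox=tml_species["TMLox"], red=tml_species["TMLHred"], mu=+1
        )
        singlet = RadicalPairScenario(
            ox=tml_species["TMLox"], red=tml_species["TMLHred"], mu=-1
        )
        t = {o.nucleus: o.rel_intensity for o in scenario_intensities(triplet, "TMLox", 0.05)}
        s = {o.nucleus: o.rel_intensity for o in scenario_intensities(singlet, "TMLox", 0.05)}
        for n in t:
            assert s[n] == -t[n]

    def test_single_nucleus_sides_normalize_to_unit(self, tml_species):
        from cidnp_kit.species import HyperfineTable, RadicalSpecies

        ox = RadicalSpecies("O1", 2.0031, HyperfineTable({"H(1)": 7.0}), "oxidized")
        red = RadicalSpecies("R1", 2.0034, HyperfineTable({"H(2)": -3.0}), "reduced")
        pair = RadicalPairScenario(ox=ox, red=red)
        for side in ("O1", "R1"):
            (obs,) = scenario_intensities(pair, side, true_slope=0.02)
            assert abs(obs.rel_intensity) == 1.0


class TestRecoverySuite:
    def test_deterministic_for_fixed_seed(self):
        a = generate_recovery_suite(3, seed=9, n_points=2000)
        b = generate_recovery_suite(3, seed=9, n_points=2000)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.spectrum.amplitude, sb.spectrum.amplitude)
            assert sa.true_slopes == sb.true_slopes
            assert sa.true_fraction == sb.true_fraction

    def test_noiseless_inversion_from_generated_areas(self):
        """At sigma=0 the intensity pipeline returns the truth to 1e-9."""
        from cidnp_kit.deconvolution import fit_mixture
        from cidnp_kit.species import ResonanceObservation

        suite = generate_recovery_suite(10, seed=21, noise_fraction=0.0, n_points=2000)
        for sc in suite:
            keys = list(sc.noiseless_areas)
            norm = normalize_intensities(sc.noiseless_areas)
            sdg = {
                name: (+1 if sc.pair.delta_g(name) > 0 else -1)
                for name in (sc.pair.ox.name, sc.pair.red.name)
            }
            adj = sign_adjust(norm, sdg)
            for side in sdg:
                pts = [
                    (sc.pair.species(side).hyperfine[n], adj[(s, n)])
                    for (s, n) in adj
                    if s == side
                ]
                fit = fit_through_origin(pts)
                assert fit.slope == pytest.approx(sc.true_slopes[side], abs=1e-9)
            if sc.mixture_candidates is not None:
                obs = [
                    ResonanceObservation(sc.pair.red.name, n, float("nan"), v)
                    for (s, n), v in adj.items()
                    if s == sc.pair.red.name
                ]
                solution = fit_mixture(
                    obs, list(sc.mixture_candidates), sign_delta_g=sdg[sc.pair.red.name]
                )
                assert solution.fractions[
                    sc.mixture_candidates[0].name
                ] == pytest.approx(sc.true_fraction, abs=1e-6)

    def test_rendered_noiseless_spectrum_recovers_slope_closely(self):
        """Rendering plus windowed integration preserves the slope to ~1%:
        the finite-window Lorentzian truncation cancels through
        normalization up to neighbor-tail contamination."""
        suite = generate_recovery_suite(5, seed=33, noise_fraction=0.0)
        for sc in suite:
            keys = list(sc.windows)
            areas = integrate_windows(sc.spectrum, [sc.windows[k] for k in keys])
            norm = normalize_intensities(dict(zip(keys, areas)))
            sdg = {
                name: (+1 if sc.pair.delta_g(name) > 0 else -1)
                for name in (sc.pair.ox.name, sc.pair.red.name)
            }
            adj = sign_adjust(norm, sdg)
            for side in sdg:
                pts = [
                    (sc.pair.species(side).hyperfine[n], adj[(s, n)])
                    for (s, n) in adj
                    if s == side
                ]
                fit = fit_through_origin(pts)
                assert fit.slope == pytest.approx(sc.true_slopes[side], rel=0.01)
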