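"""Synthetic photo-CIDNP spectra: phase-correct rendering and integration.

The generator emulates what the instrument delivers for this chemistry:
sparse methyl singlets at fixed chemical shifts, Lorentzian lineshape,
signed (absorptive/emissive) areas following Kaptein phases with magnitudes
proportional to the effective hyperfine coupling, plus additive iid
Gaussian noise.  J-coupling multiplets, time-domain effects and baseline
artifacts are deliberately absent.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .correlation import normalize_intensities
from .kaptein import gamma
from .species import (
    HyperfineTable,
    MixtureSolution,
    RadicalPairScenario,
    RadicalSpecies,
    ResonanceObservation,
)

__all__ = [
    "PeakSpec",
    "Spectrum",
    "RecoveryScenario",
    "scenario_intensities",
    "render_spectrum",
    "integrate_windows",
    "generate_recovery_suite",
    "recover_scenario",
    "evaluate_recovery_suite",
    "DEFAULT_FWHM_PPM",
]

#: Default full width at half maximum of a rendered line, ppm.
DEFAULT_FWHM_PPM = 0.01


@dataclass(frozen=True)
class PeakSpec:
    """One resonance to render: center (ppm), signed area, FWHM (ppm)."""

    center: float
    area: float
    fwhm: float = DEFAULT_FWHM_PPM

    def __post_init__(self) -> None:
        if not math.isfinite(self.center):
            raise ValueError("peak center must be finite")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")


@dataclass(frozen=True)
class Spectrum:
    """A 1D trace on a strictly ascending ppm grid, with generation metadata."""

    ppm_axis: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_axis, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if ppm.ndim != 1 or amp.shape != ppm.shape:
            raise ValueError("ppm_axis and amplitude must be 1D arrays of equal length")
        if len(ppm) >= 2 and not np.all(np.diff(ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")
        object.__setattr__(self, "ppm_axis", ppm)
        object.__setattr__(self, "amplitude", amp)


def scenario_intensities(
    pair: RadicalPairScenario,
    observed_species: str,
    true_slope: float,
    mixture: MixtureSolution | None = None,
) -> list[ResonanceObservation]:
    """Ideal normalized signed intensities for one side of a radical pair.

    Per nucleus the signed intensity is Gamma (Kaptein phase for that side)
    times |true_slope * Aiso_eff|, where Aiso_eff comes from the observed
    radical's table or, when a mixture over protonation states is supplied
    for the reduced side, from the mixed table.  The returned intensities
    are normalized within this side to the strongest line.  A nucleus with
    zero effective coupling carries intensity 0 and significant=False.
    """
    species = pair.species(observed_species)
    table: HyperfineTable = species.hyperfine
    if mixture is not None:
        if species is not pair.red:
            raise ValueError("a protonation-state mixture applies to the reduced side")
        table = mixture.mixed
    dg = pair.delta_g(observed_species)
    if dg == 0.0:
        raise ValueError("delta_g is zero; phases undefined")
    sdg = +1 if dg > 0 else -1

    raw: dict[str, float] = {}
    for nucleus, aiso in table.items():
        if aiso == 0.0:
            raw[nucleus] = 0.0
        else:
            phase = gamma(pair.mu, pair.epsilon, sdg, +1 if aiso > 0 else -1)
            raw[nucleus] = phase * abs(true_slope * aiso)
    normalized = normalize_intensities(raw)
    return [
        ResonanceObservation(
            species_name=observed_species,
            nucleus=nucleus,
            shift=float("nan"),
            rel_intensity=value,
            significant=value != 0.0,
        )
        for nucleus, value in normalized.items()
    ]


def render_spectrum(
    peaks: list[PeakSpec],
    ppm_range: tuple[float, float],
    n_points: int,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Spectrum:
    """Sum of Lorentzian lines on a uniform grid plus Gaussian noise.

    Each peak contributes area * (hwhm/pi) / ((x-c)^2 + hwhm^2), so a peak
    has its nominal signed area when integrated over the full real line.
    Rendering is deterministic for fixed inputs and seed.
    """
    lo, hi = float(ppm_range[0]), float(ppm_range[1])
    if not hi > lo:
        raise ValueError("ppm_range must be nondegenerate (lo < hi)")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    x = np.linspace(lo, hi, n_points)
    amp = np.zeros_like(x)
    for pk in peaks:
        hwhm = pk.fwhm / 2.0
        amp += pk.area * (hwhm / np.pi) / ((x - pk.center) ** 2 + hwhm**2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, noise_sigma, size=n_points)
    return Spectrum(
        ppm_axis=x,
        amplitude=amp,
        meta={"noise_sigma": noise_sigma, "seed": seed, "n_points": n_points},
    )


def integrate_windows(
    spectrum: Spectrum, windows: list[tuple[float, float]]
) -> list[float]:
    """Trapezoidal signed area of the trace over each (lo, hi) ppm window."""
    x, amp = spectrum.ppm_axis, spectrum.amplitude
    areas: list[float] = []
    for lo, hi in windows:
        if hi <= lo:
            raise ValueError(f"inverted or empty window ({lo}, {hi})")
        if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
            raise ValueError(
                f"window ({lo}, {hi}) outside axis range ({x[0]}, {x[-1]})"
            )
        mask = (x >= lo) & (x <= hi)
        if mask.sum() < 2:
            raise ValueError(f"window ({lo}, {hi}) covers fewer than 2 grid points")
        areas.append(float(np.trapezoid(amp[mask], x[mask])))
    return areas


@dataclass(frozen=True)
class RecoveryScenario:
    """One randomized end-to-end test case with its ground truth.

    ``true_slopes`` are the per-side through-origin slopes the full pipeline
    should recover after global normalization of the integrals;
    ``true_fraction`` is the generating mixture fraction of the first
    reduced-state candidate (None for unmixed scenarios).
    """

    pair: RadicalPairScenario
    mixture_candidates: tuple[RadicalSpecies, ...] | None
    true_fraction: float | None
    true_slopes: dict  # species name -> slope (1/MHz scale after normalization)
    peak_shifts: dict  # (species name, nucleus) -> ppm
    windows: dict  # (species name, nucleus) -> (lo, hi)
    spectrum: Spectrum
    noiseless_areas: dict  # (species name, nucleus) -> signed raw area


def _random_table(rng, n_nuclei: int, prefix: str) -> HyperfineTable:
    # |Aiso| in [1, 20] MHz keeps every nucleus above the polarization
    # threshold so recovery truths are well defined.
    values = rng.uniform(1.0, 20.0, n_nuclei) * rng.choice([-1.0, 1.0], n_nuclei)
    return HyperfineTable({f"{prefix}{k}": float(v) for k, v in enumerate(values)})


def generate_recovery_suite(
    n_scenarios: int,
    seed: int,
    noise_fraction: float = 0.01,
    fwhm: float = DEFAULT_FWHM_PPM,
    mixture_probability: float = 0.5,
    n_points: int = 20000,
) -> list[RecoveryScenario]:
    """Reproducible randomized radical-pair scenarios with rendered spectra.

    Each scenario draws g values in [2.0020, 2.0045] (with |delta_g| >=
    2e-4 so the Kaptein sign is well defined), 2-4 nuclei per side with
    couplings of 1-20 MHz magnitude and random sign, random precursor
    multiplicity, and — with probability ``mixture_probability`` — a second
    reduced protonation state mixed in with fraction in [0.1, 0.9].  Peaks
    are placed on a 0-10 ppm axis with >= 0.4 ppm separation and rendered
    with Gaussian noise of ``noise_fraction`` times the maximum noiseless
    amplitude.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    master = np.random.default_rng(seed)
    scenarios: list[RecoveryScenario] = []
    for idx in range(n_scenarios):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        g_ox = float(rng.uniform(2.0020, 2.0045))
        while True:
            g_red = float(rng.uniform(2.0020, 2.0045))
            if abs(g_red - g_ox) >= 2e-4:
                break
        n_ox = int(rng.integers(2, 5))
        n_red = int(rng.integers(2, 5))
        ox = RadicalSpecies(
            name="OX", g_iso=g_ox, hyperfine=_random_table(rng, n_ox, "Hx"), role="oxidized"
        )
        mixed_case = bool(rng.random() < mixture_probability)
        if mixed_case:
            red_a = RadicalSpecies(
                name="RED_A", g_iso=g_red, hyperfine=_random_table(rng, n_red, "Hr"),
                role="reduced", protonation_label="state A",
            )
            red_b = RadicalSpecies(
                name="RED_B", g_iso=g_red, hyperfine=_random_table(rng, n_red, "Hr"),
                role="reduced", protonation_label="state B",
            )
            frac = float(rng.uniform(0.1, 0.9))
            eff_red = {
                n: frac * red_a.hyperfine[n] + (1 - frac) * red_b.hyperfine[n]
                for n in red_a.hyperfine.labels()
            }
            red = RadicalSpecies(
                name="RED", g_iso=g_red, hyperfine=HyperfineTable(eff_red), role="reduced"
            )
            candidates: tuple[RadicalSpecies, ...] | None = (red_a, red_b)
        else:
            red = RadicalSpecies(
                name="RED", g_iso=g_red, hyperfine=_random_table(rng, n_red, "Hr"),
                role="reduced",
            )
            frac = None
            candidates = None
        pair = RadicalPairScenario(
            ox=ox, red=red, mu=int(rng.choice([-1, 1])), epsilon=+1
        )

        # raw signed areas: Gamma * slope * |Aiso|, one shared true slope
        slope = 0.05
        areas: dict[tuple[str, str], float] = {}
        for side in (ox.name, red.name):
            sdg = +1 if pair.delta_g(side) > 0 else -1
            for nucleus, aiso in pair.species(side).hyperfine.items():
                phase = gamma(pair.mu, pair.epsilon, sdg, +1 if aiso > 0 else -1)
                areas[(side, nucleus)] = phase * slope * abs(aiso)
        max_area = max(abs(a) for a in areas.values())
        # After global normalization and delta-g sign adjustment the fitted
        # intensity is mu*epsilon*slope*Aiso/max_area, so the recoverable
        # slope carries the sign of mu*epsilon.
        signed = pair.mu * pair.epsilon * slope / max_area
        true_slopes = {ox.name: signed, red.name: signed}

        # distinct, well-separated peak positions on a 0-10 ppm axis
        keys = list(areas)
        positions = _separated_positions(rng, len(keys), lo=0.5, hi=9.5, min_sep=0.4)
        shifts = {k: p for k, p in zip(keys, positions)}
        # +-5 HWHM windows: the finite Lorentzian capture (~87%) is uniform
        # across peaks and cancels in normalization, while the short window
        # accumulates little integrated noise and neighbor-tail overlap
        windows = {k: (p - 0.025, p + 0.025) for k, p in shifts.items()}

        peaks = [PeakSpec(center=shifts[k], area=areas[k], fwhm=fwhm) for k in keys]
        clean = render_spectrum(peaks, (0.0, 10.0), n_points, noise_sigma=0.0)
        sigma = noise_fraction * float(np.max(np.abs(clean.amplitude)))
        spec = render_spectrum(
            peaks, (0.0, 10.0), n_points, noise_sigma=sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scenarios.append(
            RecoveryScenario(
                pair=pair,
                mixture_candidates=candidates,
                true_fraction=frac,
                true_slopes=true_slopes,
                peak_shifts=shifts,
                windows=windows,
                spectrum=spec,
                noiseless_areas=areas,
            )
        )
    return scenarios


def recover_scenario(sc: RecoveryScenario) -> dict:
    """Run the full pipeline on one scenario: integrate, normalize,
    sign-adjust, correlate per side, and (for mixtures) deconvolve.

    Returns recovered per-side slopes, the recovered fraction (or None) and
    the corresponding truths for comparison.
    """
    from .deconvolution import fit_mixture  # deferred: avoids import cycle

    keys = list(sc.windows)
    areas = integrate_windows(sc.spectrum, [sc.windows[k] for k in keys])
    normalized = normalize_intensities(dict(zip(keys, areas)))
    sides = (sc.pair.ox.name, sc.pair.red.name)
    sdg = {name: (+1 if sc.pair.delta_g(name) > 0 else -1) for name in sides}
    adjusted = {k: sdg[k[0]] * v for k, v in normalized.items()}

    from .correlation import fit_through_origin

    slopes = {}
    for side in sides:
        pts = [
            (sc.pair.species(side).hyperfine[n], adjusted[(s, n)])
            for (s, n) in adjusted
            if s == side
        ]
        slopes[side] = fit_through_origin(pts).slope

    fraction = None
    if sc.mixture_candidates is not None:
        obs = [
            ResonanceObservation(
                sc.pair.red.name, n, float("nan"), max(-1.0, min(1.0, v))
            )
            for (s, n), v in adjusted.items()
            if s == sc.pair.red.name
        ]
        solution = fit_mixture(
            obs, list(sc.mixture_candidates), sign_delta_g=sdg[sc.pair.red.name]
        )
        fraction = solution.fractions[sc.mixture_candidates[0].name]
    return {
        "slopes": slopes,
        "true_slopes": dict(sc.true_slopes),
        "fraction": fraction,
        "true_fraction": sc.true_fraction,
    }


def evaluate_recovery_suite(
    suite: list[RecoveryScenario],
    slope_rtol: float = 0.02,
    fraction_atol: float = 0.02,
) -> dict:
    """Pipeline pass rates over a recovery suite.

    A scenario passes when every per-side slope is within ``slope_rtol``
    (relative) of its truth and, for mixture scenarios, the recovered
    fraction is within ``fraction_atol`` (absolute) of the generating one.
    """
    n_pass = 0
    slope_errors: list[float] = []
    fraction_errors: list[float] = []
    for sc in suite:
        result = recover_scenario(sc)
        ok = True
        for side, recovered in result["slopes"].items():
            truth = result["true_slopes"][side]
            rel = abs(recovered - truth) / abs(truth)
            slope_errors.append(rel)
            ok = ok and rel <= slope_rtol
        if result["fraction"] is not None:
            err = abs(result["fraction"] - result["true_fraction"])
            fraction_errors.append(err)
            ok = ok and err <= fraction_atol
        n_pass += ok
    return {
        "n_scenarios": len(suite),
        "n_pass": n_pass,
        "pass_rate": n_pass / len(suite),
        "max_slope_rel_error": max(slope_errors),
        "max_fraction_abs_error": max(fraction_errors) if fraction_errors else None,
        "n_mixture_scenarios": len(fraction_errors),
    }


def _separated_positions(rng, n, lo, hi, min_sep):
    """Draw n positions in [lo, hi] pairwise separated by at least min_sep."""
    for _ in range(10000):
        pos = np.sort(rng.uniform(lo, hi, n))
        if n == 1 or np.min(np.diff(pos)) >= min_sep:
            perm = rng.permutation(n)
            return [float(p) for p in pos[perm]]
    raise RuntimeError("could not place separated peaks; range too crowded")
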