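"""End-to-end photo-CIDNP analysis: sign inference, correlations, mixture.

Reproduces, from a species table and a signed peak list, the full chain of
reasoning for a disproportionation radical-pair system:

1. invert Kaptein's rule on the oxidized-side resonances to obtain the
   precursor multiplicity, with a per-nucleus consistency check;
2. correlate sign-adjusted relative intensities with each candidate
   radical's DFT hyperfine couplings (through-origin fits);
3. deconvolve the reduced side as a two-state protonation mixture under a
   zero-coupling constraint on the unpolarized nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as cidnp_io
from .correlation import correlate_species
from .deconvolution import fit_mixture
from .kaptein import DEFAULT_ZERO_THRESHOLD_MHZ, infer_precursor
from .species import (
    PRODUCT_OF_OXIDIZED,
    PRODUCT_OF_REDUCED,
    TML_RED_ANION,
    TML_RED_H5,
    load_tml_fixture,
    species_by_name,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "InconsistentSignsError"]


class InconsistentSignsError(RuntimeError):
    """Per-nucleus Kaptein inversions disagree; no consensus multiplicity."""


@dataclass
class AnalysisConfig:
    """Configuration of the full analysis.

    With all paths None the packaged TML fixture is analyzed.  The side map
    assigns each observed (diamagnetic product) species in the peak list to
    the oxidized or reduced side of the radical pair; delta-g signs are
    derived from the radical g factors as g(own) - g(counter).
    """

    species_table: str | None = None
    species_meta: str | None = None
    peak_list: str | None = None
    epsilon: int = +1
    side_map: dict = field(
        default_factory=lambda: {
            PRODUCT_OF_OXIDIZED: "oxidized",
            PRODUCT_OF_REDUCED: "reduced",
        }
    )
    mixture_candidates: tuple[str, str] = (TML_RED_H5, TML_RED_ANION)
    constraint: tuple[str, float] = ("H(6a)", 0.0)
    reference_reduced: str = TML_RED_ANION
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD_MHZ
    output_dir: str | None = None
    seed: int = 0
    flip_delta_g_signs: bool = False  # diagnostic: invert both sides' signs


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the complete analysis and return a serializable report.

    The report is deterministic for fixed inputs and settings, and echoes
    every default in effect (normalization, R^2 convention, threshold,
    delta-g convention) for provenance.
    """
    if config.species_table is not None:
        species = cidnp_io.read_species_table(config.species_table, config.species_meta)
        observations = cidnp_io.read_peak_list(config.peak_list)
    else:
        species, observations = load_tml_fixture()
    if not observations:
        raise ValueError("empty peak list: nothing to analyze")
    if config.epsilon not in (+1, -1):
        raise ValueError("epsilon must be +1 or -1")

    by_name = species_by_name(species)
    oxidized = [sp for sp in species if sp.role == "oxidized"]
    reduced = [sp for sp in species if sp.role == "reduced"]
    if len(oxidized) != 1:
        raise ValueError(f"expected exactly one oxidized species, found {len(oxidized)}")
    ox = oxidized[0]
    if config.reference_reduced not in by_name:
        raise ValueError(f"reference reduced species {config.reference_reduced!r} unknown")
    g_red_ref = by_name[config.reference_reduced].g_iso

    flip = -1 if config.flip_delta_g_signs else +1
    sign_dg_ox = flip * (+1 if ox.g_iso - g_red_ref > 0 else -1)
    sign_dg_red = -sign_dg_ox

    obs_by_side: dict[str, list] = {"oxidized": [], "reduced": []}
    for obs in observations:
        if obs.species_name not in config.side_map:
            raise ValueError(
                f"observed species {obs.species_name!r} not assigned to a side"
            )
        obs_by_side[config.side_map[obs.species_name]].append(obs)
    if not obs_by_side["oxidized"]:
        raise ValueError("no oxidized-side observations; cannot infer precursor")

    mu, consistent, per_nucleus = infer_precursor(
        obs_by_side["oxidized"],
        ox,
        sign_delta_g=sign_dg_ox,
        epsilon=config.epsilon,
        zero_threshold=config.zero_threshold,
    )

    correlations = {}
    for sp in species:
        side = "oxidized" if sp.role == "oxidized" else "reduced"
        side_obs = obs_by_side[side]
        if not side_obs:
            continue
        sdg = sign_dg_ox if side == "oxidized" else sign_dg_red
        fit = correlate_species(sp, side_obs, sign_delta_g=sdg)
        correlations[sp.name] = {
            "slope_per_MHz": fit.slope,
            "r_squared": fit.r_squared,
            "n_points": len(fit.points),
            "sign_delta_g": sdg,
            "points": [list(p) for p in fit.points],
        }

    mixture_report = None
    if obs_by_side["reduced"] and len(config.mixture_candidates) >= 2:
        candidates = [by_name[name] for name in config.mixture_candidates]
        solution = fit_mixture(
            obs_by_side["reduced"],
            candidates,
            sign_delta_g=sign_dg_red,
            constraint=config.constraint,
        )
        fit = solution.diagnostics["fit"]
        mixture_report = {
            "fractions": {k: round(v, 3) for k, v in solution.fractions.items()},
            "fractions_full": dict(solution.fractions),
            "mixed_couplings_MHz": dict(solution.mixed.items()),
            "constraint_nucleus": solution.constraint_nucleus,
            "constraint_target_MHz": config.constraint[1],
            "slope_per_MHz": fit.slope,
            "r_squared": fit.r_squared,
            "residual_MHz": solution.residual,
            "degenerate": solution.degenerate,
            # with two points and one pinned to the origin by the constraint
            # the perfect fit is guaranteed by construction, not by the data
            "r2_non_evidential": len(fit.points) <= 2
            and solution.constraint_nucleus is not None,
            "sensitivity_dp_dAiso": {
                k: v for k, v in solution.diagnostics.items() if k.startswith("dp_")
            },
        }

    report = {
        "precursor": {
            "mu": mu,
            "multiplicity": {+1: "triplet", -1: "singlet", None: "undetermined"}[mu],
            "consistent": consistent,
            "epsilon": config.epsilon,
            "sign_delta_g_observed_side": sign_dg_ox,
            "per_nucleus": per_nucleus,
        },
        "correlations": correlations,
        "mixture": mixture_report,
        "settings": {
            "r_squared_convention": "centered total sum of squares",
            "normalization": "divide by maximum absolute integral",
            "zero_threshold_MHz": config.zero_threshold,
            "delta_g_convention": "g(observed radical) - g(counter radical)",
            "include_insignificant_points": True,
            "seed": config.seed,
        },
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cidnp_io.write_report(report, out / "report.json", out / "report.txt")

    if not consistent:
        exc = InconsistentSignsError(
            "per-nucleus Kaptein inversions disagree; see report for details"
        )
        exc.report = report
        raise exc
    return report
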