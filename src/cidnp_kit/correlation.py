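"""Intensity normalization, delta-g sign adjustment and through-origin fits.

In the high-field approximation the net CIDNP intensity of a weakly coupled
nucleus is proportional to its isotropic hyperfine coupling in the
paramagnetic precursor.  Correlating signed relative intensities against
DFT couplings therefore tests a candidate radical assignment: a good
candidate gives a straight line through the origin.

Intensities are first multiplied by sgn(delta_g) of the observed side so
that both sides of a radical pair fall on a common positive-slope line, then
regressed through the origin: slope = sum(x*y)/sum(x^2).  The coefficient of
determination uses the centered total sum of squares,
R^2 = 1 - SSE / sum((y - mean(y))^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import RadicalSpecies, ResonanceObservation

__all__ = [
    "CorrelationFit",
    "normalize_intensities",
    "sign_adjust",
    "fit_through_origin",
    "correlate_species",
]


@dataclass(frozen=True)
class CorrelationFit:
    """Through-origin regression result for (Aiso, intensity) points."""

    points: tuple[tuple[float, float], ...]
    slope: float  # 1/MHz
    r_squared: float
    residuals: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if np.isfinite(self.r_squared) and self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        if len(self.residuals) != len(self.points):
            raise ValueError("one residual per point required")


def normalize_intensities(raw_integrals: dict) -> dict:
    """Scale signed integrals by the maximum absolute integral.

    The result lies in [-1, 1] with exactly one entry of unit magnitude
    (ties share it).  Signs, i.e. absorptive/emissive phases, are preserved.
    Raises ``ValueError`` when every integral is zero.
    """
    if not raw_integrals:
        raise ValueError("empty integral map")
    peak = max(abs(v) for v in raw_integrals.values())
    if peak == 0.0:
        raise ValueError("all integrals are zero; normalization undefined")
    return {k: v / peak for k, v in raw_integrals.items()}


def sign_adjust(intensities: dict, sign_delta_g_per_species: dict) -> dict:
    """Multiply each intensity by sgn(delta_g) of its species.

    Keys of ``intensities`` are ``(species_name, nucleus)`` pairs.  This is
    the adjustment that folds the emissive and absorptive sides of a radical
    pair onto one common correlation line.
    """
    out = {}
    for (species_name, nucleus), value in intensities.items():
        if species_name not in sign_delta_g_per_species:
            raise KeyError(f"no delta-g sign provided for species {species_name!r}")
        sign = sign_delta_g_per_species[species_name]
        if sign not in (+1, -1):
            raise ValueError(f"delta-g sign for {species_name!r} must be +1 or -1")
        out[(species_name, nucleus)] = sign * value
    return out


def fit_through_origin(points) -> CorrelationFit:
    """Least-squares line through the origin, y = m*x.

    slope m = sum(x*y) / sum(x^2); R^2 uses the centered total sum of
    squares.  With constant y the centered R^2 is degenerate: it is
    reported as 1.0 for a perfect fit and NaN otherwise.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points for a through-origin fit")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all x are zero; slope undefined")
    slope = float(x @ y) / sxx
    residuals = y - slope * x
    sse = float(residuals @ residuals)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2 = 1.0 if sse <= 1e-300 else float("nan")
    else:
        r2 = 1.0 - sse / sst
    return CorrelationFit(
        points=tuple(pts),
        slope=slope,
        r_squared=r2,
        residuals=tuple(float(r) for r in residuals),
    )


def correlate_species(
    species: RadicalSpecies,
    observations: list[ResonanceObservation],
    sign_delta_g: int,
    include_insignificant: bool = True,
) -> CorrelationFit:
    """Regress adjusted CIDNP intensities on a candidate radical's couplings.

    Builds (Aiso, sgn(delta_g) * intensity) pairs for every observation and
    fits through the origin.  Non-significant observations enter as exact
    zeros by default (they are genuine data points: the spectrum shows no
    polarization there); set ``include_insignificant=False`` to drop them.
    """
    if sign_delta_g not in (+1, -1):
        raise ValueError("sign_delta_g must be +1 or -1")
    pts: list[tuple[float, float]] = []
    for obs in observations:
        if obs.nucleus not in species.hyperfine:
            raise KeyError(
                f"nucleus {obs.nucleus!r} missing from hyperfine table of "
                f"{species.name!r}"
            )
        if not obs.significant and not include_insignificant:
            continue
        pts.append((species.hyperfine[obs.nucleus], sign_delta_g * obs.effective_intensity))
    return fit_through_origin(pts)
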