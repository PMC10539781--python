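"""Kaptein's net-polarization sign rule: forward prediction and inversion.

For a resonance of nucleus i in a geminate radical-pair product, the net
CIDNP phase is

    Gamma_i = mu * epsilon * sgn(delta_g) * sgn(Aiso_i)

with mu the precursor multiplicity (+1 triplet, -1 singlet), epsilon the
exit channel (+1 recombination, -1 escape), delta_g the g-factor difference
taken as g(observed radical) - g(counter radical), and Aiso_i the isotropic
hyperfine coupling of nucleus i in the observed radical.  Gamma_i = +1 means
enhanced absorption, -1 emission.

Because the rule is a product of four signs, knowing any three factors and
the observed phase determines the fourth uniquely; this is how a measured
emission/absorption pattern pins down the precursor multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .species import RadicalPairScenario, RadicalSpecies, ResonanceObservation

__all__ = [
    "UNKNOWN",
    "SignParameters",
    "gamma",
    "predict_pattern",
    "infer_unknown",
    "infer_precursor",
    "DEFAULT_ZERO_THRESHOLD_MHZ",
]

#: Sentinel for the single unknown factor in an inversion problem.
UNKNOWN = None

#: Couplings at or below this magnitude (MHz) are treated as producing no
#: observable net polarization.  Operationalizes "hardly any
#: hyperpolarization" for near-zero effective couplings.
DEFAULT_ZERO_THRESHOLD_MHZ = 0.5

_SIGNS = (+1, -1)


def _check_sign(value: int, name: str) -> int:
    # bools compare equal to 0/1; signs must be literal integers +-1
    if isinstance(value, bool) or value not in _SIGNS:
        raise ValueError(f"{name} must be +1 or -1, got {value!r}")
    return value


@dataclass(frozen=True)
class SignParameters:
    """The four factors of the sign rule; each +1, -1 or UNKNOWN (None)."""

    mu: int | None
    epsilon: int | None
    sign_delta_g: int | None
    sign_aiso: int | None

    def __post_init__(self) -> None:
        for name in ("mu", "epsilon", "sign_delta_g", "sign_aiso"):
            v = getattr(self, name)
            if v is not UNKNOWN and v not in _SIGNS:
                raise ValueError(f"{name} must be +1, -1 or UNKNOWN, got {v!r}")

    def unknown_fields(self) -> list[str]:
        return [
            name
            for name in ("mu", "epsilon", "sign_delta_g", "sign_aiso")
            if getattr(self, name) is UNKNOWN
        ]


def gamma(mu: int, epsilon: int, sign_delta_g: int, sign_aiso: int) -> int:
    """Net polarization phase: the product of the four signs.

    Returns +1 (enhanced absorption) or -1 (emission).
    """
    _check_sign(mu, "mu")
    _check_sign(epsilon, "epsilon")
    _check_sign(sign_delta_g, "sign_delta_g")
    _check_sign(sign_aiso, "sign_aiso")
    return mu * epsilon * sign_delta_g * sign_aiso


def predict_pattern(
    pair: RadicalPairScenario,
    observed_species: str,
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD_MHZ,
) -> dict[str, int | None]:
    """Predict the CIDNP phase of every nucleus of one side of a pair.

    For each nucleus of the observed radical with |Aiso| above
    ``zero_threshold`` the Kaptein phase is computed with that side's
    delta_g; nuclei at or below the threshold map to None (no predicted net
    polarization).
    """
    species = pair.species(observed_species)  # KeyError if not in pair
    dg = pair.delta_g(observed_species)
    sdg = +1 if dg > 0 else -1
    if dg == 0.0:
        raise ValueError(
            "delta_g is exactly zero for this pair; the sign rule is undefined"
        )
    pattern: dict[str, int | None] = {}
    for nucleus, aiso in species.hyperfine.items():
        if abs(aiso) <= zero_threshold:
            pattern[nucleus] = None
        else:
            pattern[nucleus] = gamma(pair.mu, pair.epsilon, sdg, +1 if aiso > 0 else -1)
    return pattern


def infer_unknown(params: SignParameters, observed_gamma: int) -> int:
    """Solve the sign rule for its single unknown factor.

    Since Gamma is a product of four signs, the unknown equals Gamma times
    the product of the three known factors (each sign is its own inverse).
    """
    _check_sign(observed_gamma, "observed_gamma")
    unknown = params.unknown_fields()
    if len(unknown) != 1:
        raise ValueError(
            f"exactly one factor must be UNKNOWN for inversion, got "
            f"{len(unknown)}: {unknown}"
        )
    product = 1
    for name in ("mu", "epsilon", "sign_delta_g", "sign_aiso"):
        v = getattr(params, name)
        if v is not UNKNOWN:
            product *= v
    return observed_gamma * product


def infer_precursor(
    observations: list[ResonanceObservation],
    species: RadicalSpecies,
    sign_delta_g: int,
    epsilon: int,
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD_MHZ,
) -> tuple[int | None, bool, list[dict]]:
    """Infer the precursor multiplicity mu from an observed phase pattern.

    Each significant observation whose nucleus has an above-threshold
    coupling in the precursor radical yields one mu via inversion of the
    sign rule; the result is the consensus.

    Returns ``(mu, consistent, report)`` where ``report`` holds one dict per
    usable nucleus (nucleus, Aiso, observed Gamma, inferred mu).  When the
    per-nucleus inferences disagree, ``consistent`` is False and ``mu`` is
    None (no consensus is claimed).
    """
    _check_sign(sign_delta_g, "sign_delta_g")
    _check_sign(epsilon, "epsilon")
    report: list[dict] = []
    for obs in observations:
        if not obs.significant or obs.rel_intensity == 0.0:
            continue
        if obs.nucleus not in species.hyperfine:
            raise KeyError(
                f"observed nucleus {obs.nucleus!r} absent from hyperfine table "
                f"of {species.name!r}"
            )
        aiso = species.hyperfine[obs.nucleus]
        if abs(aiso) <= zero_threshold:
            continue
        observed_gamma = +1 if obs.rel_intensity > 0 else -1
        mu = infer_unknown(
            SignParameters(
                mu=UNKNOWN,
                epsilon=epsilon,
                sign_delta_g=sign_delta_g,
                sign_aiso=+1 if aiso > 0 else -1,
            ),
            observed_gamma,
        )
        report.append(
            {
                "nucleus": obs.nucleus,
                "aiso_mhz": aiso,
                "gamma_observed": observed_gamma,
                "mu": mu,
            }
        )
    if not report:
        raise ValueError(
            "no usable observation: need at least one significant resonance "
            "with an above-threshold hyperfine coupling"
        )
    mus = {entry["mu"] for entry in report}
    consistent = len(mus) == 1
    return (report[0]["mu"] if consistent else None), consistent, report
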