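"""Domain model for radical species, radical pairs and CIDNP observations.

Photo-CIDNP experiments on 6,7,8-trimethyllumazine (TML) involve transient
radical pairs formed by light-induced electron transfer.  Each radical is
characterised by an isotropic electron g factor and a table of isotropic
hyperfine coupling constants (Aiso, in MHz) between the unpaired electron
and the observable methyl protons.  The diamagnetic recombination products
(TML- and TMLH) inherit nuclear hyperpolarization from these radicals, seen
as enhanced absorptive (+) or emissive (-) NMR lines.

This module defines the value types shared by the whole package and ships a
fixture reproducing the published DFT g/hyperfine data and the observed
signed relative CIDNP integrals for the TML disproportionation system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "HyperfineTable",
    "RadicalSpecies",
    "RadicalPairScenario",
    "ResonanceObservation",
    "MixtureSolution",
    "canonical_nucleus",
    "relative_couplings",
    "load_tml_fixture",
    "TML_OX",
    "TML_RED_ANION",
    "TML_RED_H5",
    "TML_RED_H1",
    "PRODUCT_OF_OXIDIZED",
    "PRODUCT_OF_REDUCED",
]

#: Greek-letter and spelled-out variants accepted for nucleus labels.
#: Stored labels are plain ASCII for file-format portability.
_NUCLEUS_ALIASES = {
    "H(6α)": "H(6a)",
    "H(8α)": "H(8a)",
    "H(7α)": "H(7a)",
    "H(6alpha)": "H(6a)",
    "H(8alpha)": "H(8a)",
    "H(7alpha)": "H(7a)",
}

# Canonical species names of the TML fixture.
TML_OX = "TMLox"
TML_RED_ANION = "TMLHred"
TML_RED_H5 = "TMLH2red(H5)"
TML_RED_H1 = "TMLH2red(H1)"

#: Diamagnetic product observed on each side of the TML radical pair.
PRODUCT_OF_OXIDIZED = "TML-"
PRODUCT_OF_REDUCED = "TMLH"


def canonical_nucleus(label: str) -> str:
    """Map Greek-letter nucleus label variants onto the stored ASCII form."""
    label = label.strip()
    return _NUCLEUS_ALIASES.get(label, label)


@dataclass(frozen=True)
class HyperfineTable:
    """Signed isotropic hyperfine couplings, nucleus label -> Aiso in MHz."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for label, value in self.entries.items():
            key = canonical_nucleus(label)
            if not key:
                raise ValueError("empty nucleus label")
            if key in clean:
                raise ValueError(f"duplicate nucleus label {key!r}")
            v = float(value)
            if not math.isfinite(v):
                raise ValueError(f"non-finite coupling for {key!r}: {value!r}")
            clean[key] = v
        object.__setattr__(self, "entries", clean)

    def __getitem__(self, nucleus: str) -> float:
        return self.entries[canonical_nucleus(nucleus)]

    def __contains__(self, nucleus: str) -> bool:
        return canonical_nucleus(nucleus) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return list(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class RadicalSpecies:
    """One paramagnetic species: g factor, hyperfine table, redox role."""

    name: str
    g_iso: float
    hyperfine: HyperfineTable
    role: str  # "oxidized" or "reduced"
    protonation_label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if not (1.9 < self.g_iso < 2.1):
            raise ValueError(
                f"g_iso {self.g_iso} outside the plausible organic-radical "
                "range (1.9, 2.1)"
            )
        if self.role not in ("oxidized", "reduced"):
            raise ValueError(f"role must be 'oxidized' or 'reduced', got {self.role!r}")


@dataclass(frozen=True)
class RadicalPairScenario:
    """A radical pair plus the two Kaptein signs that are properties of the pair.

    mu is +1 for a triplet-born pair, -1 for singlet; epsilon is +1 when the
    observed diamagnetic product stems from recombination/re-encounter, -1 for
    escape products.  The g-factor difference entering Kaptein's rule is
    directional: for the observed side it is g(own radical) - g(counter
    radical), so it flips sign between the two sides of the pair.
    """

    ox: RadicalSpecies
    red: RadicalSpecies
    mu: int = +1
    epsilon: int = +1

    def __post_init__(self) -> None:
        if self.ox.role != "oxidized":
            raise ValueError(f"ox species {self.ox.name!r} has role {self.ox.role!r}")
        if self.red.role != "reduced":
            raise ValueError(f"red species {self.red.name!r} has role {self.red.role!r}")
        if self.mu not in (+1, -1) or self.epsilon not in (+1, -1):
            raise ValueError("mu and epsilon must be +1 or -1")
        if self.ox.name == self.red.name:
            raise ValueError("the two radicals of a pair must have distinct names")

    def species(self, name: str) -> RadicalSpecies:
        if name == self.ox.name:
            return self.ox
        if name == self.red.name:
            return self.red
        raise KeyError(f"species {name!r} is not part of this radical pair")

    def delta_g(self, observed: str) -> float:
        """g(observed radical) - g(counter radical); antisymmetric in sides."""
        own = self.species(observed)
        counter = self.red if own is self.ox else self.ox
        return own.g_iso - counter.g_iso


@dataclass(frozen=True)
class ResonanceObservation:
    """One observed NMR resonance: product species, nucleus, shift, intensity.

    ``rel_intensity`` is the signed relative integral (absorptive +, emissive
    -) after normalization to the strongest line, so |rel_intensity| <= 1.
    ``significant=False`` marks a resonance showing no hyperpolarization
    above the noise; its intensity is then treated as exactly 0.
    """

    species_name: str
    nucleus: str
    shift: float  # ppm; NaN when unassigned (e.g. purely synthetic)
    rel_intensity: float
    significant: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleus", canonical_nucleus(self.nucleus))
        if abs(self.rel_intensity) > 1.0 + 1e-12:
            raise ValueError(
                f"|rel_intensity| must be <= 1 after normalization, got "
                f"{self.rel_intensity}"
            )
        if not self.significant and self.rel_intensity != 0.0:
            object.__setattr__(self, "rel_intensity", 0.0)

    @property
    def effective_intensity(self) -> float:
        return self.rel_intensity if self.significant else 0.0


@dataclass(frozen=True)
class MixtureSolution:
    """Fractions of coexisting protonation states plus the mixed couplings."""

    fractions: dict[str, float]
    mixed: HyperfineTable
    constraint_nucleus: str | None
    residual: float  # MHz, coupling-equivalent rms misfit
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        for name, frac in self.fractions.items():
            if not (-1e-12 <= frac <= 1.0 + 1e-12):
                raise ValueError(f"fraction for {name!r} outside [0, 1]: {frac}")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def relative_couplings(
    species: RadicalSpecies, anchor_nucleus: str, anchor_value: float
) -> HyperfineTable:
    """Rescale a hyperfine table so that one anchor nucleus takes a set value.

    Every coupling is multiplied by ``anchor_value / Aiso(anchor_nucleus)``,
    preserving all signs and ratios.  This is the convention behind relative
    coupling rows in published tables, where DFT couplings are rescaled onto
    the normalized CIDNP intensity of a reference resonance.
    """
    anchor_nucleus = canonical_nucleus(anchor_nucleus)
    if anchor_nucleus not in species.hyperfine:
        raise KeyError(f"anchor nucleus {anchor_nucleus!r} not in table")
    anchor = species.hyperfine[anchor_nucleus]
    if anchor == 0.0:
        raise ZeroDivisionError(
            f"anchor nucleus {anchor_nucleus!r} has zero coupling; relative "
            "normalization undefined"
        )
    scale = anchor_value / anchor
    return HyperfineTable({n: a * scale for n, a in species.hyperfine.items()})


def _fixture_species() -> list[RadicalSpecies]:
    # Published DFT values at printed precision; no extra digits invented.
    return [
        RadicalSpecies(
            name=TML_RED_ANION,
            g_iso=2.0034,
            hyperfine=HyperfineTable({"H(6a)": -5.31, "H(8a)": +15.21}),
            role="reduced",
            protonation_label="anion",
        ),
        RadicalSpecies(
            name=TML_RED_H5,
            g_iso=2.0033,
            hyperfine=HyperfineTable({"H(6a)": +1.57, "H(8a)": +18.90}),
            role="reduced",
            protonation_label="N(5)-protonated",
        ),
        RadicalSpecies(
            name=TML_RED_H1,
            g_iso=2.0034,
            hyperfine=HyperfineTable({"H(6a)": -5.38, "H(8a)": +14.41}),
            role="reduced",
            protonation_label="N(1)-protonated",
        ),
        RadicalSpecies(
            name=TML_OX,
            g_iso=2.0031,
            hyperfine=HyperfineTable({"H(6a)": +14.93, "H(8a)": +6.42}),
            role="oxidized",
            protonation_label="neutral",
        ),
    ]


def _fixture_observations() -> list[ResonanceObservation]:
    # Signed relative integrals of the photo-CIDNP spectrum, normalized to
    # the strongest line (the emissive TML- H(6a) resonance).  The TMLH
    # H(6a) resonance shows no significant hyperpolarization.
    return [
        ResonanceObservation(PRODUCT_OF_OXIDIZED, "H(6a)", 2.06, -1.0),
        ResonanceObservation(PRODUCT_OF_OXIDIZED, "H(8a)", 3.09, -0.439),
        ResonanceObservation(PRODUCT_OF_REDUCED, "H(8a)", 3.91, +0.473),
        ResonanceObservation(PRODUCT_OF_REDUCED, "H(6a)", 2.52, 0.0, significant=False),
    ]


def load_tml_fixture() -> tuple[list[RadicalSpecies], list[ResonanceObservation]]:
    """Return the packaged TML radicals and observed CIDNP peak list.

    Species: the four 6,7,8-trimethyllumazine radicals (one-electron
    oxidized neutral radical, reduced anion, and its two neutral protonated
    variants) with DFT g factors and methyl-proton hyperfine couplings.
    Observations: the four methyl resonances of the diamagnetic products
    TML- and TMLH with signed relative integrals.

    The three reduced variants share one observation set (keyed to the
    product "TMLH"): they are alternative hypotheses for the same observed
    spectrum, not independently measured species.
    """
    return _fixture_species(), _fixture_observations()


def species_by_name(species: list[RadicalSpecies]) -> dict[str, RadicalSpecies]:
    out: dict[str, RadicalSpecies] = {}
    for sp in species:
        if sp.name in out:
            raise ValueError(f"duplicate species name {sp.name!r}")
        out[sp.name] = sp
    return out


def with_flipped_coupling(species: RadicalSpecies, nucleus: str) -> RadicalSpecies:
    """Copy of a species with one coupling's sign inverted (testing helper)."""
    nucleus = canonical_nucleus(nucleus)
    entries = dict(species.hyperfine.entries)
    entries[nucleus] = -entries[nucleus]
    return replace(species, hyperfine=HyperfineTable(entries))
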