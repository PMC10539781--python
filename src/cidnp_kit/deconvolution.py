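"""Deconvolution of coexisting radical protonation states.

When a radical exists as a fast equilibrium of protonation states, the
CIDNP pattern transferred to the diamagnetic product reflects a population-
weighted average of the states' hyperfine couplings.  This module resolves
the state fractions, either exactly from a single linear constraint (for
two states, e.g. forcing the mixed coupling of a visibly unpolarized
nucleus to zero) or by joint least squares over the simplex of fractions
and the proportionality slope.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .correlation import fit_through_origin
from .species import (
    HyperfineTable,
    MixtureSolution,
    RadicalSpecies,
    ResonanceObservation,
    canonical_nucleus,
)

__all__ = [
    "InfeasibleConstraintError",
    "solve_two_species",
    "mix_tables",
    "fit_mixture",
]


class InfeasibleConstraintError(ValueError):
    """No admissible fraction satisfies the constraint; carries the nearest one."""

    def __init__(self, message: str, nearest_fraction: float):
        super().__init__(message)
        self.nearest_fraction = nearest_fraction


def solve_two_species(a1: float, a2: float, target: float) -> float:
    """Fraction p of species 1 with p*a1 + (1-p)*a2 = target.

    Closed form: p = (target - a2) / (a1 - a2).  The target must lie between
    a1 and a2 (inclusive) for p to be a valid fraction; otherwise an
    :class:`InfeasibleConstraintError` carrying the nearest admissible
    fraction (0 or 1) is raised.
    """
    if a1 == a2:
        raise ValueError(
            "the two couplings are identical; any fraction reproduces the "
            "target (degenerate) or none does"
        )
    p = (target - a2) / (a1 - a2)
    if not (0.0 <= p <= 1.0):
        nearest = min(1.0, max(0.0, p))
        raise InfeasibleConstraintError(
            f"target {target} lies outside [{min(a1, a2)}, {max(a1, a2)}]; "
            f"nearest admissible fraction is {nearest}",
            nearest_fraction=nearest,
        )
    return p


def mix_tables(
    fractions: dict[str, float], species: list[RadicalSpecies]
) -> HyperfineTable:
    """Convex combination of hyperfine tables, nucleus by nucleus."""
    by_name = {sp.name: sp for sp in species}
    missing = set(fractions) - set(by_name)
    if missing:
        raise KeyError(f"fractions refer to unknown species: {sorted(missing)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {total}, expected 1 within 1e-9")
    if any(f < -1e-12 for f in fractions.values()):
        raise ValueError("fractions must be nonnegative")

    labels = None
    for name in fractions:
        sp_labels = set(by_name[name].hyperfine.labels())
        if labels is None:
            labels = sp_labels
        elif sp_labels != labels:
            raise ValueError(
                f"species {name!r} has nucleus labels {sorted(sp_labels)} "
                f"!= {sorted(labels)}; tables must share labels to be mixed"
            )
    assert labels is not None
    mixed = {
        nucleus: sum(f * by_name[name].hyperfine[nucleus] for name, f in fractions.items())
        for nucleus in sorted(labels)
    }
    return HyperfineTable(mixed)


def _adjusted_points(observations, sign_delta_g):
    """(nucleus, adjusted intensity) with non-significant entries as zeros."""
    if sign_delta_g not in (+1, -1):
        raise ValueError("sign_delta_g must be +1 or -1")
    return [(obs.nucleus, sign_delta_g * obs.effective_intensity) for obs in observations]


def _profile_residual(fracs, tables, y):
    """SSE over intensity residuals with the slope profiled out."""
    m = tables.T @ fracs
    smm = float(m @ m)
    if smm == 0.0:
        return float(y @ y), 0.0, m
    slope = float(m @ y) / smm
    r = y - slope * m
    return float(r @ r), slope, m


def fit_mixture(
    observations: list[ResonanceObservation],
    candidates: list[RadicalSpecies],
    sign_delta_g: int,
    constraint: tuple[str, float] | None = None,
) -> MixtureSolution:
    """Resolve state fractions explaining an observed polarization pattern.

    With exactly two candidates and a ``(nucleus, target)`` constraint the
    fraction follows exactly from :func:`solve_two_species`; the quality of
    the resulting mixture is then reported as the through-origin fit of the
    adjusted intensities against the mixed couplings.  Without a constraint
    (any number of candidates >= 2) the fractions and slope are fit jointly
    by least squares over the probability simplex.

    The returned :class:`MixtureSolution` carries the fractions, the mixed
    table, a coupling-equivalent rms residual in MHz (sqrt(SSE)/|slope|),
    a degeneracy flag, and sensitivity diagnostics dp/dAiso for the exact
    two-species path.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate species")
    names = [sp.name for sp in candidates]
    if len(set(names)) != len(names):
        raise ValueError("candidate species names must be unique")

    pts = _adjusted_points(observations, sign_delta_g)
    nuclei = [n for n, _ in pts]
    if len(set(nuclei)) != len(nuclei):
        raise ValueError("duplicate nucleus in observations")
    y = np.array([v for _, v in pts])
    for sp in candidates:
        for n in nuclei:
            if n not in sp.hyperfine:
                raise KeyError(f"nucleus {n!r} missing from table of {sp.name!r}")
    tables = np.array([[sp.hyperfine[n] for n in nuclei] for sp in candidates])

    # Identical candidate tables: any fraction works; flag and split evenly.
    if all(
        np.allclose(tables[0], tables[k], rtol=0, atol=1e-12)
        for k in range(1, len(candidates))
    ):
        frac = 1.0 / len(candidates)
        fractions = {name: frac for name in names}
        mixed = mix_tables(fractions, candidates)
        fit = fit_through_origin([(mixed[n], v) for n, v in pts])
        resid = _rms_residual_mhz(fit)
        return MixtureSolution(
            fractions=fractions,
            mixed=mixed,
            constraint_nucleus=constraint[0] if constraint else None,
            residual=resid,
            degenerate=True,
            diagnostics={"fit": fit, "note": "identical candidate tables"},
        )

    if constraint is not None:
        c_nucleus, target = canonical_nucleus(constraint[0]), float(constraint[1])
        if len(candidates) != 2:
            raise NotImplementedError(
                "the exact constraint path is defined for two candidates; "
                "use constraint=None for a joint fit over more states"
            )
        a1 = candidates[0].hyperfine[c_nucleus]
        a2 = candidates[1].hyperfine[c_nucleus]
        p = solve_two_species(a1, a2, target)
        fractions = {names[0]: p, names[1]: 1.0 - p}
        mixed = mix_tables(fractions, candidates)
        fit = fit_through_origin([(mixed[n], v) for n, v in pts])
        dp = 1.0 / (a1 - a2)
        diagnostics = {
            "fit": fit,
            # sensitivity of the fraction to the constraining couplings
            "dp_dA1": -p * dp,
            "dp_dA2": (p - 1.0) * dp,
            "dp_dtarget": dp,
        }
        return MixtureSolution(
            fractions=fractions,
            mixed=mixed,
            constraint_nucleus=c_nucleus,
            residual=_rms_residual_mhz(fit),
            diagnostics=diagnostics,
        )

    # Joint fit over fractions and slope.  With u_k = slope * f_k the model
    # y_i = slope * sum_k f_k * a_ki is linear in u, so ordinary least
    # squares gives the unconstrained optimum exactly; fractions follow as
    # u / sum(u) and the slope as sum(u).  The solution respects the
    # simplex exactly when all u_k share one sign; otherwise fall back to
    # SLSQP on the simplex with the slope profiled out.
    K = len(candidates)
    u, *_ = np.linalg.lstsq(tables.T, y, rcond=None)
    total = float(u.sum())
    if total != 0.0 and (np.all(u * np.sign(total) >= -1e-12 * abs(total))):
        fracs = np.clip(u / total, 0.0, None)
        fracs = fracs / fracs.sum()
    else:
        cons = [{"type": "eq", "fun": lambda f: np.sum(f) - 1.0}]
        bounds = [(0.0, 1.0)] * K
        best = None
        # deterministic multi-start: uniform center plus each vertex-leaning point
        starts = [np.full(K, 1.0 / K)]
        for k in range(K):
            s = np.full(K, 0.1 / max(K - 1, 1))
            s[k] = 0.9
            starts.append(s)
        for s in starts:
            r = minimize(
                lambda f: _profile_residual(f, tables, y)[0],
                s,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"ftol": 1e-16, "maxiter": 500},
            )
            if best is None or r.fun < best.fun:
                best = r
        fracs = np.clip(best.x, 0.0, None)
        fracs = fracs / fracs.sum()

    fractions = {name: float(f) for name, f in zip(names, fracs)}
    mixed = mix_tables(fractions, candidates)
    fit = fit_through_origin([(mixed[n], v) for n, v in pts])
    return MixtureSolution(
        fractions=fractions,
        mixed=mixed,
        constraint_nucleus=None,
        residual=_rms_residual_mhz(fit),
        diagnostics={"fit": fit},
    )


def _rms_residual_mhz(fit) -> float:
    """Coupling-equivalent rms misfit: sqrt(SSE)/|slope| in MHz."""
    sse = float(np.sum(np.asarray(fit.residuals) ** 2))
    if sse == 0.0:
        return 0.0
    if fit.slope == 0.0:
        return float("inf")
    return float(np.sqrt(sse / len(fit.residuals)) / abs(fit.slope))
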