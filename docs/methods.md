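# Methods

This note documents the models, conventions and numerical choices behind
`cidnp-kit`, and what the synthetic-data tests do and do not demonstrate.

## Physical model and assumptions

The package analyses *net* photo-CIDNP polarization of weakly coupled ¹H
nuclei in the high-field limit. Two assumptions are made throughout:

1. **Kaptein's net-effect rule** gives the phase of each polarized
   resonance, Γᵢ = μ·ε·sgn(Δg)·sgn(A_iso,i). Multiplet (E/A) effects,
   low-field mixing and polarization transfer during relaxation are not
   modelled.
2. **Intensity ∝ A_iso.** The signed relative integral of each resonance
   in the diamagnetic product is taken proportional to the isotropic
   hyperfine coupling of the same nucleus in its paramagnetic precursor.
   This holds for short pump–probe delays and weak couplings; the
   proportionality constant (the correlation slope) is an empirical
   per-data-set quantity, not predicted here.

Signs are represented as literal integers ±1 and combined by
multiplication, so the code evaluates the rule exactly as written;
booleans are rejected.

### Δg direction convention

Δg is directional: **g(observed radical) − g(counter radical)**, so it
flips sign between the two sides of one radical pair
(`RadicalPairScenario.delta_g`). Intensities are multiplied by sgn(Δg) of
their side before correlation, folding both sides onto one positive-slope
line. ε is an *input*: for spectra acquired within ~100 ns of the laser
pulse, recombination products dominate and ε = +1; the package does not
model escape kinetics.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `zero_threshold` | 0.5 | MHz | couplings at or below this produce no predicted net polarization; operationalizes "no significant hyperpolarization" for near-zero mixed couplings |
| normalization | max-abs | — | integrals divided by the largest absolute integral of the spectrum; exactly one entry has magnitude 1 |
| R² convention | centered | — | R² = 1 − SSE/Σ(y−ȳ)²; chosen because it reproduces the reference values computed from the packaged data, which the uncentered convention does not (verified numerically in the test suite) |
| `fwhm` | 0.01 | ppm | Lorentzian full width at half maximum of simulated lines, typical of small molecules in solution |
| integration window | ±0.025 | ppm | ±5 HWHM; captures ~87 % of a Lorentzian line uniformly across peaks (cancels under normalization) while keeping accumulated noise and neighbor-tail overlap small |

Zero-intensity ("not significant") observations are retained as exact
(A_iso, 0) data points by default: an unpolarized line is evidence, and
dropping it would inflate apparent correlation quality. A flag exists to
exclude them.

## Through-origin regression

slope = Σxᵢyᵢ / Σxᵢ², the exact least-squares minimizer of Σ(y − mx)².
Residuals are y − ŷ. Degenerate inputs (all x = 0, fewer than two points)
raise. When all y are equal the centered R² is undefined; it is reported
as 1.0 for a perfect fit and NaN otherwise. The slope formula is verified
against a derivative-free numeric minimization oracle in the tests.

## Mixture deconvolution

For coexisting protonation states in fast equilibrium the product
polarization reflects a population-weighted hyperfine table,
A_mix = Σₖ fₖ A⁽ᵏ⁾ (convex combination, per nucleus).

- **Two states + one linear constraint** (the default analysis): the
  fraction follows exactly from p = (target − a₂)/(a₁ − a₂); no
  optimization, so reported numbers are deterministic. Infeasible targets
  raise an error carrying the nearest admissible fraction. Sensitivities
  dp/da₁, dp/da₂, dp/dtarget are reported, because fractions inherit the
  (potentially substantial) uncertainty of the DFT couplings they are fit
  to and should be read with that caution.
- **Joint fit (no constraint, any K ≥ 2):** the model
  yᵢ = s·Σₖ fₖ aₖᵢ is bilinear in (s, f), but substituting uₖ = s·fₖ makes
  it ordinary linear least squares; fractions are uₖ/Σu and the slope Σu.
  When the unconstrained solution leaves the simplex, SLSQP with the slope
  profiled out and deterministic multi-starts takes over.
- The residual reported with a `MixtureSolution` is the coupling-equivalent
  rms misfit √(SSE/n)/|slope| in MHz.
- With two observations and a zero constraint, the post-mixture fit has
  R² = 1 *by construction* (one point is pinned to the origin, one free
  point remains); reports flag this as non-evidential.

A joint two-nucleus fit without the hard zero constraint is available via
`fit_mixture(..., constraint=None)` but is not the default: the
zero-constraint path states the mechanistic hypothesis (no H(6α)
polarization ⇒ vanishing mixed coupling) explicitly.

## Synthetic spectra and the recovery study

`spectrum.render_spectrum` emulates only what this analysis consumes:
sparse singlets with Lorentzian lineshape (area-parameterized), signed
areas with Kaptein phases and |area| ∝ A_iso, and additive iid Gaussian
noise. It does **not** emulate J-multiplets (the packaged system's
observable methyl protons are singlets; exchangeable protons are invisible
in D₂O), baseline/phase artifacts, t₁ noise, or field/wavelength
dependence. Passing recovery tests therefore demonstrate the correctness
and noise robustness of the *analysis chain*, not instrument realism.

The randomized recovery suite (`generate_recovery_suite`) draws, per
scenario: g values in [2.0020, 2.0045] with |Δg| ≥ 2×10⁻⁴; 2–4 nuclei per
side with |A_iso| in [1, 20] MHz and random signs (the 1 MHz floor keeps
every nucleus above `zero_threshold`, so truths are well defined); random
precursor multiplicity; with probability ½ a two-state mixture on the
reduced side with fraction in [0.1, 0.9]; peak positions on a 0–10 ppm
axis separated by ≥ 0.4 ppm; a 20 000-point grid; noise σ = 1 % of the
maximum noiseless amplitude. One shared proportionality constant generates
both sides; after global max-abs normalization the recoverable slope is
μ·ε·s/max|area| (the sign rides on μ·ε), which is the recorded truth. All
randomness flows through one explicit seed; scenario generation is
byte-reproducible.

Pipeline (integrate → normalize → sign-adjust → correlate → deconvolve)
accuracy at these conditions: the acceptance test requires slopes within
2 % and fractions within ±0.02 in ≥ 95 of 100 scenarios; measured rates
are 95–100 per 100 across seeds. The residual error budget is integration
noise (∝ √window width), ~0.1 % neighbor-tail contamination, and grid
discretization; the finite-window capture factor cancels exactly under
normalization because all lines share one width.

Problem sizes throughout (100 scenarios, 2×10⁴-point grids, ≤ 8 peaks per
spectrum) keep the whole suite and the acceptance script in the seconds
range on a single CPU while leaving the noise statistics well sampled.

## Numerical details and edge cases

- Nucleus labels are stored as plain ASCII (`H(6a)`); Greek-letter
  variants (`H(6α)`, `H(6alpha)`) are accepted via a fixed alias map.
- g values and couplings of the packaged data are stored at their printed
  precision; no digits are invented. Derived quantities (slopes, R²,
  fractions) carry full floating-point precision internally and are
  rounded only for display (slopes/R² to 4 decimals, fractions to 3).
- `normalize_intensities` raises on all-zero input;
  `relative_couplings` raises on a zero anchor coupling.
- Windowed integration uses the trapezoidal rule on the grid points inside
  the window; windows must lie within the axis and contain ≥ 2 points.
- Exit codes of the CLI: 0 success, 2 input error, 3 inconsistent sign
  inference (per-nucleus μ values disagree), so pipelines can detect a
  sign-rule contradiction mechanically.

## Known limitations

- Net effect only; no quantitative spin dynamics, no time resolution, no
  field dependence — the slope of a correlation is descriptive, and
  differences between slopes of the two sides (relaxation, additional
  couplings, exchange) are outside the model.
- Mixture fractions are conditional on the supplied hyperfine tables;
  errors in those tables propagate linearly (see the reported
  sensitivities) and no uncertainty intervals are attached.
- The protonation-state deconvolution assumes fast exchange relative to
  the polarization transfer, i.e. a single averaged table; slow-exchange
  two-component spectra would need per-state peak lists instead.
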