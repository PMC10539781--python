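# cidnp-kit

Analysis toolkit for **photo-CIDNP** (photo-chemically induced dynamic
nuclear polarization) NMR of radical-pair chemistry, built around the
light-induced disproportionation of 6,7,8-trimethyllumazine (TML), a
precursor of the flavin cofactor family.

A photo-excited molecule that undergoes electron transfer creates a
transient radical pair; nuclear-electron hyperfine coupling inside that
pair sorts nuclear spins between the recombination and escape channels, so
the diamagnetic products show strongly enhanced absorptive (+) or emissive
(−) NMR lines. Two classic results let one read mechanism out of those
phases and intensities:

- **Kaptein's net-polarization sign rule.** For nucleus *i* in a geminate
  product,

  Γᵢ = μ · ε · sgn(Δg) · sgn(A_iso,i),

  where μ = ±1 is the precursor multiplicity (+ triplet, − singlet),
  ε = ±1 the exit channel (+ recombination, − escape),
  Δg = g(observed radical) − g(counter radical), and A_iso,i the isotropic
  hyperfine coupling (MHz) of the nucleus in the observed radical.
  Γ = +1 means enhanced absorption, −1 emission. Knowing three factors and
  the observed phase determines the fourth — this is how an emissive
  pattern pins down a triplet precursor.

- **High-field intensity rule.** Net CIDNP intensity is proportional to
  A_iso, so a through-origin regression of signed relative intensities
  against DFT-computed couplings (slope m = Σxy/Σx², centered R²) tests a
  candidate radical assignment, and a convex mixture of protonation-state
  hyperfine tables can be deconvolved from the same data — e.g. by forcing
  the mixed coupling of a visibly unpolarized nucleus to zero.

The package provides, as composable library modules plus a thin
`cidnp-kit` CLI:

| module | what it does |
|---|---|
| `cidnp_kit.species` | domain types + the packaged TML data set (DFT g/A_iso tables, observed signed integrals) |
| `cidnp_kit.kaptein` | forward sign-rule prediction and inversion (precursor inference with consistency check) |
| `cidnp_kit.correlation` | intensity normalization, Δg sign adjustment, through-origin fits |
| `cidnp_kit.deconvolution` | exact two-state and least-squares K-state mixture resolution |
| `cidnp_kit.spectrum` | synthetic Lorentzian spectra, windowed integration, randomized recovery scenarios |
| `cidnp_kit.analysis` / `cidnp_kit.cli` | end-to-end pipeline, file formats, console commands |

## Worked example

```bash
$ cidnp-kit reproduce-tml
precursor multiplicity: mu = +1 (triplet)
TMLHred: slope = 0.0277 MHz^-1, R2 = 0.7827
TMLH2red(H5): slope = 0.0249 MHz^-1, R2 = 0.9863
TMLH2red(H1): slope = 0.0288 MHz^-1, R2 = 0.7553
TMLox: slope = 0.0672 MHz^-1, R2 = 0.9996
mixture fractions: 0.772 : 0.228
mixed Aiso(H(8a)) = 18.1 MHz; slope = 0.0262 MHz^-1, R2 = 1 (non-evidential)
```

Reading the output: both methyl resonances of the TML⁻ product are
emissive; with recombination products (ε = +) and Δg < 0 on the oxidized
side, inverting the sign rule for each nucleus yields μ = +1 both times —
a triplet precursor, consistently. The oxidized radical TMLox⚫ correlates
almost perfectly with the observed intensities (slope 0.0672 MHz⁻¹,
R² = 0.9996). On the reduced side no single protonation state explains the
data as well; a 0.772 : 0.228 mixture of the N(5)-protonated neutral
radical and the anionic radical drives the mixed H(6α) coupling to zero —
exactly what the spectrum shows (no H(6α) polarization) — and gives a mixed
H(8α) coupling of 18.1 MHz. The post-mixture R² = 1 is flagged
*non-evidential*: with two points and one pinned to the origin by the
constraint, a perfect fit is guaranteed by construction.

The same steps are available individually (`correlate`, `deconvolve`,
`infer-precursor`) on your own species tables and peak lists, and
`simulate` / `integrate` handle synthetic spectra; see
`cidnp-kit --help` and the file-format notes in `cidnp_kit/io.py`.

Library use:

```python
from cidnp_kit import load_tml_fixture, correlate_species

species, observations = load_tml_fixture()
ox = next(sp for sp in species if sp.name == "TMLox")
tml_minus = [o for o in observations if o.species_name == "TML-"]
fit = correlate_species(ox, tml_minus, sign_delta_g=-1)
print(f"{fit.slope:.4f} /MHz, R2 = {fit.r_squared:.4f}")
# 0.0672 /MHz, R2 = 0.9996
```

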