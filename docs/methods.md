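# Methods

## Scope and model

chirokit automates three computational procedures used to establish the
structure and absolute configuration of chiral natural products: validation
of a proposed molecular formula against high-resolution ESI mass spectra,
enantiomer discrimination by comparison of measured and simulated
electronic circular dichroism (ECD) spectra, and R/S calls from modified
Mosher (MTPA ester) chemical-shift differences.  It deliberately consumes
the *outputs* of quantum chemistry (per-conformer relative Gibbs free
energies and TDDFT excitation energies / rotatory strengths); it performs
no electronic-structure or conformer-search calculations itself.

## Mass arithmetic

Atomic constants are an internal table of IUPAC monoisotopic masses
(C 12 exactly, H 1.00782503, N 14.00307400, O 15.99491462, F 18.99840322,
Na 22.98976928, S 31.97207100, Cl 34.96885268, P, Br, I) with isotope
abundances and standard valences; the electron mass is 0.00054858 Da.
The electron-mass correction is always applied to adduct m/z: cations lose
one electron mass, anions gain one.  Published "calcd." values are
occasionally computed without this correction; such entries differ from
ours by ~0.0005 Da and we do not force agreement with them.  m/z is kept
at full precision internally and rounded to 4 decimals only for output,
ppm errors to 1 decimal.

Isotope patterns are computed at unit (nominal-mass) resolution: each
element's isotope distribution is placed on integer M+k slots by integer
mass difference from its monoisotopic isotope (¹³C on M+1, ³⁷Cl on M+2),
raised to the atom count by repeated convolution, and the per-element
results convolved and normalized to a tallest peak of 1.  Fine structure
within a slot is merged on purpose — this is what a practitioner reads off
an ESI spectrum when judging the ~3:1 chlorine signature.  The one-chlorine
window on M+2/M is [0.24, 0.42], centred on the theoretical ≈0.32; organic
molecules without Cl/S/Br sit below 0.05.

The formula grammar is flat (no parentheses, charges or isotope labels)
because formulas of isolable small molecules are printed flat.  Formula
inference from an observed m/z is out of scope.

## Conformer weighting

Statistical weights are Boltzmann factors of the supplied relative Gibbs
free energies, gᵢ = exp(−ΔGᵢ/RT)/Σⱼ exp(−ΔGⱼ/RT), with
R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹ and a default T = 298.15 K
(configurable; Gibbs energies are conventionally quoted at standard
temperature).  ΔG values are used exactly as supplied — no electronic-energy
fallback.  Conformer selection keeps ΔG ≤ cutoff with an inclusive
boundary (default 4 kcal/mol); the ΔG = 0 reference always survives, so
renormalization is always possible.

Class-mixture reweighting addresses the case where rotamer-family
populations are imposed rather than computed (e.g. modeling a 40:60
θ1 = 0°:180° mixture): each family's conformers are Boltzmann-split within
the family and renormalized so the family total equals its stated
fraction.  With a single family this reduces exactly to plain Boltzmann
weights.  Ties in ΔG are broken by input order for reporting only.

## Band shapes, scaling and comparison

Stick spectra are broadened with Gauss-type bands on the energy axis,

    Δε(E) = 1/(2.297·10⁻³⁹ √π ζ) Σᵢ Eᵢ Rᵢ·10⁻⁴⁰ exp(−((E − Eᵢ)/ζ)²),

with ζ (eV) taken as the 1/e half-width — the standard convention in
ECD-averaging practice — and R in 10⁻⁴⁰ cgs.  The prefactor makes the
band-area identity ∫Δε/E dE = Σ Rᵢ/22.97 hold, which the tests verify by
quadrature at small ζ.  Spectra are rendered on a wavelength grid
(default 190–400 nm, 1 nm; conversion 1239.84193 eV·nm).  The empirical UV
shift Δλ (default +4 nm) is applied to the *theoretical* curve on the
wavelength axis by linear interpolation with edge-held ends; on a 1 nm
grid an integer shift is exact.

Amplitude calibration is removed by dividing the curve by the magnitude of
its positive characteristic band near 290 nm: the scaler searches ±25 nm
around the requested reference wavelength for positive local maxima
(scipy `find_peaks`) and uses the tallest; it fails loudly, reporting the
window, when none exists.  Scaling is idempotent and invariant under
multiplication by any positive constant.

Spectral agreement is quantified as cosine similarity of the two scaled
curves resampled on a common grid in a comparison window (default
λ ≥ 200 nm, where the informative bands of the compounds this emulates
lie).  Cosine is sign-sensitive: mirror-image (enantiomeric) spectra score
exactly −1.  The enantiomer call returns "as-modeled" when the modeled
curve fits at least as well as its pointwise negation, "mirror" otherwise,
and raises an undecidable error on a tie below 1e−12 — cosine against the
mirror image is just the negated similarity, so the decision reduces to
its sign.  Doubling the grid density changes the similarity by < 1e−3.

## Mosher analysis

Δδ = δ_S − δ_R per proton, exactly.  The geometric step of the MTPA model
— which substituent branch lies on which side of the ester plane — cannot
be inferred without the drawn structure, so it is delegated to the user as
side labels A/B, with the convention that side A carries negative Δδ for
an R center.  The call is a vote: each proton with |Δδ| ≥ 0.005 ppm
(below 2-decimal shift resolution counts as zero; threshold configurable)
supports R or S by its sign and side; the winning fraction is the
consistency, the call is withheld below a threshold (default 0.8 — real
assignments show fully consistent patterns) and a tie is undecidable.
Swapping the two ester columns provably mirrors the call at identical
consistency; proton order is irrelevant.

## Synthetic data

The generators emulate the study inputs that are never deposited:

* **Ensembles** — one conformer at ΔG = 0 (the hydrogen-bond-stabilized
  dominant rotamer of the emulated compounds), remaining energies
  exponential with scale 2 kcal/mol truncated at 8 kcal/mol so the
  4 kcal/mol selection boundary is exercised from both sides; 8 conformers
  with 6 transitions each by default.  Every conformer carries a
  guaranteed transition at 4.275 eV (≈290 nm) with positive rotatory
  strength |N(15, 3.75)| (10⁻⁴⁰ cgs) so the characteristic scaling band
  exists; the other transitions have energies uniform in 3.5–6.5 eV
  *outside* a ±0.5 eV guard band around the characteristic transition and
  rotatory strengths N(0, 15).  The guard band mirrors the emulated
  compounds, whose ~290 nm band keeps its sign and position across
  conformations while the shorter-wavelength region is strongly
  conformation-dependent.  Dihedral-class labels are drawn with a 60%
  θ1 = 180° fraction (the more stable family).
* **Measurements** — sign × amplitude × (the full theoretical pipeline
  output) plus additive Gaussian noise and a slow Legendre-polynomial
  baseline, both expressed as fractions of the peak |Δε| (defaults 10% and
  2%) and scaled with the amplitude so that noise-to-signal is
  calibration-independent.  Real instrument noise is neither white nor
  wavelength-independent; passing recovery tests shows robustness of the
  *decision*, not fidelity of the noise model.
* **Mosher tables** — Δδ signs follow the declared configuration with
  independent flips at a stated probability, |Δδ| uniform in
  [0.5, 1.5] × 0.08 ppm, δ_R uniform in 0.8–6.5 ppm.

All generators are pure functions of their spec including the seed.  The
Monte-Carlo enantiomer recovery alternates true signs across trials and
derives per-trial seeds from a master seed.  In rare synthetic draws the
neighboring bands leave no local extremum inside the ±25 nm scaling
window; the recovery harness then normalizes by the largest magnitude near
the reference band instead — cosine similarity is invariant to the
positive factor, so the decision is unaffected (the strict scaler still
refuses such curves when called directly).

Problem sizes in the default test run: 100 recovery trials at 10% noise on
the 211-point grid, 200 Mosher seeds at 10% sign-error probability —
chosen to put Monte-Carlo error well below the 95% thresholds they are
tested against while keeping the suite interactive.

## What passing tests do and do not show

The synthetic recovery experiments establish that the decision machinery —
scaling, comparison, sign votes — is correct and noise-robust under the
stated noise model.  They cannot validate the physics upstream of it:
whether a particular DFT level yields accurate ΔG values or rotatory
strengths is outside this package, and published ensemble data for the
motivating compounds are not available to replicate their specific
spectra.  The mass targets, in contrast, are exact desk-scale arithmetic
reproduced to print precision.

## Known limitations

* Single-charge adducts only; no elemental-composition search; no fine
  isotope structure.
* Gaussian bands with a single global ζ; no vibronic structure, no
  gauge-choice handling, no wavelength-dependent solvent shift beyond the
  single Δλ.
* The Mosher step trusts the user's A/B side assignment; it does not model
  MTPA phenyl anisotropy or predict shifts.
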