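# Methods

## Scope

`vseprobe` turns nitrile-stretch IR band parameters of a photoreceptor's
photocycle states into local electric fields at the probe. It covers four
stages — band fitting, temperature normalization, field conversion, and
noncovalent/hydrogen-bond decomposition — plus a forward simulator that
generates spectra from known ground truth. Everything upstream of the IR
observables (structure determination, molecular dynamics, QM/MM spectra and
field calculations) is out of scope; the electronic-structure results enter
only as per-variant anchor constants in a config file.

## Physical model

A cyanophenylalanine label (oCNF/pCNF, ortho-/para-cyanophenylalanine)
reports the electric field *E* projected onto its C≡N bond through two
independent observables.

**Frequency (Stark) route.** For a nitrile free of hydrogen bonds, the
stretching frequency is linear in the field:

    ν = ν₀ + |Δμ̃|·E,      ν₀ = 2234.5 cm⁻¹,  |Δμ̃| = 0.268 cm⁻¹/(MV/cm)

ν₀ is the gas-phase benzonitrile frequency; the tuning rate comes from
benzonitrile-in-solvent calibration. H-bonding shifts the frequency in the
*opposite* direction and breaks this relation, so the frequency route is
reserved for components classified as H-bond-free.

**Intensity (TDM) route.** The transition dipole moment is linear in the
field, μ = μ₀ + A·E with A < 0, and proportional to √(integral intensity).
μ₀ is label-specific (4.44 for oCNF, 7.04 for pCNF, (km·mol)^1/2), A = −0.047
(km·mol)^1/2 per MV/cm is label-independent. Crucially the TDM is insensitive
to H-bonding, so this route works for H-bonded populations. Because absolute
absorbances are not comparable across samples, the dark state Pfr acts as an
internal standard: with its ensemble TDM μ_Pfr and field E_Pfr known from
electronic-structure work,

    μ_PP = μ_Pfr·√(I_PP / I_Pfr)            (TDM of a photoproduct)
    E_PP = E_Pfr·(μ_PP − μ₀)/(μ_Pfr − μ₀)    (A cancels in the ratio)

The ratio form is deliberate: the printed per-variant anchor pairs imply
slightly variant-specific effective slopes at the envelope level, and the
ratio never needs A for total fields. A is shipped as a config default; it
was back-solved from the published substate field/TDM pairs (e.g.
(5.948 − 4.44)/(−32.09) = −0.047) and is consistent to three decimals across
both label types. `fit_tdm_field_line` re-derives (μ₀, A) from any set of
(field, TDM) samples by ordinary least squares.

**Substates.** Band components resolved within one state are coexisting
probe environments with mole fractions x_i, Σx_i = 1. Applying the internal
standard to a *component* intensity yields the scaled TDM m_i = √x_i·μ_i,
not μ_i. The solver closes the system case by case:

* one H-bond-free plus one H-bonded component: the free component's field
  follows from its frequency, so x₁ = (m₁/μ₁)²; closure gives x₂ = 1 − x₁,
  μ₂ = m₂/√x₂, E₂ = (μ₂ − μ₀)/A;
* a single component: x = 1; field from frequency if free, from the TDM if
  H-bonded;
* two H-bonded components: a one-parameter family (no frequency reference).
  The solver samples the family on an x-grid and, by default, reports the
  member minimizing |E_sum − E_tot|; a caller-pinned mole fraction overrides
  this. Near-degenerate optima are flagged ambiguous. Note that for the one
  such state in the packaged data (Y165pCNF Pr) the family's best gap sits at
  x₂ = m₂²/(m₂² + m₃²) while the published choice is x₂ = 0.36 with a larger
  gap; the published solution is reproduced through the pin, which the
  packaged config sets.

Components are classed H-bonded when their RT-normalized frequency exceeds
2228.0 cm⁻¹. The threshold sits between the two observed frequency classes
(≤ 2227.1 vs ≥ 2229.0 cm⁻¹) and at the benzonitrile zero-water point; the
boundary itself counts as non-H-bonded. It is a per-run config value.

**Consistency metric.** Per state, E_sum = Σx_i·E_i (component route) is an
estimate independent of E_tot (envelope route; for Pfr the anchor itself).
Their gap, 100·|E_sum − E_tot|/|E_tot|, is reported per state, and the
root-mean-square over all variant/state rows is the method's overall
internal-consistency figure (≈ 27% on the packaged data). Dark states use
the anchor verbatim — the envelope relation is never self-applied to Pfr.

**Noncovalent/H-bond split.** For an H-bonded component the frequency shift
mixes two sensitivities, Δν = |Δμ̃|·E_non + k·E_HB with k = −0.2 cm⁻¹/(MV/cm)
(the benzonitrile/water slope of −0.317 rescaled to the calibration's field
definitions; the original slope is carried as a provenance constant only).
With E_non + E_HB = E_i this is a 2×2 linear system solved exactly:

    E_non = (Δν − k·E_i)/(|Δμ̃| − k),   E_HB = E_i − E_non

H-bond-free components are never decomposed; their whole field counts as
noncovalent in the state totals E_tot,non = x₁E₁ + Σx_i·E_non,i and
E_tot,HB = Σx_i·E_HB,i (H-bonded i), computed with unrounded mole fractions.
|E_tot,HB| maps onto a conventional strength scale: very weak < 15 ≤ weak
< 30 ≤ medium < 45 ≤ strong < 60 ≤ very strong (MV/cm), lower-inclusive
because the published class edges do not resolve boundary membership.

## Band fitting

Spectra are cropped to the nitrile window (default 2210–2250 cm⁻¹) and
baseline-corrected by a degree-0–2 polynomial fitted to band-free flanks
(user intervals or the outer 15% of the window). The envelope is then fitted
as a sum of 1–3 Gaussians (nonlinear least squares via lmfit); areas come
analytically from amplitude × FWHM × √(π/4ln2). Model order is chosen by
BIC with a conservative ΔBIC ≥ 10 acceptance rule, except that a model whose
residual is already at numerical precision is treated as exact (BIC is
meaningless below the noise floor). Initial centers come from peak picking
plus greedy peak stripping of a lightly smoothed envelope, with a
deterministic restart schedule (seeded jitter plus symmetric splits of the
dominant peak for doublets). FWHM is bounded to 3–25 cm⁻¹, the realistic
range for protein nitrile bands.

When the spectrum was flank-corrected, the mixture fit refits a small linear
residual baseline jointly with the Gaussians, bounded to 5% of the peak
absorbance. Flank-only correction systematically subtracts whatever band
tail reaches the flanks (a ~1% area bias for 7 cm⁻¹-wide bands 15 cm⁻¹ from
the window edge); the bounded joint term absorbs exactly that without being
able to impersonate a band.

## Temperature normalization

Intermediates are cryo-trapped, so photoproduct (PP) observables measured at
a trapping temperature T are referred to Pfr at 300 K, assuming Pfr's
temperature dependence transfers to the photoproducts:

* intensities: I(PP, RT) = I(PP, T)·I(Pfr, RT)/I(Pfr, T), with the scale
  factor taken from the Pfr *envelopes* so that the component/envelope
  closure Σ I_i = I_tot survives normalization exactly;
* frequencies: ν(PP, RT) = ν(Pfr, RT) − (ν(Pfr, T) − ν(PP, T)), per
  conjugate component.

Conjugate components are matched across states by ascending-frequency rank
(the low/high band keeps its identity through the photocycle), not by
nearest distance. If the photoproduct resolves fewer components than Pfr
(a single symmetric band), the state falls back to envelope-level
normalization against the Pfr intensity sum and centroid frequency, and is
flagged single-component.

## Synthetic data

The generator composes the same relations forward: a substate with split
(e_non, e_hb) and weight x produces a Gaussian band at
ν₀ + |Δμ̃|·e_non + k·e_hb + thermal_shift with area
x·(μ₀ + A·(e_non + e_hb))²·scale·temperature_factor, and states sum their
bands over a configurable grid with a polynomial baseline and seeded i.i.d.
Gaussian noise on absorbance. Anchors implied by the RT dark-state truth
(μ_Pfr, I_Pfr, E_Pfr = Σx·E) are written to the dataset manifest. Because
truths live strictly in-model, the full pipeline is an exact inverse at zero
noise; the test suite asserts recovery of every mole fraction and field to
1e-6 on a three-state photocycle. Default band FWHM is 7 cm⁻¹, chosen so
published doublet geometries appear as resolvable but overlapping pairs.

What the generator does *not* emulate: non-Gaussian band shapes, detector
drift, correlated baselines, temperature-dependent widths, and any breakdown
of the linear frequency/TDM relations themselves. Passing round-trip tests
therefore bound algorithmic error, not the physical adequacy of the model on
real spectra.

The Monte-Carlo recovery tests use truths patterned on the published
F192pCNF band layout (doublet separation 5.6 cm⁻¹, weights 0.24/0.76 to
0.40/0.60). Substantially more overlapped geometries (separation ≲ 4 cm⁻¹ at
FWHM 7 with a 1:5 area ratio) are close to non-identifiable at the 1% noise
level — distinct two-Gaussian solutions reach the noise floor — which is a
property of the deconvolution problem, not of this implementation. Recovery
error of band areas scales essentially linearly with the noise level
(measured exponent ≈ 1.0 over noise fractions 0.001–0.02); the regression
test asserts monotone, at-most-linear growth.

## Packaged data and published-table regression

The package ships the published normalized band-fit table for the four Agp2
variants (Y165oCNF, F192oCNF, Y165pCNF, F192pCNF; states Pfr, Lumi-F,
Meta-F, Pr), the per-variant anchors, and the default calibration. Two known
typographical issues in the source table are resolved in the fixture: the
Y165pCNF Lumi-F component TDM is stored as 14.618 (the value consistent with
the intensity relation and the envelope row, vs a printed 14.168) and a
decimal-comma slip in the F192pCNF Lumi-F envelope TDM is stored as 8.319.

`reproduce_paper()` re-runs the pipeline on the fixture and diffs every cell
against the embedded expected tables. Two input routes exist: the published
intensities are printed with fewer significant digits than the TDMs derived
from them, so the *exact-input* route reconstructs unrounded intensities
from the published TDMs (I = I_Pfr·(μ/μ_Pfr)²) and lands within ~0.1% of
every published field; starting from the rounded printed intensities agrees
within ~0.5–1.5% and shifts the per-state consistency percentages by up to
~0.6 points. Default comparison tolerances: 1% relative on field/TDM cells,
±0.01 absolute on mole fractions, ±0.15 percentage points on the
consistency column.

## Numerical conventions

* Fields are signed projections onto the C≡N bond (all packaged values are
  negative); no absolute values are taken anywhere except in the consistency
  percentage and the strength-class magnitude.
* All chained quantities use unrounded intermediates; rounding (fields and
  mole fractions to 2 decimals, TDMs to 3) happens only in report writers.
* Mole-fraction closure is enforced to 1e-9 within the solver; component
  intensities must sum to the envelope within 1% upstream.
* Degenerate inputs raise typed errors: non-positive intensities, a Pfr TDM
  equal to μ₀ (degenerate internal standard), mole fractions outside (0, 1),
  non-positive TDMs from the calibration line.

## Known limitations

* Gaussian band shapes by construction; no Voigt or Fourier
  self-deconvolution alternatives.
* The H-bond sensitivity k is a single scalar; σ- vs π-type H-bond mixtures
  are not distinguished.
* The temperature-transfer assumption (Pfr dependencies apply to
  photoproducts) is adopted, not modelled.
* For two-H-bonded-component states the solver's gap-minimizing selection is
  a documented choice among a genuinely underdetermined family; conclusions
  for such states should quote the family, not only the selected member.
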