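# Methods

This note records the models behind each analysis stage, the defaults and
units of the parameters that matter, what the synthetic generators do and
do not emulate, and the numerical choices made where the design was open.

## Chain lattice and tilt from grazing-incidence diffraction

**Model.** The hydrocarbon chains of a condensed phospholipid monolayer
pack on a 2D lattice described by an oblique cell with the constraint
a = b and cell angle γ ∈ (90°, 180°). Two low-order reflections are
observable: the degenerate {1 0}/{0 1} pair at q = |a*| and the
non-degenerate {1 −1} reflection at q = |a* − b*|. Inversion uses
γ* = 180° − γ:

    cos γ* = 1 − q²_nd / (2 q²_deg),    a = 2π/(q_deg sin γ),
    A_M = n_chains · a² sin γ           (n_chains = 2 for a diacyl lipid).

Collective chain tilt makes each Bragg rod peak out of plane at

    q_z(hk) = q_xy(hk) · cos ψ_hk · tan θ,

where ψ_hk is the in-plane angle between the tilt direction ê and the
reciprocal vector g_hk. The azimuth ψ is measured from the bisector of a*
and b* (the nearest-neighbour direction); positive ψ rotates ê toward b*,
which grows the angle to a* (ψ + γ*/2) and shrinks the angle to b*
(ψ − γ*/2), while the {1 −1} rod sits at sin ψ. At ψ = 0 the pair is
exactly degenerate at q_z > 0 and the {1 −1} rod lies in the horizon —
the nearest-neighbour-tilt signature. ψ is reported in the reduced sector
[0°, 30°]; the ψ → −ψ ambiguity of which pair member is {1 0} is resolved
by trying both assignments and keeping the lower residual.

**Reduction pipeline.** Maps are integrated over q_z (default
0.0–0.7 Å⁻¹, covering both rods of a condensed film), in-plane peaks
fitted as pseudo-Voigts over a linear background (exact Voigt available;
pseudo-Voigt has the same centres at these signal-to-noise levels and
cheaper derivatives), rod profiles fitted as Gaussian-plus-constant in a
±1 FWHM q_xy window, and (θ, ψ) solved by bounded least squares. A
brute-force (θ, ψ) grid search at 0.05° step is kept as an oracle and a
finite lattice-sum of tilted chains independently validates the forward
rod positions in the tests. The degenerate pair is assigned to the
lower-q_xy peak by standard distorted-hexagonal indexing (override
available). Uncertainties on A_M, θ, ψ propagate from the peak-centre
covariance by the first-order delta method. A rod maximum on the grid
edge (q_z = 0 for untilted or NN-tilted films) is flagged `at_edge`.

**Isotherm.** The limiting molecular area extrapolates a straight-line
fit of the condensed branch (default window 20–40 mN/m) to π = 0; a
zero-slope branch or a non-monotone window is an error, not a number.

## Slab reflectivity

The forward model is the Parratt recursion with Névot–Croce damping
exp(−2 k_{z,j} k_{z,j+1} σ²) per interface. The roughness model is a
choice — the error-function profile-slicing alternative gives the same
result at these σ/d ratios and the Névot–Croce factor is kept as the
default; an independent Abelès matrix implementation agrees to 1e-10 and
serves as the oracle. Only SLD contrasts matter (tested as invariance
under a global SLD offset). Resolution smearing is omitted by default.

The monolayer model is two slabs — tails over headgroups on water
(SLD 9.47e-6 Å⁻² at 12.5 keV) — with one shared roughness, the simplest
model that fits such data. Fitting happens in log10 R with lmfit;
MCMC mode runs a seeded affine-invariant ensemble (32 walkers, burn-in
half the chain) and reports medians and 68% intervals. Fits pinned at
bounds or with log-space residuals above the noise level are flagged
(`at_bound`, `poor_fit:possible_multimodality`) — a wrong local minimum
is never returned silently. Kiessig fringe spacing estimates use
refraction-corrected minima, q′ = 2·sqrt((q/2)² − 4πΔρ), restricted to
the upper half of the located minima where the residual ~1/m shift from
the q-dependence of the interface amplitudes is negligible.

Headgroup hydration: n_w = (SLD·t·A_M − b_head)/b_water, with an optional
volume-consistency residual t·A_M − (V_head + n_w V_water); negative n_w
warns as unphysical.

## Electrochemistry

Coverage from capacitance minima, θ = (C0 − C)/(C0 − C1): C0 is the bare
metal|electrolyte interface (≈24.8 μF·cm⁻² for Au(111) in 0.1 M NaF near
−0.1 V), C1 a defect-free bilayer (0.8 μF·cm⁻², half the value of a
monolayer on mercury), C the measured minimum. The quoted coverage uses
the negative-sweep minimum (5.7 μF·cm⁻²); the positive-sweep value (6.5)
is a second supported input — the choice is the user's, the default
mirrors the reported number.

Chronocoulometry: the charge passed on stepping from a held potential E
to the desorbing potential is σ(E_des) − σ(E), so the negated transient
integrals give σ(E) up to one constant. For the bare surface the constant
is fixed by σ(pzc) = 0 — the pzc of Au(111) in NaF is a required input,
not a built-in constant. For the film-covered surface it is fixed by
matching the calibrated bare curve at the most negative common potential,
where the film is desorbed and the two interfaces are the same interface.

Film pressure by electrocapillary back-integration (dγ = −σ dE, equal γ
in the desorbed state):

    π(E) = ∫_{E_join}^{E} [σ_film − σ_bare] dE′,

with E_join defaulting to the most negative common potential.
Unit conversion: 1 μC·V·cm⁻² = 10⁻² J·m⁻² = 10 mN·m⁻¹. On the
constant-capacitance toy (C_b = 25, C_f = 5 μF·cm⁻², shared pzc 0 V,
joined at −1 V) the closed form is π(E) = ½(C_b−C_f)(E_j² − E²), i.e.
100 mN·m⁻¹ at 0 V. Integration is trapezoidal on the union of the two
potential grids, no smoothing. Every potential carries a named reference
electrode (SCE, Ag|AgCl|3 M KCl, SHE) with a configurable offset table.

## Infrared orientation analysis

**Optical constants.** From a decadic transmission absorbance A over path
d (25 μm demountable cell): k = ln 10 · A/(4π d ν̃); n by the
Maclaurin-grid Kramers–Kronig transform (opposite-parity summation
handles the principal value) anchored at n_inf (default 1.41, typical of
lipid tails). The transform window truncates the dispersion integral; on
a Lorentz-oscillator check the error stays below 0.5% away from the
window edges, which sets the recommended margin of a few bandwidths.

**Cell optics.** The spectro-electrochemical cell (prism window |
electrolyte gap | film | gold) is modelled with characteristic 2×2
matrices using tilted admittances η_s = ξ, η_p = ñ²/ξ,
ξ = sqrt(ñ² − n₀² sin²φ) with the Im ξ ≥ 0 branch. In the e^{+ikz}
downward-wave convention the matrix off-diagonals carry −i sin β; the +i
convention is the complex conjugate and is only equivalent for
non-absorbing layers — the distinction matters here because every layer
of interest absorbs. A recursive Fresnel implementation is the
independent oracle (agreement 1e-10), R + T = 1 holds for transparent
stacks, and the mean-square field profile confirms the surface selection
rule: on gold |E_z|² exceeds the tangential components by >100× at 60°.
The (angle of incidence, gap thickness) optimum is a grid search on the
band-integrated film absorbance ΔS = −log10(R_film/R_reference); a
boundary optimum is flagged. The film's non-resonant index contrast
offsets ΔS smoothly, so band areas are integrated after removing a
linear baseline through the window edges.

**Orientation.** On a metal only the surface-normal field survives, so a
band's integrated intensity measures cos² of its transition-dipole tilt.
Comparing with the area simulated for the same film with randomly
oriented dipoles (isotropic average 1/3):

    cos² θ = A_exp/(3 A_iso),

with the magic angle 54.7356° at A_exp = A_iso. All per-band optical
weighting is routed through the simulated isotropic reference rather than
a closed-form constant. Measured areas up to 5% above the 3·A_iso
saturation limit (noise near vertical dipoles) clip to θ = 0 with a
warning; beyond that they are an error. The methylene symmetric and
asymmetric stretch dipoles are mutually orthogonal and orthogonal to the
all-trans chain axis, giving

    cos² θ_chain = 1 − cos² θ_sym − cos² θ_asym,

asserted (not fitted) and tested to 1e-9; negative residuals within 0.02
clip to zero. The same machinery applies to the phosphate R–O–P–O–R′
backbone via its two stretch dipoles. Band deconvolution uses
pseudo-Voigt (mixed Gaussian–Lorentzian) lineshapes with a linear
baseline per window; the mixing fraction is held at the template value by
default because freeing it on heavily overlapped regions trades area
between neighbours. Six-band C–H and two-band amide-I templates ship with
the package. The amide-I analysis reports only the area fraction of the
higher-wavenumber component (weakly hydrogen-bonded carbonyls) — band
intensities there confound orientation with hydrogen bonding, so no tilt
is computed from them.

## Synthetic generators

One `GroundTruth` dataclass drives every stream; a fixed seed gives
bit-identical output (per-stream generators are derived from the seed and
a stable CRC of the stream name). Defaults emulate the study conditions
for a palmitoyl-sphingomyelin film and are not tuned per test:

- lattice: a = 5.013 Å, γ = 116.2°, θ = 20.6°, ψ = 12° (SM-like);
  a DPPC-like preset (5.054 Å, 116.1°, 27.1°, ψ = 0) is provided;
- capacitance: film plateau 5.7, bare 24.8 μF·cm⁻²; desorption step at
  −0.8 V with 50 mV logistic width (the step shape is a modelling choice;
  the measured shape is not parameterised anywhere);
- charge density: bare σ = C0(E − pzc_bare) with pzc_bare = 0.25 V vs
  Ag|AgCl|3 M KCl (a field-typical value; the true pzc in NaF is an
  input, not a constant); film σ follows the shallow line
  Cf(E − pzc_film), pzc_film = 0.45 V, blended onto the bare curve below
  the desorption potential. The film line lying above the bare one over
  the adsorbed range is what makes π > 0; its crossing with the bare line
  near +0.19 V produces the film-pressure maximum. The derivative of this
  σ model adds a desorption pseudocapacitance peak that the simpler
  sigmoid capacitance generator omits — the two streams are as consistent
  as the two real measurements are;
- transients: single-exponential, τ = 5 ms over a 0.15 s step from a
  −0.91 V desorbing potential in 0.05 V increments; real double-layer
  transients are multi-exponential, but one τ suffices for integral
  roundtrips. Step series in tests run to −1.1 V so the film and bare
  curves have fully merged at the anchoring potential;
- XRR: tails 16.5 Å at 8.5e-6 Å⁻², heads 8.5 Å at 13.5e-6 Å⁻², shared
  roughness 3.5 Å on water (≈25 Å total);
- PM-IRRAS: six C–H bands (2850/2872/2902/2920/2936/2960 cm⁻¹) with
  areas 3 cos²(dipole tilt) × isotropic reference; methylene dipole tilts
  derive from a chain-tilt-vs-potential profile (≈19° at positive
  potentials rising through a small maximum near −0.4 V to ≈30°) with a
  45° twist splitting sin²θ_chain equally between the two dipoles; amide
  components at 1630/1660 cm⁻¹ with a high-band fraction ramping with
  charge-density magnitude;
- isotherm: linear condensed branch crossing π = 0 at 43 Å² with slope
  −6 mN·m⁻¹·Å⁻², softened toe;
- noise: additive Gaussian for spectra, maps and capacitance (2%, 1%),
  multiplicative log-normal for XRR (5% — reflectivity spans decades).

**What the generators do not emulate** — and hence what passing recovery
tests do not show about real data: detector geometry, image splicing and
beam damage; diffuse scattering and Scherrer broadening beyond the fitted
widths; adsorption/desorption hysteresis and kinetics; photoelastic
modulator artefacts; multi-exponential transients; temperature drift.
Recovery within the stated tolerances demonstrates the correctness of the
inference chain, not instrument-level realism.

## Problem sizes

Default analyses use a 400 × 160 GIXD map, 250–300 point reflectivity
curves, ~30-potential step series at 1200 samples per transient, and
200-point spectral windows at 1 cm⁻¹ — sizes chosen to match typical
reduced instrument output while keeping a full pipeline run in seconds.
MCMC demos use 16–32 walkers over a few hundred steps; production
refinements should lengthen the chains and check the flagged diagnostics.

## Known limitations

- The two-slab XRR model is the simplest adequate one; the three-slab
  staggered-headgroup alternative is deliberately out of scope.
- ψ from two rod positions is weakly constrained near the symmetric
  (ψ = 0) point, where the residual surface is flat to first order.
- The Kramers–Kronig window truncation biases n near the window edges;
  widen the measured window rather than extrapolating k.
- The film-pressure integral inherits any miscalibration of the pzc as a
  smooth bias; it is exact only relative to the named reference state.
- Amide-I component areas are not orientation observables; only their
  fraction is reported.
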