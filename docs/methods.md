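# Methods

`beamforge` implements a machine-agnostic, convolution-based beam and
fluence model for independent Monte Carlo photon dose calculation. The
beam model is commissioned entirely from standard water-phantom beam data
— no LINAC head geometry enters anywhere — and consists of four
components: a tunable photon energy spectrum, an electron-contamination
weight, an off-axis scale (OAS) map, and a collimator-scatter convolution
kernel that encodes the machine's output factors.

## Beam model

**Spectrum.** The spectrum is a binned distribution g(E). Starting from a
generic published-shape 6 MV spectrum g0 (packaged, 15 bins of 0.4 MeV
from 0.2 to 5.8 MeV, mean 1.73 MeV), a single slope parameter s tilts it
around the mean energy:

    g_s(E) = g0(E) · (1 + s (E − ⟨E⟩_g0)).

Positive s hardens the beam. Total probability is conserved for every
admissible s (those keeping the factor positive on carrying bins), and
the mean energy shifts by exactly s·Var_g0(E) — both are enforced to
1e-12 in tests. The slope is fitted by bounded Brent search (default
bounds −0.12…0.25, absolute tolerance 1e-3) on the squared deviation
between the calculated and measured reference-field (10×10 cm²) PDD,
discretized by the trapezoidal rule on the measured depth grid. Because
dose is linear in the spectrum weights, the engine computes one
central-axis depth-dose basis curve per energy bin (a single transport
run); every candidate spectrum's PDD is then an algebraic combination, so
the scalar search is effectively free and sees no fresh Monte Carlo noise
between evaluations.

In the commissioning workflow the spectrum objective is a robustified
shape match rather than the literal squared difference:

* the depth range starts beyond the CSDA range of the fastest contaminant
  electrons — the buildup discrepancy is, by the model's own
  construction, attributed to electron contamination (next step), and
  letting the spectrum fit chase it biases the slope heavily;
* a free multiplicative amplitude is fitted in closed form — the measured
  PDD is normalized to a maximum that contains the electron component, so
  a photon-only model differs from it by a uniform scale in the fit
  region that must not be charged to the slope;
* the collimator-scatter "halo" signature (the difference between the
  model PDD with and without the current kernel) is included as a
  nuisance regressor, jointly fitted by linear least squares. The halo
  adds a smooth depth trend that is nearly collinear with a slope change;
  without the regressor, the unavoidable uncertainty of the derived
  kernel's tail imprints directly on the slope (swings of ±0.04 per-MeV
  were observed in controlled closed-loop experiments).

The stand-alone `fit_spectrum_slope` defaults to the plain full-depth
objective.

**Electron contamination.** The photon-only PDD Dx (reference field,
tuned spectrum) is compared with the measured PDD in the buildup region
z ≤ d_max; the residual is attributed to contaminant electrons carrying
the same energy fluence as the photons. De is calculated by the CSDA
electron engine from the same fluence and normalized to its maximum, and
the weight we minimizes Σ_{z≤dmax} (Dx + we·De − PDD)². Because measured
PDDs are max-normalized, the candidate curve is renormalized inside the
objective; the resulting mildly nonlinear 1-D problem is solved by
bounded search from the closed-form linear estimate, then polished by a
fixed-point iteration that is exact in the noiseless case.

**Off-axis scale.** C0(x, y) = h(√(x²+y²)) with h the measured diagonal
profile of the largest field at d_max (projected to the SAD plane,
normalized to the center; clamped beyond its last sample). In the
commissioning workflow the flattened region of h (values above 80% of the
center) is fitted by an even polynomial in r and that envelope is used
over the whole map: the measured drop at the largest-field edge is the
collimation, which the aperture masks represent — baking it into C would
double-count the edge and corrupt the corners of the largest field. One
multiplicative refinement C1 = C0·(h/h0) follows, where h0 is the
calculated diagonal profile; the ratio is restricted to the flattened
region of both profiles (the penumbra ratio is dominated by
edge-gradient mismatch and has huge leverage on any smooth fit), fitted
by the same even-polynomial family, held constant beyond, and the map is
renormalized to 1 on the axis. Diagonal profiles are extracted by
averaging the two grid diagonals (four-fold field symmetry), halving
their statistical noise.

**Collimator-scatter kernel.** The total scatter factors Scp(f) are split
as Scp = Sc·Sp: Sp comes from engine calculations with the fluence
convolution omitted (central-axis dose at d_ref, normalized to 10×10),
and Sc = Scp/Sp. Noise can make the extracted Sc dip against field size;
a pool-adjacent-violators projection restores monotonicity before
interpolation. Square-field Sc values (anchored at Sc(0) = 0) are
interpolated monotonically (PCHIP) over the equivalent-square side
√(fx·fy) to form a rectangular surface. The defining constraint is that
the convolved fluence at the field center equals Sc of the collimated
field:

    Sc(fx, fy) = ∫∫_field K(x, y) C(x, y) dx dy.

Differentiating by both field-size arguments picks up the four field
corners; with the circular symmetry of K·C this gives
∂²Sc/∂fx∂fy (fx, fy) = K(fx/2, fy/2)·C(fx/2, fy/2), i.e., the kernel is
sampled at half the field size. The implementation evaluates the mixed
difference exactly per pixel (the pixel integral of the mixed derivative
telescopes through the surface itself), divides by C, and symmetrizes
circularly. Because circular symmetrization redistributes a few percent
of mass relative to the square measured fields, the radial profile is
then refit in a layer-cake parameterization — a nonnegative combination
of centered disk indicators, which is exactly the set of nonincreasing
radial profiles — with the measured output-factor constraints enforced at
high weight and a small regularization pulling toward the differenced
shape. Below half the smallest measured field the data cannot resolve the
kernel at all; by default the regularization target concentrates that
unresolved core mass in the central pixel (physical collimator-scatter
kernels drop sharply from the center, and smearing the core would blur
every aperture edge in the fluence). The result is circularly symmetric,
nonnegative, radially nonincreasing, and reproduces Sc at every measured
field to machine precision; for the synthetic machine's
delta-plus-exponential-tail truth it recovers the core mass (r < 1 cm)
within 0.5% and the Sc predictions at unmeasured field sizes to well
under 1%.

**Commissioning order and passes.** The four stages always run in the
fixed order spectrum → electron contamination → OAS → kernel, the order
of least mutual dependence, and the workflow iterates the whole sequence
(four passes by default, configurable). The iteration is needed because
the stages are not fully separable in a scatter-rich engine: the first
pass has no kernel, so its spectrum absorbs part of the missing fluence
halo; the initial OAS carries the phantom-scatter dome of the measured
dose profile, which biases the pass-1 phantom-scatter extraction of the
largest field by about a percent and hence the first kernel's tail.
After the single OAS refinement (performed once, in pass 2, once a
kernel exists in the forward model) the kernel stabilizes and the
spectrum converges — in the closed loop the recovered slope sequence is
0.010, 0.013, 0.043, 0.046 against a ground truth of 0.050.

## Fluence calculation

Per beam, on a 1 mm cell-centered SAD-plane grid:

1. Segment intensity I = Σ_i M_i·T_i with T_i = 1 inside the aperture,
   α = 0.75 on the tongue-and-groove boundary (aperture pixels whose
   ±1-pixel y-neighbor is outside; leaf travel is along x), and β = 0
   (leakage) outside.
2. OAS scaling I ← I·C.
3. Collimator-scatter convolution f = I ⊗ K (kernel in per-cm² units, so
   the discrete convolution multiplies by the pixel area; FFT for kernels
   wider than 15 pixels, direct otherwise, equal to 1e-8).
4. Energy weighting: the energy fluence is the separable density
   f(x, y)·g(E).

Apertures are rasterized with a half-open pixel-center rule so a w-mm
opening is exactly w pixels wide (a closed symmetric rule on the
center-aligned odd grid would give w±1); this shifts every aperture by
half a pixel, identically in the synthetic generator and the forward
model.

## Transport engine

Particles start from a point source; positions are sampled on the SAD
plane proportional to the fluence, energies proportional to the spectrum,
and each particle is back-projected along its source ray to a start plane
5 cm above the phantom surface (below any beam modulation devices).
Sampling uses an exact inverse-CDF ("independence") sampler by default;
a Metropolis-Hastings random-walk sampler (Gaussian pixel-jump proposal,
σ = 5 mm, 1000-sample burn-in, one chain per seed) is provided as an
alternative backend and agrees with the independence sampler within a
total-variation distance of 0.01 on coarse bins.

The medium is water with density scaling only. Photon interactions are
Compton scattering (Klein-Nishina, Kahn sampling), photoelectric
absorption and pair production; photoelectric and pair coefficients are
packaged tables with standard published magnitudes, the incoherent
coefficient is computed from the Klein-Nishina cross section so that
attenuation and sampling are mutually consistent, and coherent scattering
is neglected. Electrons follow the continuous slowing down approximation
with Highland multiple scattering; the CSDA range table is the numerical
integral of the packaged stopping-power table, so range tests are
self-consistent. Cutoffs: photons 10 keV, electrons 100 keV (simple
termination with local deposit).

Two photon estimators exist:

* **Analog** (`transport_photons`): conventional collision-by-collision
  transport of a sampled stream, scoring transferred energy at collision
  sites or handing it to the CSDA electron stepper. Per-voxel
  uncertainty comes from batch statistics (10 batches). Used for the
  physics sanity checks (exp(−μz) narrow-beam attenuation, 1/√n
  uncertainty scaling, energy bookkeeping).
* **Hybrid expected-value** (`DoseEngine`): the production estimator.
  The first-collision energy release is computed deterministically by ray
  tracing every fluence pixel (zero variance); each Monte Carlo history
  then samples the chain of scattered generations, depositing the
  expected first-collision transfer of each generation continuously along
  its flight path. The released energy is redistributed along the beam
  axis with a per-energy-bin forward depth-deposition kernel computed by
  the package's own CSDA electron model (deterministic), which produces
  the dose buildup without per-event secondary tracking. At the
  commissioning scale of 1e6 histories per calculation this keeps
  central-axis PDD noise near half a percent, where analog collision
  scoring would leave 10-15% — the difference between a usable and an
  unusable closed loop at desk-scale history counts.

Random numbers are counter-based per history (splitmix64 of the seed and
the history index): every history's stream is independent of all others,
so runs are bit-reproducible given the seed, and paired calculations that
share seeds (the closed-loop validation) stay correlated even when a few
histories change their sampled pixel. The closed-loop study exploits this
deliberately — corresponding forward calculations in the golden-machine
generator, the commissioning workflow and the recalculation derive their
seeds from common tags, so recovery tests compare like noise with like
and measure estimator consistency rather than Monte Carlo noise.

Magnetic fields are supported as three component volumes on the phantom
grid, tri-linearly interpolated. The electron direction update per step s
is Δv = (s/R)·(v×B)/|v×B| with R the relativistic gyroradius
pc/(e c B) — the first-order similar-triangles update; the deflection
direction is +v×B by convention. The gyroradius for a 1 MeV electron in
1.5 T is 3.16 mm and the integrated trajectory closes to a circle within
1%. Magnetic deflection acts on transported electrons (including the
contamination component); the depth-kernel redistribution of
photon-released energy does not bend in the field — a known limitation
at high field strengths.

Dose components combine as D = Dx + we·De, uncertainties in quadrature.
The fluence grid is 1×1 mm²; the dose grid is 2×2×2 mm³. Commissioning
water-phantom calculations use a 36×36×32 cm³ tank (large enough for the
20 cm largest field plus lateral scatter), SAD = SSD = 100 cm, d_ref =
5 cm.

## Synthetic golden machine

The generator owns ground truth: slope s* = 0.05, electron weight
we* = 0.04, a gently horned flattened-beam OAS polynomial
(1 + 3e-4·r² − 1e-6·r⁴), and a collimator-scatter kernel of the
delta-plus-exponential-tail family (tail mass 0.10, range 1.5 cm — a
total Sc variation of ~8% from 2 to 20 cm fields, matching the magnitude
seen on clinical machines). Beam data are produced by the same forward
model used in commissioning: PDDs and the diagonal profile by transport
with the true parameters (PDDs include the weighted electron component),
Scp as the product of the kernel's Sc integral and the engine's Sp.
Optional multiplicative Gaussian noise is applied; a noisy Scp table that
loses monotonicity is regenerated with a warning.

Because generator and commissioning share the forward model, closed-loop
recovery tests isolate the commissioning mathematics from absolute
physics fidelity: they demonstrate that the parameter estimation is
consistent, not that the simplified engine reproduces a clinical beam.
Real measured data additionally contain detector volume effects,
positioning errors, beam-current drift and head-geometry details that the
golden machine does not emulate.

## Validation at desk scale

The closed-loop study (seed 1, 1e6 photons and 2e5 electrons per
calculation) generates golden beam data, commissions a model, and
recalculates: PDDs for 5×5, 10×10, 20×20 cm² fields, 10×10 cross-profiles
at 1.5/5/10 cm depth (percent of the 10×10 central dose at d_max), and
output factors for 3-20 cm fields at d_ref. Agreement is scored by 1-D
gamma (2%/2 mm, 10% low-dose threshold, global normalization) and by
maximum absolute deviations. Problem sizes (1e6 histories, 2 mm dose
grid, the field list above) are chosen so the whole study runs in minutes
on one CPU while keeping Monte Carlo noise well below the gamma criteria.

## Numerical choices and degenerate inputs

* Scalar searches: Brent with xatol 1e-3 (slope) and 1e-6 (electron
  weight); both polished/validated against closed-form or grid oracles.
* Gamma: exhaustive search within 3×DTA at DTA/4 steps (3-D) or DTA/10
  (curves); evaluated dose tri-linearly interpolated; signed by the local
  dose difference; reference and evaluated roles are not symmetric.
* Reference point: 90% isodose volume, Euclidean distance transform,
  argmax with lowest-flat-index tie-break.
* Degenerate inputs rejected with specific errors: zero-mass fluence,
  empty buildup region, non-monotone Scp, missing 10×10 output factor,
  non-positive calculated diagonal profile inside the constrained radius,
  tampered model archives (SHA-256 over component arrays).
* Dose files store float64 payloads by default so round-trips are
  lossless.

## Known limitations

* Water-equivalent medium with density scaling only; no material
  composition lookup, no bremsstrahlung production.
* The hybrid estimator redistributes photon-released energy along the
  beam axis with a mean-transfer CSDA kernel; lateral secondary-electron
  spread and magnetic bending of those secondaries are not modeled.
* Annihilation quanta are followed in the hybrid estimator but dropped in
  the analog mode (pair production is <1% of interactions at 6 MV).
* The kernel is only constrained by the measured square fields: below the
  smallest half-field radius the split between a central spike and a
  short-range tail is not identifiable from output factors alone.
* One OAS refinement per pass; strongly non-radial open-field shapes
  (e.g., asymmetric horns) are outside the model family.
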