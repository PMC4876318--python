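# Methods

## Model and assumptions

The scattering object is a stack of planar lamellae of apolar crystalline
fibrils (α-chitin in the motivating application). Three assumptions carry
the whole construction:

1. **Fibre symmetry.** The unit cell is rotationally averaged about the
   fibril long axis, so an equatorial reflection such as (110) smears into
   a thin ring in the plane perpendicular to the fibril. All rings from
   all fibril orientations lie on the reciprocal sphere of radius
   q₁₁₀ = 2π/d₁₁₀.
2. **Gaussian in-plane distribution.** Within a lamella the fibril angle γ
   (measured from the beam axis toward −z_L) follows a normalized Gaussian
   w(γ; γ₀, Δγ₀) with 180° period. The width convention is
   f(u) ∝ exp(−u²/a²), i.e. a = √2·σ, used consistently for w, for the
   ring band width a_x, and for the β-convolution kernel.
   The 180° periodicity is imposed by a periodic image sum (n = −4…4,
   converged below 1e−7 for Δγ₀ ≤ 90°); an alternative "two-root" mode
   evaluates unwrapped Gaussians at the two antipodal fibril
   representatives instead. The two differ by at most ~0.5 % in
   normalization at Δγ₀ ≈ 90° and are both exposed on
   `FibreDistribution(wrapped=...)`; wrapped is the default because it
   preserves exact normalization at any width.
3. **Elastic scattering with exact Ewald curvature.** Points measurable on
   the detector lie on the circle where the Ewald sphere cuts the
   reflection sphere. Every such point has beam-axis component
   qx_L = −q₁₁₀²/(2k), kept exact (no small-angle approximation). This
   offset is what makes the azimuthal peak separation deviate from 180°
   and gives the sign of γ₀ observable.

### Coordinate and sign conventions

Laboratory frame: x along the beam, y vertical (up), z
horizontal-transverse; detector azimuth χ counterclockwise from +z_L
(so χ = 90° is up). Body→laboratory rotation R(α, β) = R_x(−β)·R_z(α).
The free signs were fixed against the observable behaviour of I(χ):

* α > 0 strengthens the upper (χ = 90°) peak;
* β > 0 rigidly shifts both peaks toward larger χ (peaks at ≈ 90° + β and
  270° + β);
* γ₀ > 0 pulls the two peaks together (separation < 180°), γ₀ < 0 pushes
  them apart — matching the sense in which exocuticle locations with
  sub-180° separations report positive γ₀.

Reported parameter ranges: γ₀ ∈ (−90°, 90°] (γ₀ and γ₀+180° are the same
apolar population); IP β ∈ [−45°, 45°]; OP β ∈ [−90°, −60°] ∪ [60°, 90°],
fitted internally on the continuous interval [60°, 120°] and mapped back
through the exact model symmetry (α, β, γ₀) ≡ (−α, β−180°, −γ₀).

## Forward evaluation routes

* `profile_integral` — quadrature of w(γ)·ring_kernel(q·n(γ), a_x) over a
  full turn on a 2048-point uniform γ grid (configurable; converged below
  1e−6 relative for a_x ≥ 5e−3 Å⁻¹ at the default geometry). This is the
  reference model and the oracle for the closed form.
* `profile_closed` — the a_x → 0 limit,
  I(χ) = 2·w(γ_r)/√(qx²+qz²) with γ_r = atan2(qx, qz) in the body frame.
  The full turn counts each apolar fibril twice (hence the factor 2); the
  double-counting is a pure rescaling absorbed by the family scale λ.

**Degenerate pole handling.** Where the Ewald point maps onto a body-frame
pole, √(qx²+qz²) → 0 and the closed form diverges; the denominator is
floored at 1e−6·q₁₁₀ and such azimuths flagged. More importantly, for
small a_x the Ewald circle *narrowly misses* the pole spike, producing a
notch in I(χ) at χ = ±90° for an untilted lamella — an artefact of the
sharp-ring limit, not of the physics. Consequently the untilted maxima of
the raw closed form (and of the integral model at small a_x) flank 90°/270°
symmetrically rather than sitting exactly on them; tests and measurements
therefore use lobe centroids and the half-maximum arc rather than raw
argmax positions.

**β-convolution.** The remedy (and the physical statement that principal
fibril directions fan over residual tilts about the beam) is a discrete
Gaussian convolution in β: 11 offsets spanning ±2.5·Δβ with Δβ = 5° by
default. 11 points keep the discretization error below 0.5 % of a
101-point kernel. The convolution fills the notch completely for broad
distributions (Δγ₀ ≳ 55°, which covers the 50–89° range seen in cuticle);
for narrow distributions the notch is wider than the kernel and a shallow
residual dip at ±90° survives — fitting is unaffected because generator
and fit model share the same kernel, but users comparing to finite-a_x
data with Δγ₀ ≲ 40° may want a larger Δβ or the integral route.

**Peak separation measurement.** The profile of an untilted family has
four machine-equal maxima (a symmetric pair flanking each of 90°/270°
around the notch). The separation is defined as: strongest peak, then the
strongest peak in the opposite half-circle, with height ties (equal to
1e−6 relative) broken toward the antipode; quadratic sub-bin refinement
throughout. This yields exactly 180° in the symmetric case and the unique
pair otherwise.

## Fitting

Weighted least squares over the 11 parameters (α, β, γ₀, Δγ₀, λ per family
plus background), σ = √max(I, 1) when no uncertainties are supplied
(Poisson counting). The optimizer is bounded trust-region least squares
(through lmfit). The landscape is multimodal — notably near the pole
degeneracy at α ≈ ±4.3° and in the width direction, where sharpening a
misplaced peak raises χ² before lowering it — so the fit is globalized in
four deterministic, seeded stages:

1. cheap exploratory runs from the peak-based initialization plus 8
   principal-direction (γ₀) seeds per family;
2. full polish of the best start;
3. block-coordinate family sweeps: one family's γ₀ (grid of 8), Δγ₀
   (5°, 15°, 30°, 60°) and, for the OP family, β branch are re-seeded with
   the other family frozen, followed by a joint polish on improvement (up
   to 3 rounds);
4. six random perturbation restarts ("hops") around the best solution.

Stages 3–4 stop early once the weighted χ² falls below 1e−6 per data
point, a level only a noiseless profile reaches. With these defaults a
noiseless two-family profile from any of the four shipped cuticle
parameter sets refits to machine precision in 2–10 s on one core.

Initialization: detected maxima (scipy, 5 %-of-range prominence, circular
wrap) are clustered into lobes within 30° — this absorbs notch-split
sub-peaks and the spike forest near the pole degeneracy — and lobes are
paired by separation ≈ 180° with similar widths and heights. The broad
pair seeds the IP family, the sharp pair the OP family; β from the pair
mean, γ₀ from the separation via the inverted untilted relation, α from
the height asymmetry, Δγ₀ by inverting a precomputed width-vs-Δγ₀ table of
the forward model, scales from peak heights. Fewer than two peaks falls
back to a neutral seed. Δγ₀ > 85° raises a "near-isotropic" flag: γ₀ is
then weakly identified and its uncertainty should be read from the
reported standard errors, not the point value.

`grid_fit` is the brute-force oracle: an exhaustive single-family search
over (α, β, γ₀, Δγ₀) at ≥ 1° resolution with scale and background solved
by weighted linear least squares at each node (non-negativity enforced),
refusing grids above 10⁷ nodes. A simultaneous two-family grid squares the
node count and is out of reach at any useful resolution, which is why the
nonlinear fit above exists.

## Detector layer

Flat-detector mapping: tan 2θ = r/D, q = (4π/λ)·sin θ, χ = atan2(up,
horizontal) with "up" = decreasing row index. Cake regrouping averages
unmasked annulus pixels per 1° azimuth bin (mean, not sum, so bin mean ×
pixel count conserves annulus counts exactly); default annulus half-width
0.05 Å⁻¹ about q₁₁₀. Optional radial background subtracts the mean of two
flanking annuli of equal width. Solid-angle and polarization corrections
are omitted by default (negligible over the narrow annulus at the default
geometry) — the regrouping function is the hook where they would enter.
Masked pixels are carried as a mask in memory and as negative counts in
files (TIFF is written as signed 32-bit for this reason); EDF and HDF5 are
also supported.

## Synthetic data

`simulate_profile` evaluates the two-family model on a uniform χ grid,
rescales the maximum to a target peak count and draws Poisson counts —
matching a photon-counting detector; a Gaussian option is not provided
because at the count rates of interest Poisson is both correct and cheap.
`render_image` builds a full frame: the azimuthal model modulated by a
radial Gaussian ring (width 0.02 Å⁻¹) on a 487×619 grid of 0.172 mm pixels
(Pilatus-class; the ring plus annulus just fits the default beam centre).
`simulate_scan` emits a 7×12 mesh at 100 µm spacing by default, with the
IP β rotating linearly from +15.1° to −17.5° across the mesh — the
curvature signature of a carina ridge, with endpoints at the values
reported for the two flank locations of the shipped parameter table.
Generators are deterministic under a fixed seed and attach machine-readable
ground truth, so recovery tests never copy parameters by hand.

What the generator does *not* emulate: detector point-spread and module
gaps, beam polarization and absorption, radial streaking from strain,
multiple overlapping reflections, and spatial correlation of noise between
scan points. Passing recovery tests therefore demonstrate correctness of
the inverse model under its own forward assumptions, not robustness to
every instrumental artefact of real beamline frames.

## Problem sizes in the shipped tests

The acceptance suite fits four noiseless two-family profiles (360 bins),
runs a 50-replicate Poisson Monte Carlo on a single-family profile at 10⁴
peak counts, and one full render→integrate→fit round trip at 10⁵ peak
counts on one 487×619 frame — sizes chosen so the whole suite completes in
a few minutes on a single core while still exercising every stage at the
fidelity of the study conditions. The scan-mapping tests use short
transects (3–7 points) of the same per-point problem.

## Known limitations

* The closed form's residual notch for narrow distributions (above).
* γ₀ is intrinsically weakly identified as Δγ₀ → 90° (near-isotropic
  lamellae); flagged, not suppressed.
* OP-family β very close to ±90° sits at the seam of the canonical range;
  values are reported on (−90°, 90°] with the sign flips of the exact
  symmetry applied, so −87° and an equivalent +93° representation are the
  same physical lamella.
* Only equatorial (hk0)-type rings are modelled; meridional reflections
  need a different intersection geometry. One ring is fitted at a time.
* Per-point fits are independent; no spatial regularization across the
  scan (a neighbour warm-start hook exists but is off by default).
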