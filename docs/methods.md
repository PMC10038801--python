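# Methods

`p2t` simulates pair-production tomography (P2T): imaging from the
coincident 511 keV annihilation photons created when a megavoltage X-ray
beam undergoes pair production inside the imaged object.  This note records
the model, its assumptions, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Physical model

**Geometry.** The simulation lives in the axial plane of a single-ring
detector (1,440 azimuthal elements, 240 cm diameter, 10 cm axial width).
Phantoms are 2D voxel grids (default 2 mm spacing) with half-open voxel
extents and 0-based indices.  The finite axial detector extent is treated
analytically: annihilation photons are emitted isotropically in the plane,
and the axial acceptance appears only as the band efficiency
width/diameter = 4.17 % per photon (0.17 % per pair).  The exact band
solid angle would give 4.16 %; the band approximation reproduces the
conventional printed value and the difference is irrelevant at the 1e-3
level.  `project_to_ring` still accepts 3D directions and applies the
|z| <= 5 cm cut, so tilted-ray acceptance can be tested explicitly.

**Cross sections.** A three-channel parametric model stands in for library
cross sections (the package needs correct *proportionalities*, not
NIST-exact values, because every image is normalised):

* photoelectric: mu_pe = k_pe * rho * Z_eff^3 / E^3 (negligible above
  0.2 MeV by construction),
* Compton: mu_c = k_c * rho * (E/0.511)^-0.574 — a power-law fit to the
  decline of the water Compton mass attenuation between 0.511 and 10 MeV;
  the electron-density factor Z/A is treated as a single global constant
  (only the rho proportionality matters),
* pair production: mu_pp = k_pp * rho * Z_eff * (E - 1.022)^1.25, exactly
  zero below the 1.022 MeV threshold.  The Z_eff linearity (Bragg
  additivity of the pair-production mass attenuation) is the contrast
  mechanism the package exists to study and is exact in this model.

Scales are calibrated deterministically so that mu(water, 511 keV) =
0.096 /cm and the beam-effective mu(water, 10 MV) = 0.05 /cm, textbook
magnitudes that make attenuation-correction factors realistic.  The
"10 MV effective" coefficient uses energy-fluence weights p(E)*E: over a
soft bremsstrahlung spectrum, plain fluence weighting over-weights
low-energy photons that are removed within the first centimetres and
would not represent the penetrating beam.

**Spectrum.** Default 10 MV beam: thick-target analytic shape
f(E) ~ (E_max - E)/E on [0.2, 10] MeV, binned at 0.1 MeV.  Any
`Spectrum` (including a measured one) can be substituted.

**Primary transport.** Primaries fly in straight lines from a point
source; the free path is sampled exactly from the inhomogeneous
exponential law by marching the voxel grid (Siddon-segment sampling,
numba).  The interaction type is drawn with probabilities mu_i/mu_total
at the interaction voxel.  Photoelectric and Compton interactions
terminate the history; secondaries are not tracked.  Contamination of the
coincidence data is therefore modelled only through (a) the survival/
weighting of annihilation photons, (b) the per-beam discard of detector
modules struck by unscattered primaries, and (c) an optional flat
accidental background rate.  Detected-photon *purity percentages* of a
full secondary-tracking Monte Carlo are outside this model's numeric
scope; the filter cascade is verified qualitatively (background strictly
lowers list-mode purity, the energy window restores it monotonically).

**Positron range.** Travel distance before annihilation:
R | T+ ~ Weibull(k = 1.35, scale = a * T+), direction isotropic in 3D,
magnitudes scaled by rho_water/rho.  The positron kinetic energy of a
pair event is T+ ~ U(0, hv - 1.022) (the Bethe-Heitler partition is
nearly flat), with hv drawn from the spectrum weighted by mu_pp(E).  The
single coefficient `a` is solved once, deterministically, by quantile
inversion so that the median R over this population in water is 4.6 mm.
Only the median is pinned; the distribution shape (and hence the tails of
the annihilation blur) is a modelling choice.  The median T+ of this
population is about 1.5 MeV, somewhat above the ~1.1 MeV a full
simulation reports — a direct consequence of the parametric
pair-production energy shape; it slightly rescales `a` but cannot affect
the calibrated median.  The in-plane components of the 3D displacement
move the annihilation point; positrons whose step would exit the grid
annihilate at the exit point.

**Detection.** t_detection = t_incident + t_travel + t_response with
t_response ~ N(0, dT^2); t_travel is the geometric path length / c.
Energies are recorded ideally (the window acts on background records).
Release times within a pencil have i.i.d. U(0, 2/R) gaps; volume
excitation (VE) starts all pencils of a view together, scanning
pencil-beam excitation (SPBE) runs them strictly sequentially.  The
default release rate (5e4 photons/s per pencil) keeps accidental
multi-photon clusters inside the 1 ns window rare (<1 %) even with a
whole view firing concurrently.  Coincidences: time-sorted records are
chained with the 1 ns window; exact two-record clusters on distinct
elements become LORs; clusters of three or more are discarded entirely
(standard multiple-coincidence rejection — the usual PET convention,
adopted here as policy).  No arc-separation cut is applied.

**Variance reduction.**  Two optional (default-on in the pipeline)
standard techniques multiply the usable event yield without changing any
expectation:

* *forced pair production*: the interaction point is sampled from the
  analog law, but the event is always scored as a pair with statistical
  weight mu_pp/mu_total;
* *energy importance sampling*: primary energies are drawn from
  q(E) ~ p(E) * (mu_pp/mu_total)(E) with exact p/q weight compensation,
  so the sampled population concentrates on pair-producing photons.  In
  water the two weights cancel to a constant, so weight variance stays
  negligible.

Attenuation of annihilation photons is applied either as Bernoulli
thinning or as a multiplicative survival weight (config flag); both give
the same expected sinogram, which is verified by test.  Because the
simulation plane is 2D, a pencil's photon density falls as 1/r rather
than the 3D 1/r^2; each event carries one extra geometric weight sad/r so
that tallies reproduce the 3D inverse-square fluence the correction
model assumes.

## Fluence model and corrections

The per-voxel fluence of pencil b follows inverse square plus exponential
attenuation, f_vb = f_rb * (d_ref/d_v)^2 * exp(-int mu_10MV dl), with the
line integral computed by Siddon ray tracing.  f_rb is read as *particles
per pencil*: for a point source the fluence at the body-entry reference
point itself scales as 1/r_entry^2, so the entry radius cancels and the
source-axis distance (default 100 cm, configurable — the original
source-to-isocentre distance for P2T beams is not published) sets the
reference scale.  A `reference="entry"` mode evaluates the textbook
formula with f_rb as the fluence value at the entry point instead.

For *quantitative* correction of P2T images the package uses a
pair-weighted spectral fluence map: the spectrum is split into 12 groups
of equal pair-production weight p(E)*mu_pp(E), each attenuated with its
group-effective mu, then summed.  A single effective-mu map would
over-attenuate the image-forming (much harder) part of the beam by
roughly 2 % per centimetre of water, which is fatal to a 1 %-level
linearity claim.  The fluence-corrected image I/f is then proportional to
rho * Z_eff.

Attenuation correction: P_c(i) = P_r(i) * exp(+int mu_511 dl) on the
sinogram for FBP; the same per-LOR chord factor weights the event tallies
for SPB and TOF.  In weighting mode the two photons' survival weights
multiply to exp(-int over the full chord), so correction and attenuation
cancel exactly, as in ideal PET.

## Reconstruction

* **Rebinning**: LORs are binned by signed perpendicular offset to the
  isocentre and azimuth folded to [0, pi), into 227 radial bins of 2 mm
  (extent ±22.7 cm) x 1,440 angles; angle bin k is centred at
  (k+0.5)*pi/1440.  The radial coordinate is deposited with linear
  interpolation between the two nearest bins: the discrete element pairs
  realise a lattice of chord offsets whose spacing near the centre
  (~2.6 mm) exceeds the bin width, and nearest-bin histogramming leaves
  periodically empty bins that the ramp filter amplifies into severe
  banding.
* **FBP**: per-angle zero-padded FFT, pure |f| ramp (no apodisation),
  inverse FFT, pixel-driven back projection with linear interpolation.
  The operator is linear and reconstructs a unit-density analytic disk to
  a flat interior within a few tenths of a percent.
* **SPB**: each coincidence is located at the intersection of its LOR
  with the axis of the pencil active at emission (in-plane lines
  intersect exactly; near-parallel pairs and intersections outside the
  detector chord are rejected — the skew-line gate of a 3D geometry
  degenerates to this in 2D), then splatted as a truncated Gaussian
  (sigma = 2 mm, 3-sigma support, kernel renormalised so each event
  deposits exactly its weight).
* **TOF**: the annihilation is placed on the LOR at distance
  (L + c*dt)/2 from the earlier-triggered element (dt = t_i - t_j <= 0),
  i.e. the midpoint displaced by c|dt|/2 toward the earlier element;
  positions implied outside the chord are clamped to its end and
  counted.  The recorded noisy dt is used as-is (no deconvolution).
  Resolution limit: Delta-R = c*Delta-T/2 (3 mm at 20 ps, 45 mm at
  300 ps).
* LOR endpoints are snapped to element sector centres (finite
  1,440-element resolution).

## Fixture phantoms

Elliptical water body, axes 20 x 24 cm, in air.  Ten circular inserts
(radius 1.75 cm — a typical QA-phantom insert size) on an inner ellipse
(0.64 of the body semi-axes), at angles 18°..342° in 36° steps; the
bottom three slots hold iodine, ytterbium and bismuth (left to right) and
define the partial-view region of interest.

* *nanoparticle phantom*: 7 slots hold 5 %-by-weight aqueous solutions of
  I, Ba, Gd, Yb, Ta, Au, Bi (Z = 53..83; solution density from ideal
  volume additivity), 3 slots hold water.
* *tissue phantom*: air, lung (inhale 0.26 g/cm3 / exhale 0.50 g/cm3),
  adipose, breast, water, muscle, liver, trabecular bone, dense bone,
  with standard tissue-composition-table values.  The breast composition
  (mammary gland, 0.99 g/cm3) differs from water by 1 % in density but
  13.7 % in Z_eff — the package's tables reproduce the characteristic
  ~13.6 % contrast-theory value to within the 0.1 % weight-fraction
  rounding of such tables.

## Scaled studies and their limits

The full-scale version of these experiments uses tens of billions of
primaries on a CPU cluster; this package runs desk-scale equivalents with
variance reduction:

* *High-Z linearity*: 3e7 primaries split between a 20-beam SPBE run
  (300 ps detector, feeds SPB) and a 20-beam VE run (20 ps, feeds TOF and
  FBP); >2e6 accepted coincidences per run.  Contrast is measured in
  1.2 cm ROIs against the pooled three water inserts and regressed on Z.
  Expected at this scale: r^2 >= 0.99 for fluence-corrected GT and
  >= 0.9 for SPB/TOF; FBP remains noise-dominated at imaging dose, as in
  the original study.
* *Partial view*: two opposing beams restricted to the bottom aperture
  band (y in [-8.6, -3] cm, ~20-25 % of the field), 4e6 primaries,
  compared with the full-view run through three-insert-normalised ROI
  intensities at 3x combined Poisson SE.
* *Dose monitoring*: a synthetic head-like ellipse (16 x 14 cm, one
  bone-like insert) irradiated by 7 converging aperture-limited beams;
  TERMA = sum over energy groups of f(E)*E*mu(E)/rho, the P2T tally and
  a Gaussian-blurred TERMA (sigma = 5 mm) as a documented *dose
  surrogate* — not a transport-based dose — compared through cIVH
  curves.  Real plans additionally involve optimised fluence maps and 3D
  scatter; those are accepted as inputs, not computed.

What passing these studies shows: the chain beam -> pair production ->
positron blur -> coincidence detection -> correction -> reconstruction
preserves the rho*Z_eff contrast mechanism and the partial-view property
under realistic attenuation, timing and finite-resolution effects.  What
it does not show: performance under full secondary-particle
contamination, detector-physics effects (scintillation, pile-up,
depth-of-interaction), 3D multi-ring geometry, or real patient anatomy.

## Numerical choices and degenerate inputs

* Siddon boundary ties use the half-open voxel convention (lower edge
  inclusive); traversal sums reproduce clipped chord lengths to 1e-9.
* Zero-length ray segments, voxels coincident with a source, empty ROIs
  or masks, zero reference means, sub-threshold energies, zero densities
  at an annihilation site, and LORs without pencil ids all raise
  explicit errors.
* Zero-density voxels are excluded from TERMA (set to 0 and counted).
* Fluence correction masks voxels below 1e-3 of the fluence maximum and
  reports the masked fraction.
* All randomness flows from one `numpy.random.Generator`; per-(beam,
  pencil) release schedules use spawned substreams so schedules are
  reproducible independently of chunking.
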