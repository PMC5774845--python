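# Methods

## The transmission-array model

Egyptian fruit bats (*Rousettus aegyptiacus*) echolocate with tongue
clicks emitted through the narrowly parted lips, and can re-aim their
sonar beam between the two clicks of a ~20 ms pair without any visible
motion of the head or mouth.  This package models the mouth opening as an
*acoustic transmission array*: a set of N elements along the lip gap, each
re-radiating the click that originates at the tongue.  Because element *n*
sits a distance *r_n* from the tongue, its radiation carries the phase
factor `exp(i k r_n)` (k = ω/c the wavenumber), and the far field is the
coherent sum

    P_total(u) = Σ_n P_n(u) · exp(i k r_n)

where `P_n(u)` is the far field of element *n* alone.  The tongue-path
factors are phase-only: no 1/r_n amplitude weighting is applied, and all
elements are driven with equal amplitude (the per-element source strength
is unknown; equal weighting is the maximally uninformative choice).
Moving the tongue re-shapes the whole phase profile at once — steering the
beam with a single parameter, exactly as an inter-element phase gradient
steers an engineered phased array, but without individual element control.

Three realizations of `P_n` are provided:

* **Boundary-element (BEM)**: `P_n` is the exterior Helmholtz field of a
  unit monopole placed one mesh-edge-length outside the rigid head
  surface at the element location.  This is the physically complete
  model; it is also ~10⁴× more expensive than the alternatives.
* **Baffled fast mode** (default for multi-frequency work): `P_n` is a
  monopole with geometric phase `exp(−i k x_n·u)` and the obliquity
  amplitude `((1 + u·n̂)/2)^p` about the element's outward surface normal
  n̂.  The obliquity stands in for the head's shadowing of backward
  radiation.  The exponent default `p = 2` was chosen so that fast-mode
  main lobes have widths comparable to the rigid head's directivity at
  mid-band; `p = 1` (a plain cardioid) leaves the −3 dB lobe nearly
  hemispheric and merges side structure into it.
* **Pure monopoles** (`freefield_array_beam`): the textbook phased-array
  limit, used for the closed-form steering-law and interference checks.
  Unbaffled monopole arrays radiate backward symmetrically, so this mode
  is for physics validation, not for head-realistic patterns.

The *piston comparator* is the conventional model for mouth-emitting
biosonar: a circular piston of radius *a* in an infinite rigid baffle,
`D(θ) = 2 J₁(ka sin θ)/(ka sin θ)` about the head aim and zero behind the
baffle plane.  Its beam is concentric at every frequency and its center
never leaves the axis — the null hypothesis against which the array
signatures are judged.

### Why the beam center migrates with frequency

For a straight array with a linear phase profile, the steering angle
`sin θ_s = Δφ/(kd)` is frequency-independent when the phase gradient
itself scales with k (as `k·Δr` does).  The mouth aperture, however, is a
*curved* arc and the tongue a nearby point source, so the phase profile
`k·r(s)` is not linear in arc length: no single direction aligns all
elements.  At low frequency the residual phase errors are small in
radians and the whole aperture contributes, pulling the lobe toward the
aperture's average normal (lateral).  At high frequency only the
sub-aperture with locally consistent phase stays coherent, and the lobe
migrates toward that sub-aperture's steering direction (toward the
midline for the default configuration).  This geometry-induced chirp is
the mechanism behind the frequency-dependent beam-center shift, and it
disappears for the piston, as the model predicts.

## Geometry

The canonical head is a *simplified artificial shape*: an ellipsoidal
cranium with a protruding rounded rostrum and optional ear bumps, sampled
as a radial function on a latitude/longitude grid and triangulated
watertight, then rescaled per axis so the bounding box is exactly
length × width × height (default 40 × 25 × 25 mm — a placeholder for
adult *R. aegyptiacus* head dimensions, configurable).  Ear bumps have
compact support and sit low enough that the cranium alone fixes the
bounding box, so the ears-removed variant differs only inside the ear
patches.  The mouth line is the frontal arc of the lip-seam latitude row
(10–20° below the equator), its vertices tagged left/right of the
sagittal plane.  Element sets occupy the central 60 % of one side's arc
(discrete: N evenly spaced vertices; continuous: every vertex on a
regular arc-length grid), and `rostral_shift` slides that window toward
the rostrum for placement-sensitivity studies.  Where the published
element sets sat on the real head is not recorded; this placement is the
package's own choice and every experiment exposes it.

The default emitting configuration (left clicks) is 6 discrete elements
on the left arc with the tongue 3 mm toward the emitting side and 75 %
deep into the mouth cavity.  In this regime the model exhibits the
observed phenomenology: a beam a few tens of degrees lateral at 25 kHz
drifting monotonically toward the midline by 55 kHz, an
elevation-elongated −3 dB ellipse, and ~30° of azimuthal steering per
6 mm of lateral tongue travel (forward-shifted arrays steer farther).
Units are millimetres in geometry and metres/SI inside acoustics.

## Boundary-element solver

Direct collocation with piecewise-constant elements on the closed
triangle mesh: `(I/2 − D) p = p_inc` with the double-layer operator D
evaluated by a 6-point degree-4 Gauss rule per triangle (flat-panel
principal-value self terms vanish), dense solve.  Irregular-frequency
mitigation uses CHIEF: extra collocation rows at interior points (mesh
vertices shrunk toward the volume centroid — valid for star-shaped
bodies), solved in the least-squares sense.  CHIEF was preferred over a
Burton–Miller coupling because the hypersingular operator is delicate
with constant panels while CHIEF is a few extra rows; at the ka this
package solves densely (ka ≤ ~20) a handful of interior points suffices.
Validation: for a monopole at 1.3 radii from a rigid sphere at ka = 2,
the far field matches the analytic partial-wave series to ~1.3 % RMS on
a 320-panel mesh (λ/8 edges) and ~0.3 % after one refinement step.

## Beam-pattern reconstruction

Per click and microphone, the raw ESD is compensated by spherical
spreading `20·log10(range/r_ref)` (r_ref = 0.1 m), atmospheric absorption
`α(f)·range` with α from the ISO 9613-1 analytic formulas (the correction
model is not otherwise specified; ISO 9613-1 is the standard choice),
microphone sensitivity, and receiving directivity (flat by default, with
a pluggable baffled-piston receiver model).  Microphone directions are
expressed in a bat-centred frame built from three head markers: aim from
the rear-pair midpoint to the front marker, head-up from the marker-plane
cross product, azimuth positive to the animal's left and elevation
positive dorsal.  When markers drop out, the aim falls back to the
horizontal projection of the trajectory tangent with the floor normal as
head-up.

**Interpolation.** Scattered directional samples are interpolated with an
exact Gaussian radial-basis interpolant on chordal distance (a monotone
function of the great-circle angle), kernel scale 2× the median
nearest-neighbour spacing, solved with a constant polynomial term.
Interpolation runs in the linear energy domain — the ESD itself — rather
than in dB.  Two numerical findings drove this design: polyharmonic
(thin-plate) kernels on ~34 sparse spherical nodes with a 40 dB dynamic
range produce long-range ringing that can place the global maximum over
100° from the true peak, and any interpolant evaluated far from the
sample set is extrapolation.  Accordingly the evaluation grid is masked
to cells within a coverage angle (default 30°) of a sample; uncovered
cells are set to the floor (−60 dB) and excluded from normalization.
The interpolant reproduces its nodes to better than 1e−9 dB.

**Contours and ellipses.** Maps are normalized to a 0 dB maximum per
frequency; the −3 dB iso-contour enclosing the maximum is extracted on
the grid and projected under the equal-area Eckert IV projection (forward
auxiliary angle solved by Newton iteration to 1e−10).  A direct
least-squares conic fit constrained to ellipses (stable partitioned
formulation) summarizes the contour; the ellipse center, mapped back
through the inverse projection, *defines* the beam center, and the
azimuth/elevation extents are measured on the inverse-projected ellipse
boundary, compensating the projection's elevation stretch.  Circles
report zero rotation by convention.  A cross-check metric — the mean
direction of all cells above −1 dB — agrees with the ellipse center to a
few degrees on well-sampled beams.

**Quality criteria.** Five parameterized predicates gate clicks:
azimuthal span ≥ 120°, elevational span ≥ 60°, the maximum-intensity
microphone not on the convex-hull boundary of the sampled directions,
≥ 5 microphones within 30° of the maximum-intensity microphone, and peak
level ≥ 10 dB above the noise floor.  The original thresholds are not
published; these defaults are declared approximations, all exposed in
configuration.

## Alignment and averaging

Each click is iteratively centred at the 35 kHz reference frequency:
reconstruct → fit the −3 dB ellipse → shift every microphone coordinate
by minus the ellipse center, stopping when the center is within tol
(default 0.5°; the validation experiments use 0.25°) or after 20
iterations.  What exactly should be *rotated* during alignment is left
open by the procedure's description; rotation of the constellation about
the origin to level the ellipse's major axis is implemented behind a
flag, with pure shifting as the default.  Shifted elevations are kept
strictly off the poles, where azimuth degenerates.

Aligned clicks of one side are merged by pooling their per-microphone
normalized samples, averaging in 10° × 10° azimuth–elevation bins (empty
bins stay missing), and interpolating the occupied bin centers with the
same spherical RBF at kernel scale 1× the bin spacing — bin centers form
a dense regular set, and a tighter kernel avoids radially smoothing away
the beam's anisotropy.  Because averaging pools *samples* across clicks
rather than per-click maps, the average beam is far more densely sampled
than any individual click.

## Synthetic sessions

The generator emulates the flight-room experiment: a 2.3 × 2.3 × 2.4 m
room; 34 microphones, most tiling the front wall (toward which the bat
flies) and the rest on the other walls, ceiling and floor, all facing
the room center — a uniform spread of 34 microphones over 4π would put
only ~0.4 microphones inside a 25°-wide main lobe, which no interpolant
can recover; a shuttle flight (C² sinusoids in x, y, z) with rigid
head-stage markers at 200 frames/s and independent per-frame marker
dropout (default 5 %); click pairs at 5 pairs/s with a 20 ms intra-pair
interval, left then right, emitted while heading toward the front wall,
with inter-click angles drawn uniformly from 20–60° (the colony's true
distribution is unpublished; the uniform support is a declared stand-in)
split symmetrically about the head aim.

Per microphone, the truth model's level in the click's beam frame has
spreading, absorption and sensitivity *applied*, so that the
reconstruction's compensation inverts the propagation exactly; i.i.d.
Gaussian noise in dB (default σ = 1 dB) is then added per microphone and
frequency.  Raw levels are not floored at the noise floor, so noise-free
round trips are exact to 1e−9 dB; the stored noise-floor value feeds the
SNR quality criterion.  Truth models: an anisotropic Gaussian (24° × 36°
−3 dB widths — the fast fixture), the baffled piston (5 mm radius; small
enough to be realistic, large enough that a −3 dB contour exists at
25 kHz), and the transmission-array fast mode; a per-click randomized
pool of models supports the sampling-bias validation.  Truth models are
expressed in a *beam-centred* frame: the array model is rotated (an
isometry, iterated until the residual is < 0.25°) so its own 35 kHz beam
center sits at the origin, making "click aim" mean "beam direction" for
every model and keeping inter-click angles measured between beams.
Right-pointing clicks use the azimuthal mirror image of the left-click
truth model.  Everything is
deterministic in the session seed, to the point of byte-identical HDF5
serialization.

What the generator does **not** emulate: room reverberation and echoes,
waveform-level click structure (ESDs are synthesized directly),
microphone self-noise spectra, motion-capture jitter beyond marker
dropout, and behavioral correlations between click aim and flight
manoeuvres.  Pipeline validations on this data therefore demonstrate
correctness of the *analysis chain* under known truth, not robustness to
every artifact of real recordings.

## Problem sizes and numerical choices

Validation experiments use a 1° reconstruction grid, 25–55 kHz in 5 kHz
steps, ~200-click sessions for pipeline recovery, sphere meshes of
320/1280 panels for the BEM oracle, and 30-click populations per model
arm for the rank-sum comparisons — sizes at which every experiment runs
on a single CPU in minutes while leaving the statistics stable.  The
rank-sum test switches from exact enumeration to the tie-corrected
normal approximation above a combined n of 12.  Dense linear algebra
throughout; no iterative solvers.

## Known limitations

* The fast mode's obliquity factor is a surrogate for scattering; it
  cannot reproduce diffraction ripple or ear effects, and BEM runs at
  full click-band frequencies require meshes (≳10⁴ panels) beyond the
  dense solver's comfortable range.
* The simplified head is a re-creation from a described construction,
  not a replica; published per-element coordinates do not exist.
* Beam-center recovery through the pipeline is validated to ~1° with
  1 dB noise; systematic biases below that level (kernel smoothing,
  binning) are not separately corrected.
* The two-sided aperture experiment assumes perfect bilateral symmetry
  of the head mesh, which the constructed geometry satisfies exactly but
  a real head would not.
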