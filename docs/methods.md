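# Methods

`uedindex` predicts and indexes Bragg-spot patterns from thin, imperfect
quasi-single crystals in transmission electron diffraction, where blurred
and overlapping reflections defeat position-only autoindexing.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Diffraction model

All intensities are kinematical: a reflection `hkl` carries
`|F_hkl|^2` evaluated from the CIF contents with the 5-Gaussian electron
scattering-factor parameterization for neutral atoms (amplitude
`f(s) = sum_i a_i exp(-b_i s^2)`, `s = sin(theta)/lambda = 1/(2d)`),
per-site occupancy and Debye-Waller factor `exp(-B_iso s^2)`, and a global
intensity scale and B-factor correction `exp(-B_global h^2/2)` applied at
prediction time.  Multiple scattering is out of scope; for the highly
mosaic, small-domain samples targeted here its residual effect is treated
as intensity noise that the matching is designed to tolerate.

Four imperfections broaden each reciprocal-lattice point (RLP), each as an
independent Gaussian:

* **Finite domain size** (shape transform): a trivariate normal, either a
  single relrod of width `sigma_shp` (1/Å) along a fixed direction
  ("standard"), or a full crystal-fixed covariance ("ANISO").  The widths
  relate to real dimensions through minimax-fitted factors:
  `sigma_z = t/2.35` for a thin plate (Gaussian vs the normalized sinc^2
  profile) and `sigma_z = D/2.99` for a solid sphere (vs the Fourier
  transform of the z-projected autocorrelation of the ball), with
  `sigma_q = 1/(2 pi sigma_z)`.  Both constants are re-derived at run time
  by `minimax_gaussian_factor` (bounded scalar minimization of the maximum
  absolute deviation on q in [0, 3], 6001 grid points, xatol 1e-6).
* **Mosaicity**: domain orientations scatter about the mean lattice
  orientation as a trivariate normal of rotation vectors, covariance
  `Sigma_omega` (isotropic `sigma_mos^2 I` or six parameters: three
  principal sigmas + three ZYZ Euler angles, lab frame).
* **Beam divergence**: a rotationally symmetric angular spread
  `sigma_divg` convolved into the mosaicity on the two axes perpendicular
  to the beam (a rotation about the beam does not change the beam).
* **Energy bandwidth**: a fractional spread `sigma_bwdth = d(lambda)/lambda`
  entering as an effective angular width `a h sigma_bwdth` with
  `a = lambda/2`: a radius change `dk = k sigma_bwdth` of the Ewald sphere
  shifts the sphere near an RLP at resolution h by about
  `2 sin^2(theta) dk = (h^2 lambda/2) sigma_bwdth`, which is the
  displacement an angular spread `a h sigma_bwdth` would produce.  In the
  anisotropic path this term is embedded isotropically (`3x3` identity);
  only its tangent-plane marginal is observable, where it coincides with
  the scalar quadrature `sigma_MOS^2 = sigma_mos^2 + sigma_divg^2 +
  (a h sigma_bwdth)^2`.

## Intensity and centroid of one reflection

For an RLP at lab vector `g` (length h), a local frame is built with
`e3 || g`, `e1 || k_i x g` (falling back to X when `g || k_i`) and
`e2 = e3 x e1`.  Rotations about `e3` do not move the RLP, so the
rotation-vector distribution is marginalized over that axis and converted
to tangent-plane displacements `(rho1, rho2) = h (omega2, -omega1)`,
giving the displacement covariance
`Sigma_h = h^2 [[S22, -S12], [-S12, S11]]` from the projected rotation
covariance `S`.  The shape covariance (rotated to the lab for the
crystal-fixed ANISO form) is added in the local frame, yielding a full
trivariate Gaussian around the RLP.

The Ewald sphere is locally a plane with unit normal
`n = (g + k_i)/|g + k_i|`.  The predicted integrated intensity is the
integral of the trivariate Gaussian over that plane, i.e. a 1-D normal
density `N(delta; n^T T n)` in the offset `delta`.  The offset uses a
curvature correction: instead of the chord (radial) distance, the
excitation error `e_mos` is measured as arc length on the constant-|h|
sphere in the `(e2, e3)` plane (solving
`sin(a) e2.z + cos(a) e3.z = -h lambda/2` for the smaller root), and
`delta = e_mos * |n_t|` with `n_t` the in-tangent-plane component of `n`.
For pure isotropic mosaicity this reduces exactly to
`I(e)/I(0) = exp(-e^2 / (2 h^2 sigma^2))` in the arc length e; for small
offsets it coincides with the straight-line trace integral of the
tangent-plane treatment.  The reported `partiality` is this density value
(units Å); intensity = `scale * |F|^2 * exp(-B h^2/2) * partiality`.

The centroid is the conditional mean of the Gaussian on the Ewald plane,
`mu = -delta T n / (n^T T n)`, mapped back to the sphere radially and
projected to the detector.  An RLP exactly on the sphere therefore
predicts its geometric projection.

**Standard modeling** replaces this with the two-case construction:
`sigma*^2 = sigma_shp^2 + (h sigma_MOS)^2`; case A evaluates the Gaussian
density at the arc excitation error `e_mos` (intersection of the
constant-|h| sphere with the Ewald sphere), case B at the relrod
excitation error `e_shp` (intersection of the relrod line with the
sphere); intensity and detector centroid are averaged with weights
proportional to `h sigma_MOS / e_mos` and `sigma_shp / e_shp`, normalized
to sum 1, with each excitation error floored at 1e-6 1/Å (the weights
diverge on-sphere, where the two cases coincide anyway).  The relrod is
along +Z unless tilted; in tilt series with `tilt_use` it co-rotates with
the sample.

Degenerate (zero-variance) directions contribute delta factors: only
`n^T T n` enters the intensity, and a zero value yields zero intensity
rather than jitter.  Reflections beyond 4 combined sigmas of excitation
are skipped (`cutoff_sigma`, configurable); the neglected Gaussian tail is
< 0.01% of peak.  The rotation of the shape function by the in-plane
rotation components is neglected (tangent-plane approximation); the
marginalization is accurate for sigmas up to several degrees and degrades
gracefully for extreme anisotropy.

## Matching and cost

Observed spots get disjoint circular **ambits**; the default radius is
half the minimum pairwise spot distance, and user radii are clipped down
to that bound (the disjointness is load-bearing: every prediction belongs
to at most one spot).  Membership is strict (`< r_a`).  Per spot,
contributions sum and centroids are intensity-weighted.  The cost is

    S = S(I,hits) + w2 * S(I,nohits) + wP * S(P)

with `S(I,hits) = sum w_io (I_clc - I_obs)^2`, `w_io = I_obs^(-1/2)` for
target "I", or `sum (sqrt(I_clc) - sqrt(I_obs))^2` for target "sqrt(I)"
(whose no-hit branch is then `sum I_clc`, consistent with an observed
intensity of zero); unmatched spots contribute `r_a^2` to `S(P)`.
Supplied sigma(I) columns are parsed but not used (a warning is logged).
R factors are the conventional linear-scale forms
`R_I = sum|k I_clc - I_obs| / sum I_obs` with k the least-squares scale
(and the analogue on square roots); the tool labels them as such since
several conventions exist.

## Orientation search

Orientations are parameterized by the beam direction in the crystal frame
(polar angles Theta, Phi) plus a rotation Psi about the beam
(`R = Rz(psi) Ry(-theta) Rz(-phi)`, so `R^T z` is the beam direction in
crystal coordinates).  Directions are the 12 nside^2 pixel centers of an
equal-area HEALPix tessellation (nside 64 by default: 49 152 directions,
0.92 deg resolution, every direction within 1 deg of a center), visited
in a bit-reversed nested order so any prefix covers the sphere
quasi-uniformly; Psi is sampled in 1 deg steps (17 694 720 orientations
total).  The HEALPix pixel-center math is implemented here (vectorized
NESTED pix2ang) since no HEALPix library is part of the dependency set.

For a fixed direction, changing Psi rotates the predicted pattern rigidly
about the beam center (before the elliptical distortion), so reflections
are predicted once per direction and matched against all Psi values by
polar-interval arithmetic with an exact strict-ambit distance check; the
scan is deterministic, interruptible and resumable from a plain-text
checkpoint.

The figure of merit is the normalized overlap
`FOM = sum_io sqrt(I_clc,io I_obs,io) / sqrt(sum_all I_clc sum_io I_obs)`
in [0, 1]: scale-free (Cauchy-Schwarz equality at exact
proportionality), rewarding simultaneous intensity agreement and hit
coverage, and penalizing intensity predicted outside all ambits through
the denominator.  Alternative FOMs can be swapped in; this one is a
design choice, not a canonical definition.  Export of the best
orientations is greedy with a 12 deg minimum separation; inversion mates
are not deduplicated (for centrosymmetric intensities on a nearly flat
Ewald sphere, `R` and `Rz(180) R` are near-indistinguishable).

## Refinement

`PatternModel.fit` minimizes S by trust-region-reflective least squares
(scipy) on the residual vector (intensity residuals in the target's
convention, `sqrt(wP) d_io`, `sqrt(w2)`-weighted no-hit terms), with
bounds keeping sigmas nonnegative and the scale positive, forward
differences with per-parameter steps (1e-3 deg for angles, 1e-6 relative
for dimensionless quantities), and `ftol = xtol = 1e-10`.  Ambit
assignment is recomputed at every evaluation, so S is piecewise smooth;
the Gaussian blurring that motivates the whole model is also what makes
these seams benign in practice.  Accepted steps never increase S; an
uphill seam crossing at termination is rejected in favor of the starting
point.  Frozen parameters pass through bit-identically.  Tilt-series fits
concatenate residuals over images, with per-image intensity scale factors
and tilt-angle offsets (image 1 fixed) gated by the `k0_corr`/`omg_corr`
flags; the tilt-axis direction and, in single-image projects, the image
rotation are not fittable.

The pipeline helper (`refine_orientation`) encodes a staged workflow:
orientation+scale on the plain intensity target first, then a full fit on
the sqrt(I) target with `wP = S(I)/S(P)` evaluated at the hand-over
point.  The second stage is what pins the orientation to well below the
grid resolution: with `wP = 0` a sub-ambit rigid rotation of the pattern
leaves S unchanged, so orientations are only determined to the ambit
scale.

## Synthetic fixtures

The generator writes a complete project from a toy triclinic P-1
molecular cell (7 asymmetric sites: 2 S, 1 O, 1 N, 3 C; V ~ 1414 Å^3,
invented, labeled synthetic).  The emulated study conditions: 90 keV
electrons (lambda 0.0392 Å), 512x512 detector of 55 um pixels at 450 mm
camera length, plate-like domains of 400 Å thickness (sigma_shp via the
2.35 factor), isotropic mosaicity 2 deg, divergence 0.3 mrad, bandwidth
5e-4 — values chosen once as representative of transmission UED on
organic crystals.  Spots are formed by clustering predictions and then
iterating the ambit merge to a fixed point, so that with zero noise the
written reduced data equal the ambit-merged simulation exactly and the
generating parameters are an exact zero-residual fixed point of the fit.
Noise is multiplicative log-normal on intensities (default sigma 0.1) and
Gaussian centroid jitter (default 0.3 px); spots below 0.5% of the
strongest are dropped (typically ~140 spots remain).  Regeneration from
the same seed is byte-identical.

What passing on these fixtures shows: the geometry chain, profile
algebra, matching and optimizer recover parameters under the model's own
noise assumptions.  What it does not show: robustness to non-Gaussian
relrod profiles (sinc^2 side maxima), dynamical-scattering intensity
distortions, background and peak-extraction errors, or detector
nonlinearity — real reduced data carry all of these.  Accordingly the
fitted "thickness" is an effective, not geometric, quantity; the
Gaussian fit biases it low because widening sigma_q compensates the sinc
side lobes.

Rendered images draw each prediction as a 2-D Gaussian (detector-plane
projection of the reciprocal profile, isotropized for rendering, plus the
divergence footprint `sigma_divg * L_eff` and a radial bandwidth smear
`sigma_bwdth * r`), truncated at 4 sigma and floored at 0.7 px so the
pixel sum matches the integrated intensity to better than 0.5%.  These
broadenings affect images only, never the cost function.

## Problem sizes used in the test suite

The shipped tests run the grid search at nside 8-16 with the fixture's
~140 spots and a 1.2 Å scan resolution cutoff (a full nside 16 x 360 Psi
scan takes ~15 s on one core), the end-to-end recovery at 20 seeds, and
the Monte-Carlo oracle at 10^6 rotation samples per case; these sizes
were chosen so the whole suite completes in minutes while keeping every
statistical check at least 3 standard errors sharp.

## Known limitations

* Kinematical intensities only; no absorption or anomalous scattering.
* Ion scattering factors fall back to the neutral atom (logged).
* The bandwidth embedding and the FOM/R-factor definitions are documented
  package choices where the field has no single convention.
* Orientation angles at the gimbal loci (theta = 0 or 180) are recovered
  only up to the phi/psi degeneracy.
* The elliptical distortion has the inherent (eps, phi0) <->
  (-eps, phi0+90 deg) degeneracy; fits may return either representative.
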