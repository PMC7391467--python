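# Methods

## Model

### Receptive profiles and the lift

A V1 simple cell at retinal position `q = (q1, q2)` tuned to orientation
`theta`, spatial frequency `omega > 0` (radians/pixel) and phase `phi` is
modeled by the complex Gabor profile

    Psi_{(q,z)}(x, y, s) = exp(-i (r . (x-q1, y-q2) - (s-phi))) exp(-|x-q|^2 / sigma^2)

with wave vector `r = (-omega sin theta, omega cos theta)`.  The wave
propagation speed along the phase coordinate `s` is fixed to 1 (static
setting).  Every profile is the *mother* profile `exp(-i(omega y - s))
exp(-|x|^2/sigma^2)` composed with the inverse of a rigid motion (rotation
by `theta` about `q`, translation, phase shift) — the family is the orbit
of a group action, which is what induces the model geometry.

The printed form of the profile has a unit-width Gaussian; experiments use
"scale 2 pixels".  We generalize the envelope to `exp(-|d|^2/sigma^2)` with
`sigma` in pixels, recovering the unit form at `sigma = 1`.

The **lift** of an image `I` is the correlation `O(q, theta, omega) =
sum_d Psi(d) I(q+d)` per (orientation, frequency) channel, evaluated at
`s = 0`, `phi = 0`.  No conjugate appears in the forward inner product; the
conjugate belongs to the inverse transform.  The 5D coefficient field is
stored as 4D + an analytic phase axis: the coefficient at phase `phi` is
exactly `exp(-i phi)` times the phase-zero coefficient, so materializing
phases costs nothing and processing only `phi = 0` loses nothing.

### Geometry

On coordinates `(x, y, theta, omega, s)` the contact form is
`Theta = -omega sin(theta) dx + omega cos(theta) dy - ds`.  Its kernel is
spanned by the horizontal frame

    X1 = cos t dx + sin t dy,  X2 = d/dt,
    X3 = -sin t dx + cos t dy + omega d/ds,  X4 = d/domega.

The nonzero brackets are `[X1,X2] = sin t dx - cos t dy`, `[X2,X3] =
-cos t dx - sin t dy`, `[X3,X4] = -d/ds`; together with the frame,
`[X1, X2]` restores full rank (Hörmander condition), so horizontal curves
connect any two feature points.  The package derives all brackets
symbolically (sympy) rather than trusting a table, and checks the contact
property by evaluating `Theta ^ dTheta ^ dTheta` numerically with
complex-step differentiation.  **Convention note:** under the determinant
wedge normalization `1/(1! 2! 2!)` this 5-form evaluates to exactly
`-2 omega` times the coordinate volume; literature using other
normalizations quotes the coefficient as `omega`.  The invariant content —
proportionality to `omega`, nonvanishing on `omega > 0` — is what the
tests assert.

Each fixed-frequency layer carries the group of rototranslations + phase
shifts.  The multiplication we implement rotates the second factor's
translation by the **first** factor's angle (`g h = (q^g + R_{theta_1} q^h,
theta_1+theta_2, phi_1+phi_2)`), which satisfies the group axioms; a
printed variant using `R_{theta_1+theta_2}` violates the identity axiom and
is retained only behind a `printed=True` flag for comparison.

### Horizontal integral curves

Constant-coefficient horizontal curves `gamma' = c1 X1 + c2 X2 + c3 X3 +
c4 X4` model association fields.  They integrate in closed form: circular
arcs of radius `|c1/c2|` in the image plane when `c2 != 0`, straight lines
when `c2 = 0`, with `theta(t) = c2 t + theta0`, `omega(t) = c4 t + omega0`
and a quadratic phase `phi(t) = phi0 + c3 omega0 t + c3 c4 t^2 / 2`.  The
branch switch uses `|c2| > 1e-10` (below which division is fp-unsafe; the
two branches already agree to ~1e-5 at `|c2| = 1e-8`).  Curves are
truncated where `omega` would leave `R^+` (a manifold constraint).  A
classical fixed-step RK4 integrator of the velocity field serves as an
independent oracle; the suite checks agreement to 1e-6 on `t in [0,1]`.

## Inverse transform and normalization

The continuum inverse is the adjoint integral with conjugate profiles over
all positions and features.  Discretely we sum `conv(O_{k,l},
conj(Psi_{k,l}))` with quadrature weights `dtheta = 2 pi / K` (uniform) and
trapezoidal weights on the (nonuniform) frequency grid; the phase axis
contributes only the constant factor `M`, absorbed by the normalization.
The reproducing constant is not known in closed form, so the adjoint is
normalized in the Fourier domain by the bank's weighted spectral coverage
`C(f) = sum_z w_z |F Psi_z(-f)|^2`:

- **gain** `C / max(C, floor)^2` with `floor = 1e-3 max(C)`: exactly `1/C`
  wherever coverage is above the floor, rolling smoothly to **zero** below
  it.  Out-of-coverage content is suppressed, never amplified — a plain
  floored division (`1/max(C, floor)`) amplifies boundary-mismatch energy
  at weakly covered frequencies by up to `max(C)/floor` relative to the
  passband and visibly corrupts reflect-mode reconstructions.
- **boundaries**: the forward lift pads reflectively (default; periodic
  mode available for spectral experiments).  In reflect mode the Fourier
  division is applied to the whole-sample symmetric (DCT-style) extension
  of the adjoint output and then cropped; the coverage filter is even, so
  this realizes reflective boundary conditions for the deconvolution and
  keeps boundary error local (interior max error ~1e-3, global relative L2
  ~4% on a 64x64 band-limited scene with 25-pixel filters).  On a periodic
  grid the bank-normalized round trip is exact to machine precision
  wherever coverage is above the floor.
- **normalization modes**: `"bank"` (above; the production choice — it
  inverts the *given* bank as well as possible) and `"radial"`, which
  divides by the angular average of the coverage instead.  The radial mode
  is deliberately independent of the orientation count K: it represents
  the orientation-continuum inverse, so orientation under-sampling shows
  up as genuine round-trip error instead of being absorbed into a
  bank-adapted Wiener filter.  `roundtrip_error` therefore defaults to
  periodic + radial; with the dense 29-frequency protocol the error falls
  monotonically in K (6.6% at K=4, 0.34% at K=8, ~0.10% at K=16 and 32 on
  the reference band-limited scene).

## Laplace–Beltrami flow

Enhancement evolves each frequency channel `u(x, y, theta)` (a
rototranslation layer; `c3 = c4 = 0` in this reduced flow) by
`du/dt = L u` with

    L u = (1/sqrt(det g)) sum_ij Y_i ( sqrt(det g) g^{ij} Y_j u ),
    g = I + w w^T,  w = (Y1 u, Y2 u),  Y_i = sqrt(c_i) X_i.

Writing the operator in the weighted fields `Y_i` makes the
small-amplitude limit exactly the weighted sub-Riemannian Laplacian
`c1 X1X1 u + c2 X2X2 u` and matches the induced-metric entries
`delta_ij + sqrt(c_i c_j) X_i u X_j u`.  The rank-one structure gives
closed forms `det g = 1 + |w|^2` and `g^{-1} = I - w w^T / det g`, used
throughout (and cross-checked against brute-force linear algebra).

Weights follow the homogeneity convention `c1 = 1`, `c2 = beta^2` with
`beta = K / N` (K orientation samples on an N-pixel image): it equalizes
the sampling units of the spatial and angular axes.

### Discretization

- `X1` differences sample `u(q ± (cos theta_k, sin theta_k))` off-grid by
  cubic B-spline interpolation (prefiltered once per slice; a linear mode
  exists for monotonicity arguments).  `X2` uses periodic theta neighbors
  with spacing `2 pi / K`.
- The divergence form uses **staggered half-point fluxes** for the
  diagonal terms (conductivities `sqrt(det g) g^{ii}` arithmetically
  averaged between neighbors) and two passes of the central stencils for
  the cross terms (which vanish at identity metric).  Consequences:
  constants are exact fixed points, and at identity metric the scheme
  collapses to the classic second-difference Laplacian — the
  small-amplitude limit holds to ~1e-14 instead of the O(h^2) mismatch a
  twice-applied central first difference would leave.
- Explicit Euler step `u <- u + dt L u`; real and imaginary parts evolve
  as independent scalar flows, each inducing its own metric (default;
  `metric_source="modulus"` shares the modulus-induced metric).  The
  metric is recomputed every iteration (`metric_period` configurable).
  Non-finite values abort with the iteration number.
- Spatial boundaries are reflective, theta is periodic.

### Stability

The Gershgorin bound on the time step, with `s = 2 pi / K` and
`r = c1/c2`, is

    dt <= 4 s^2 r / (1 + 2 sqrt(2) s sqrt(r) + 3 s^2 r - |1 - s^2 r|),

which evaluates to 0.87 at the reference configuration (K = 16, r = 16);
all shipped protocols use `dt = 0.1`.  Two empirical notes, measured on
the seeded fixture: (i) at `dt = 0.1` the per-channel energy `sum u^2`
decreases strictly monotonically (the property the tests assert); (ii) at
half the printed bound (`dt ≈ 0.43`) the energy can transiently increase
by ~1% between iterations — the Gershgorin bound controls eigenvalue
location of the frozen-metric operator, not L2 monotonicity of the
explicit step, whose von Neumann limit for the identity-metric
linearization is `2 / (4 (c1 + c2/dtheta^2)) ≈ 0.36` here.  The flow
remains bounded (the evolving metric damps large gradients), but monotone
diffusion behavior should not be expected between 0.36 and 0.87.

## Synthetic data

The fixture generator emulates the enhancement experiments' conditions:
64x64 grayscale scenes in [0, 1], sums of oriented gratings
`0.5 + 0.5 c cos(omega0 (-x sin t0 + y cos t0) + p)` with sub-Nyquist
frequencies, plus seeded additive white Gaussian noise (`sigma_n` in
intensity units, unclipped — clipping happens only at image export).  The
standard scene has two gratings (theta = 0, omega = 0.75) and (theta =
pi/3, omega = 1.5), contrast 0.5 each, `sigma_n = 0.1`, seed 42 — noise
PSNR 20 dB, the regime where the printed experiments operate.  A separate
deterministic *band-limited* image (DFT-commensurate gratings, spectrum
confined to ~[0.5, 2.3] rad/pixel) supports transform round-trip
experiments free of boundary and out-of-band confounds.

What the fixtures do **not** emulate: natural-image statistics (broadband
1/f spectra, edges, occlusions), so a green enhancement test establishes
that the flow denoises coherent oriented multi-frequency structure — not
that it is competitive on photographs.  Reconstruction quality on
broadband images is limited by the bank's coverage (content beyond the
sampled frequency band is suppressed by design).

## Known limitations

- The flow processes each frequency channel independently (`c3 = c4 = 0`);
  the 4-field operator needed for texture inpainting (diffusion across
  frequency/phase) is not implemented — only the metric weights are
  exposed.
- Reconstruction is Wiener-like, not a frame-exact dual: for banks with
  coverage holes the inverse is band-limited accordingly (a warning
  reports the uncovered spectral fraction).
- `beta = K / N` assumes square (or near-square) images; non-square inputs
  use the row count.
- No sub-Riemannian distance/geodesic computations (no eikonal solver) —
  only the integral-curve families needed for association-field renderings.
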