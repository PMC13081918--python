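# Methods

`organoflow` models solute delivery and readout in a perfused organoid
imaging chamber: a vertical well (5 mm deep, 5.6 mm across) holding a
single spherical organoid (1.8 mm), perfused with a fluorescent tracer
standing in for a morphogen (SAG), imaged through calibration to
concentration, and scored for dorsal-ventral regionalization. This note
records the model, its assumptions, and the choices made where the
device datasheet leaves parameters open.

## Flow model

At the device's speed (5e-3 m/s) and scale (~5 mm), Re = rho u L / mu ≈ 4
(water-like medium, the stated medium viscosity 6.92e-3 Pa s), so
inertia is negligible and we solve steady incompressible **Stokes flow**
on a staggered (MAC) grid with a sparse direct factorization. Boundary
conditions: uniform normal inflow on the inlet port, a uniform outflow on
the outlet scaled so net outflow equals net inflow exactly, no-slip on
all walls. The discrete divergence is zero to machine precision
(checked against 1e-8 of the inlet flux per cell); an obstacle-free
channel reproduces the plane-Poiseuille profile to 0.1% relative L2 at
32 cells across.

Two modelling devices connect the 2D frontal plane to the 3D chamber:

* **Organoid no-slip by Brinkman penalization.** Organoid cells carry a
  drag `1e8 * mu / h^2`, driving interior speeds to ~1e-8 of the inlet
  speed; the transport step then zeroes organoid-adjacent face
  velocities outright, so the tracer enters the tissue by diffusion
  only, consistent with the measured surface diffusivity.
* **Out-of-plane drag.** A strictly planar cavity over-predicts
  recirculation because it lacks the shear of the cylindrical well's
  front/back walls. We add a depth-averaged Brinkman term
  `12 mu / b^2` (b = well diameter) in the momentum equations. It is
  optional (`out_of_plane_depth=None` gives the true 2D solution, used
  for the channel benchmarks).

Note the stated medium viscosity (6.92e-3 kg/(m s)) is ~10x water at
37 C; both values are accepted and neither changes the velocity field,
which is set by the imposed inflow.

## Delivery protocol

The pump injects a fixed tracer volume — 70 uL at the nominal 50 nM —
once every 300 s. At the stated linear speed that is a few seconds of
pumping per cycle, so the **flow itself is pulsatile**: the solver gates
the velocity field with the pulse protocol (`flow_gated=True`). During
an injection, the Stokes field advects tracer in at the event
concentration; between injections all boundaries are closed and the
field evolves by diffusion alone. Nothing is ever washed out, so the
chamber loads stepwise toward the pulse concentration — quickly along
the perfusion path, slowly in sheltered regions.

The default 2D pulse duration (4.0 s) preserves the *injected volume
fraction* per cycle: 70 uL into the ~123 uL well exchanges 57% of the
chamber volume, which the 2D inlet flux (5e-3 m/s through the 0.8 mm
port) delivers to the 28 mm^2 frontal section in ~4 s. The raw 3D
duration (~14 s through a 1 mm^2 port) is available by configuration, as
is an ungated, continuously perfused mode.

## Transport scheme

Scalar transport `dc/dt + div(u c) = div(D grad c) - k c` is discretized
in conservative finite-volume form: first-order upwind advective fluxes,
explicit diffusion with harmonic-mean face diffusivities across the
medium/organoid interface (D_medium 4e-10 m^2/s, a typical small-dye
value, configurable — it is not a stated device parameter; D_organoid
6.5e-14 m^2/s as measured), Dirichlet inlet concentration while the pump
runs, zero-gradient outflow, no-flux walls, and an optional first-order
uptake rate inside the organoid (default 0; only a surface
diffusivity is specified for the tissue, no consumption). The time step is 90%
of the positivity bound (`stability_limits`), which makes the update
monotone, so the **discrete maximum principle** holds: fields stay in
[0, 50] nM by construction, and closed-domain mass is conserved to
roundoff (validated at 1e-6 over 1000 steps). The scheme matches the
closed-form erfc solution of a 1D advection-diffusion front to <= 2%
relative L2 at 128 cells (tolerance asserted: 5%).

Concentrations are carried in a single nominal unit (nM, `c_inlet=50`).
Device documentation mixes units for this quantity (50 nmol/m^3 vs
50 nM); the package treats 50 nM as nominal throughout and takes no
position on the conflict.

## Chamber configuration and ROI layout

Port positions, port sizes and the organoid's resting position are not
stated device parameters; they are fixed once in `organoflow.chamber` so the simulated
exposure pattern reproduces the qualitative roles observed for the six
readout regions (top and downstream surfaces load fastest; sheltered
lower/upstream surfaces slowest; mid-chamber in between): inlet on the
left boundary at y = 4.2-5.0 mm, outlet on the right at y = 3.6-4.4 mm,
organoid centred at (1.3, 2.5) mm. With the organoid near the inlet-side
wall, the narrow gap's hydraulic resistance (proportional to width^-3)
blocks the wall current, forcing perfusion over the organoid and down
the outlet side — which is what orders the regions correctly. ROIs are
0.45 mm discs: Top/Bottom just outside the vertical rim, Right at the
upper-right (outlet-facing) rim, Left at the lower-left (sheltered) rim,
Center at the organoid centre (reads ~0: tissue diffusion over 4000 s
penetrates only ~30 um), and Middle in the mid-chamber fluid between
organoid and outlet-side wall. ROI means/extrema are computed over the
stored snapshot cadence (default 100 s for the full run; the fields
evolve monotonically under the gated protocol, so denser tracking adds
nothing).

With the default setup (112 x 100 cells, t_end 4000 s, ~13 s on one
CPU): global maximum 50.0 nM; peak ordering Top 49.98, Right 49.98 >
Middle 49.89 > Left 48.98, Bottom 42.3 nM; Middle averaged over
3000-4000 s is 49.3 nM. Doubling the resolution from 56 to 112 changes
late-run ROI means by at most ~3.4% (slowest region; exposed regions
<0.1%).

## Fluorescence quantification

Camera intensity is affine in concentration, `I = m c + b` (saturation
and quenching out of scope). Calibration is ordinary least squares on
aliquot means; R^2 is the coefficient of determination (a constant
response returns slope 0 and R^2 = 0 rather than NaN). Inversion is
`(I - b)/m` with negative pixels clamped to 0 and the clamped fraction
reported. Gradient structure is summarised as pairwise ROI offset series
and their trailing-window standard deviation. The reference calibration quality
measured on the device (R^2 = 0.9423) depends on raw measurements that
are not available here; the package reproduces the procedure and validates recovery
statistically: at 5%-of-full-scale Gaussian noise, 200 seeded
replicates give mean slope bias well under 2% with R^2 >= 0.94 in over
90% of replicates.

## Regionalization scoring

* **Domain segmentation**: organoid mask = largest connected component
  above a low threshold, holes filled; ventral mask = pixels above a
  second threshold computed on organoid pixels only, intersected with
  the organoid mask (containment enforced). The low threshold defaults
  to the lower cut of a three-class Otsu — plain two-class Otsu can
  latch onto the dorsal/ventral split when the bright ventral domain
  dominates the histogram; both methods are selectable. Areas are pixel
  counts times pixel area; the ventral fraction is 100 * A2 / A1. The
  "total area" in the reference 47.49% value is the outer domain A1:
  58,546.90 / 123,258.40 = 47.50%, whereas A2/(A1+A2) would give 32% —
  so A1 is the denominator here.
* **Spot detection** at a fixed physical diameter (4.5 um, the average
  nuclear size): difference-of-Gaussians band-pass at the spot scale
  (sigmas 0.5x and 2x the nominal spot sigma, FWHM/2.355), local maxima
  with minimum separation equal to the diameter, a noise-adaptive
  threshold (5 robust sigma of the band-passed image), and sub-pixel
  centroid refinement. Deterministic for fixed input.
* **Colocalization**: a marker spot is double-positive iff its nearest
  nucleus centre lies within 14 um (closed bound; KD-tree query,
  validated exactly against the all-pairs count). A nucleus may support
  markers from several channels; a marker matches only its nearest
  nucleus.
* **Exclusivity**: overlap index |A∩B|/|A∪B| in [0,1] (0 = fully
  exclusive territories); the both-empty case returns 0 with a
  `defined=False` flag.

## Synthetic data

Generators are seeded and bit-reproducible, and each returns the ground
truth needed to score its stage: rendered stacks (affine camera,
Gaussian or Poisson-Gaussian noise; default noise 5% of full scale — no
camera noise model is available), uniform calibration aliquots, a two-domain
organoid phantom (disc of radius 198 um matching the measured ~123,258
um^2 cross-section, ventral circular segment of requested area fraction,
linear dorsal-ventral cross-fade over a transition band emulating the
biological boundary zone), and nuclei images (Gaussian spots of 4.5 um
FWHM placed by rejection sampling, Bernoulli marker subsets, optional
radial jitter). What the phantoms do **not** emulate: optical PSF,
scattering through tissue, photobleaching, illumination flat-field, cell
crowding/overlap. Tests passing on them validate the analysis chain's
correctness, not its robustness to those real-image effects.

## Known limitations

* The 2D frontal-plane reduction, even with the out-of-plane drag,
  exchanges the mid-chamber faster than the 3D well: the mid-chamber ROI
  settles near the pulse concentration by 4000 s instead of the ~40 nM
  level seen in the full 3D chamber (within the documented
  geometry-approximation band, but at its edge). Sheltered-region
  loading times are also partly set by upwind numerical diffusion, so
  slow-ROI values carry a few-percent resolution dependence.
* The recirculating tubing loop (inlet/outlet hold-up volumes, 150 s
  recirculation time) is not modelled; the gated protocol subsumes it
  into "no washout between injections".
* The flow solver is 2D only; the optional coarse 3D mode was not built
  (grid labelling generalises, the MAC solver does not without
  substantial work).
* Z-stack spot detection is per-plane 2D; no 3D blob linking is
  implemented in the default path.
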