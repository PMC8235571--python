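# Methods

This note documents the models, numerical schemes, parameter choices and
known limitations of the `nasospray` pipeline.

## Scope and intent

The package simulates one actuation of a nasal spray into a single nasal
passage and the subsequent gravity-driven migration of the deposited liquid
film, in the inverted (vertex-to-floor) head position that aligns gravity
with the olfactory roof.  It is a desk-scale research tool: the geometry is
a parametric synthetic stand-in for a subject-specific airway, the airflow
is prescribed rather than solved, and droplet counts are represented by
statistical particles.  Quantitative deposition fractions are therefore
specific to the synthetic geometry; the object of study is the workflow and
the phenomenology (orientation/plume sensitivity, film translocation,
overflow thresholds), which are robust to these simplifications.

## Synthetic airway geometry

The passage is a swept tube over a piecewise centerline
(straight–arc–straight–arc–straight in the sagittal plane): a short
vertical vestibule entry (4 mm) into a 10 mm-radius ~90° bend, a horizontal
run holding the nasal valve (5 mm) and turbinate region (40 mm), a
nasopharynx bend (12 mm radius) and a vertical pharynx outlet (18 mm) —
about 0.10 m of passage in total, adult-nose scale.  Cross-sections are
ellipses interpolated between anatomical control stations: nostril inlet
5.5×5.5 mm semi-axes, valve slit 2.5×9 mm (0.71 cm², the flow-limiting
constriction), turbinate 3×18 mm (tall and narrow), expanding again toward
the pharynx.  A gentle three-lobe lateral pinch in the turbinate marks the
meatus channels.

Region labels: arclength spans assign VEST / VALVE / (turbinate) / NP /
PHARYNX; inside the turbinate, faces are banded by the anatomical vertical
coordinate into inferior / middle / superior meatus (bottom, middle, top
thirds), and the olfactory patch (OL) overrides the superior band on the
roof over 60–92% of the turbinate length.  Two deliberate design choices:

* **The olfactory span sits posterior to the direct-strike zone.**  A
  narrow, well-aimed plume hits the turbinate roof at 20–50% of its length;
  the olfactory cleft in a real nose is likewise shielded from straight-line
  ballistic impact.  Placing OL behind the strike zone makes the initial
  olfactory dose small (fractions of a percent) and means olfactory dosing
  is dominated by film migration — the mechanism under study — rather than
  by direct impaction.
* **The transverse device angle β defaults to 0.**  The synthetic passage is
  mirror-symmetric about the sagittal plane, so its neutral device
  orientation is in-plane; a fixed transverse tilt (natural in an asymmetric
  real nostril) simply aims the axis at the side wall here.  β remains a
  free parameter.

Anatomical frame: x left→right, y anterior→posterior, z inferior→superior.
Upright gravity is (0,0,−g); the vertex-to-floor pose flips it to (0,0,+g).
Meshes are manifold except the two open boundary loops (nostril, pharynx).
Debug geometries (unit cube, cylinder, flat patches, straight tube, periodic
vertical strips) are built through the same container machinery and carry
analytic areas for verification.

## Spray release

One actuation is `n_simulated` statistical particles (default 2×10⁴ in the
pipeline), each carrying dose/n of liquid volume; the physical count
(dose ÷ single-droplet volume, e.g. 884,194 droplets for 0.10 mL at 60 µm)
enters only the release arithmetic.  Initial positions sample a truncated
normal radial density (scale = half the 1 mm nozzle exit radius) on the exit
disc; the off-axis direction angle grows linearly with radius up to half the
full plume angle θ; speeds follow a Gaussian radial profile (centerline
jet, fast core / slow fringe).  The profile is normalized so that the
droplet-mean exit speed equals the configured V (10 m/s default) — V is a
measured mean in the spray-characterization literature — and each droplet's
speed is additionally jittered by a uniform ±50% factor representing
actuation variability.  Monodisperse 60 µm by default; a 60 ± 25 µm normal
size spectrum is available (non-positive draws resampled).

The nozzle frame anchors on the cross-section at the insertion depth
(default 4 mm) at the tip / middle / base of the nostril plane; the axis is
the vertical rotated by α in the sagittal plane, then β about the vertical.
If the axis meets the wall within 1 mm of the exit the placement is
rejected — the infeasible deep-insertion configurations.

## Airflow and droplet transport

At 1.8 L/min the nasal airflow is laminar and 60 µm droplets at 10 m/s have
stopping distances of centimeters: deposition is inertia- and
gravity-dominated.  The background air velocity is therefore prescribed:
along the local centerline tangent, section-mean speed Q/A, an elliptic
parabolic profile vanishing at the wall (section mean exactly 1, so flux is
conserved), and a configurable SM/MM/IM partition (default 0.05/0.55/0.40)
of the turbinate flow across the vertical meatus bands with per-band
quadrature normalization.  The interface accepts any queryable field, so an
externally computed (e.g. CFD) point cloud can replace it.

Droplets relax exponentially onto the local air velocity
(`τ_p = ρ_p d²/18μ`, Schiller–Naumann multiplier clamped at Re_p = 1000)
with trapezoidal position updates; per-step displacement is capped at half
the smallest mesh edge so a wall crossing cannot be stepped over.  Wall
impaction uses Möller–Trumbore segment–triangle tests against a uniform
voxel grid of faces (ties at a shared edge resolve to the lowest face id);
any contact deposits the droplet (perfect adsorption).  Droplets crossing
the nostril or pharynx plane escape; a 2 s flight-time limit marks the rest
expired, and the three fates partition the release exactly.  The tracking
loop is compiled with numba; the first call in a session pays a one-off
compilation cost.

Deliberately omitted, consistent with the flow regime: turbulent
dispersion, droplet–droplet collisions, evaporation and hygroscopic growth,
Brownian motion, two-way momentum coupling.

## Eulerian wall film

Cell-centered finite volumes on mesh faces.  Height advances by first-order
upwind edge fluxes of hV with an outflow limiter (a face cannot export more
than it holds in a step), which conserves volume to round-off and keeps
h ≥ 0.  Momentum is advected with the same upwind fluxes; vectors crossing
an edge rotate through the shared-edge hinge so film velocity stays in each
face's tangent plane on curved surfaces.  Tangent-plane gradients use
per-face least-squares stencils over hinge-unfolded neighbor centroids
(exact for linear fields); the capillary Laplacian is the Green–Gauss
divergence of that gradient.  The singular wall-drag term 3ν_l V/h is
treated implicitly with h regularized at h_min = 10 nm; its steady balance
with tangential gravity reproduces the Nusselt drainage speed g h²/(3ν_l)
independently of the time step, which the tests verify at 2% on a periodic
vertical strip.

Time stepping is explicit with an adaptive Courant bound
dt = C·min_edge/max|V| (C = 0.5), clamped to [dt_min, dt_max].  Reference
bounds are 10⁻⁷–10⁻⁵ s; the desk-scale pipeline default raises dt_max to
10⁻⁴ s on the ~1.5 mm mesh, where the Courant bound still governs whenever
the film actually moves.  Deposits accrete at their recorded impact times
(the film builds over the ~10–60 ms actuation window) rather than as one
instantaneous dump, which avoids artificial millimeter-thick start-up
puddles; each accretion mixes the droplets' tangential momentum into the
resident film mass-weightedly (the q̇ source).

**Contact-line pinning** models the epithelial liquid-holding capacity: a
face with h < h_pin contributes no outflux and its velocity is zeroed.  The
default h_pin = 200 µm is set by the observation that a ~0.1 mL dose spread
over its few-cm² deposition footprint (≈ 200 µm mean thickness) remains
static over the simulated window; with this value the solver exhibits the
observed regimes — films below a critical dose never leave their footprint,
films above it overflow and translocate toward gravity.  h_pin is
configurable and the pinning tests exercise other values.  Film separation
and stripping (droplet re-entrainment, dripping) are stubbed off: liquid
that would physically drip instead creeps along the wall, which makes the
simulated migration an upper bound on wall-borne transport.  Air shear on
the film is available (Couette estimate at a 0.3 mm near-wall sampling
distance) but the film stage defaults to quiescent air, as the inverted
head position is held after actuation; evaporation, temperature coupling,
non-Newtonian rheology and mucociliary clearance are out of scope.

## Dosimetry conventions

Deposition fraction = liquid volume in a region ÷ applied dose, in percent;
escaped and expired volumes are reported separately so the accounting
closes to 100%.  Volume weighting keeps polydisperse runs meaningful.
Candidate delivery systems are ranked lexicographically: olfactory DF
(descending), then superior-meatus DF (descending), then vestibule waste
(ascending).  Reported DFs and fold changes round to two decimals, percent
changes to integers.  The published regional dose table used in the
arithmetic checks contains an internal inconsistency (an 8.5-fold quoted
from an initial 0.16% versus the tabulated 0.15%, and a 9.4-fold versus the
tabulated 6.23/0.67 = 9.30); the package always computes folds from its own
inputs and reproduces the tabulated arithmetic (8.73, 9.30, −84%).

## What the synthetic runs do and do not show

The generator emulates the anatomy's *function* — a converging bent
vestibule that filters sprays, a slit valve that only well-aimed narrow
plumes thread, a tall turbinate whose roof collects them, an olfactory
patch reachable mainly by film migration under inverted gravity.  It does
not reproduce subject-specific scroll-shaped turbinates, left–right
asymmetry, mucosal compliance or surface texture, so absolute deposition
fractions here (e.g. a 97% superior-meatus dose for the 10°/45° system) are
far larger than in a real, more dissipative airway, and the olfactory
enhancement folds are correspondingly larger than the ~ninefold scale
reported for MRI-based anatomy.  Passing tests demonstrate correct
arithmetic, solver physics against closed forms, conservation and
determinism, and the direction and ordering of the sensitivity and
migration effects — not patient-level dose predictions.

## Numerical sizes used by default

~5,600 faces (1.5 mm target edge) for the passage; 10⁴–2×10⁴ statistical
particles per actuation; film window 0.2 s at dt ≤ 10⁻⁴ s (a few thousand
steps).  A full pipeline run takes ~10 s on one CPU after numba
compilation; the dose sweep in `analysis/05` about two minutes.  All
stochastic stages derive child seeds from the single run seed, and a fixed
seed reproduces every artifact byte-for-byte.
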