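# Methods

This note documents the models behind `dermaflux`, their assumptions, the
parameter defaults and why they were chosen, the numerical choices that
matter, and what the synthetic-data generators do and do not emulate.

## Network hemodynamics

The printed vascular plexus is represented as an undirected channel graph.
Each segment is a straight cylindrical channel of diameter d and length L
treated as a Hagen–Poiseuille resistor with hydraulic conductance
g = πd⁴/(128µL). This 1D reduction assumes steady, laminar, fully developed
Newtonian flow — justified here because the channels are long relative to
their 0.5 mm diameter and the Reynolds number at 2.4 mL/min is far below the
laminar limit. Junction losses, entrance effects, pulsatility and
non-Newtonian (cell-laden) rheology are deliberately not modelled; the 1D
network reproduces zone ordering and shear magnitudes, not local 3D flow
features near junctions.

The linear system is assembled as a weighted graph Laplacian with a fixed
volumetric inflow at the inlet node and the outlet gauge pressure pinned to
0 Pa (only pressure differences are physical). Mass conservation at interior
nodes then holds to solver precision (~1e-15 relative; the tests require
1e-9). Wall shear stress per segment is the Poiseuille closed form
τ = 32µ|Q|/(πd³), converted to dyn/cm² (1 dyn/cm² = 0.1 Pa).

Defaults, configurable throughout:

| parameter | default | rationale |
|---|---|---|
| inlet flow | 2.4 mL/min | the device's culture perfusion rate |
| viscosity µ | 1.0 mPa·s | culture medium ≈ water at 37 °C |
| channel diameter | 500 µm | printed channel dimension |

The bundled layout is an explicit approximation of the printed pattern — the
exact CAD topology and segment lengths are not tabulated anywhere — built on
a 6 mm footprint: an inlet manifold feeding two innermost horizontal rails,
five vertical interconnects per side bleeding flow to an outermost rail at
the top and bottom, and a mirrored outlet manifold. Zone hints follow the
pattern's anatomy (innermost rails high-shear, outermost rails mid-shear,
vertical interconnects low-shear). When hints are present the classifier
*verifies* the mean-shear ordering low < mid < high and flags (never raises
on) violations; without hints it splits segments by two user-supplied shear
cutoffs. On this layout the solved zone means are 2.5 / 5.5 / 13.5 dyn/cm²
(span ≈ 5.3×), spanning the physiological range of cutaneous vessels;
because the real channel lengths are unknown, exact reproduction of the 3D
FEM shear map is not attempted.

## Barrier transport forward model

Dextran transport is modelled in a 2D plan view, consistent with the
measurements being planar confocal ROI intensities; depth effects and
intralumenal advection-depletion are out of scope (continuous perfusion
replenishes the lumen, so it acts as a constant-concentration reservoir C₀).
Fluorescence intensity is assumed proportional to concentration with no
photobleaching correction.

In the gel, ∂C/∂t = D∇²C with zero-flux outer boundaries; across the vessel
wall a Robin condition J = P·(C₀ − C_wall). The solver is explicit FTCS on a
raster grid (default spacing 25 µm; the grid must resolve the membrane ring)
with time step 0.25·dx²/(4D) — a safety factor of 4 under the 2D CFL bound.
The membrane exchange is discretized as a finite-volume series conductance —
the membrane permeability P in series with the half-cell diffusive path
2D/dx, P_eff = 1/(1/P + dx/(2D)) — and integrated exactly within each step
via C ← C₀ + (C − C₀)·exp(−P_eff·dt/dx) on the first ring of gel cells.
This choice is what makes three properties hold simultaneously:

- unconditional stability in P, including the barrier-free limit P → ∞,
  where the scheme degenerates to a constant-concentration surface at the
  lumen–gel face;
- exact mass conservation: the time-integrated membrane influx equals the
  gel mass gained to machine precision;
- proper grid convergence: halving the default spacing changes the
  central-polygon trace by < 0.1% RMS.

Two closed forms serve as independent oracles on a quasi-1D strip domain:
the semi-infinite constant-surface solution C₀·erfc(x/(2√(Dt))) and the
surface-conductance (Robin) solution
C/C₀ = erfc(u) − exp(hx + h²Dt)·erfc(u + h√(Dt)) with h = P/D and
u = x/(2√(Dt)), evaluated through the scaled complementary error function
erfcx so the exponential term never overflows (the identity
exp(hx + h²Dt)·erfc(b) = erfcx(b)·exp(−u²) with b = u + h√(Dt)). The solver
matches both within 0.03% RMS at 5 µm spacing; the acceptance checks require
1%.

The "central polygon" ROI of the bundled layout is the central avascular
cell of the plexus — the gel region enclosed by the inner rail, the outer
rail and two adjacent vertical interconnects — inset one channel radius from
each channel axis. A thinner enclosed strip exists between the two inner
rails, but it saturates within ~15 minutes at the default parameters and
would leave the late trace uninformative about P.

## Inverse estimation

Estimation is two-stage, matching how such assays are analyzed: the gel
diffusivity D is fitted first on acellular (barrier-free) devices, where the
erfc solution applies, by minimizing the joint sum of squared residuals over
concentration time-courses at ≥ 3 distances from the vessel wall; then the
endothelial permeability P is fitted with D held fixed, by matching the
simulated central-polygon trace to the observed one. Both are plain
(unweighted) least squares — a weighting hook exists but is off by default —
minimized over the log of the parameter by bounded scalar (Brent)
minimization, bounds P ∈ [1e-3, 1e3] µm/s and D ∈ [0.1, 1e4] µm²/s,
relative tolerance 1e-3 on the parameter, at most 100 objective evaluations
(typical fits use ~15). The t = 0 sample is excluded: the model starts from
a dye-free gel, so it carries no information.

Degenerate and ill-posed inputs are reported, not hidden: after each fit the
objective is probed at 4× above and below the estimate, and if the SSE
changes by less than 1e-4 of the observed signal power (or the signal is
identically zero) the result is flagged `flat_objective` with
`converged=False`. This catches both all-zero traces (estimate pinned at a
bound) and the membrane-insensitive regime where P is far above the
diffusion-limited range and the trace no longer constrains it. Noiseless
self-generated data are recovered within optimizer tolerance (≪ 2%) across
P ∈ [0.05, 50] µm/s; at 5% multiplicative imaging noise the recovered P
stays within 10% of truth in ≥ 95% of seeded replicates, because the ROI
mean averages the pixel noise down substantially. Each observed trace is
fitted separately; replicate devices are averaged after fitting.

## Trafficking quantification

The image pipeline mirrors a manual ImageJ workflow, made deterministic:
frames are min-max rescaled to 8-bit, thresholded (Otsu by default, since
the original "predefined" threshold values are not recorded; a fixed
threshold can be supplied and is echoed in output metadata), and segmented
into 8-connected components. Components smaller than a minimum area
(default: 4 px² expressed in µm²) are discarded; touching cells merge into
one component — no watershed — matching simple mask counting. Cell identity
is *not* tracked across frames: retention is the count ratio
100·N_ROI(t)/N_ROI(t₀), so detaching cells and new arrivals trade off
against each other. The baseline is the first frame by default
(configurable); the retention denominator convention (attached cells at
baseline) is likewise configurable by choosing the baseline frame. Zones
must be pairwise non-overlapping (zero-tolerance polygon intersection); a
zone with no baseline cells is reported as undefined rather than failing the
whole analysis.

Infiltration depth uses the Euclidean distance transform of the vessel mask
complement: each detected cell whose centroid lies outside the vessel mask
gets the distance (µm) at its centroid pixel to the nearest vessel pixel;
centroids inside the lumen are excluded from the infiltrated count (and
tallied separately). A centroid exactly on the vessel boundary scores 0. No
minimum-distance cutoff is applied. Distances agree with brute-force
nearest-vessel search within one pixel diagonal.

Coordinates are physical µm with the raster convention origin top-left,
x right, y down; pixel centers sit at (i + 0.5)·pixel size, and polygon
inclusion is evaluated at centers.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed) using a dedicated
PCG64 stream, and records a ground-truth object sufficient to score every
downstream output (true D/P per dye, exact per-frame per-zone surviving-cell
counts, exact placed distances). Defaults encode the study conditions:

- **Dextran time-lapse**: two dyes, (D, P) = (16 µm²/s, 0.62 µm/s) for
  20 kDa and (53 µm²/s, 0.41 µm/s) for 40 kDa, frames every 5 min for
  60 min; concentration maps linearly to intensity; multiplicative Gaussian
  noise (default sd 5%, clipped at zero; chosen as a simple sufficient model
  for robustness testing — a Poisson option would be straightforward but is
  not needed by any current test).
- **T-cell perfusion**: cells are placed uniformly on vessel pixels inside
  each zone polygon (pairwise separated, across zones too, so noise-free
  counting is exact), and each survives every interval by an independent
  Bernoulli draw with its zone's survival probability. Whole-device
  cumulative survival defaults are 55%/20% (naïve) and 60%/45% (Th1) at
  5/10 min, converted to per-interval conditional probabilities; the early
  shear dependence is expressed by per-zone 5-min survival defaults
  {LS 0.80, MS 0.55, HS 0.45}, and late shear independence by equal
  second-interval probabilities. Frames default to 0/5/10 min.
- **Infiltration endpoint**: per-cell distances are sampled from a
  half-normal distribution (mean 233 µm with epidermis, n = 22; 68 µm
  without, n = 15). Only the mean and maximum of the real distance
  distribution are observationally constrained, so the half-normal shape is
  this package's declared assumption, pluggable and recorded in the truth.
  Each cell lands on the background pixel whose distance-transform value
  best matches its sample (so the realized distance is recorded exactly);
  samples beyond the device extent are redrawn up to 100 times, then raise.
- Cells render as 3 px-radius disks with σ = 1 px Gaussian blur at a default
  5 µm/px imaging scale (≈ 15 µm cell diameter). Sub-diffraction realism,
  PSF modelling and flow-coupled advection of moving cells are non-goals.

What passing on synthetic data does **not** show: robustness to uneven
illumination, debris, densely touching cells, focus drift, or photobleaching
— none of which the generators emulate. Results on real microscopy depend on
threshold choice in ways the noise-free round-trips cannot probe.

## Problem sizes used in validation

The validation suite uses a 128-cell-wide transport grid (46.875 µm spacing)
for permeability recovery, a 64-cell grid for the 20-replicate noise study, a
5 µm/px quasi-1D strip for the oracle comparisons, and 50-seed ensembles on
compact three-zone masks for the retention statistics; these sizes make the
whole suite run in well under a minute per module while leaving every check
comfortably inside its tolerance (the forward model is grid-converged below
0.1% at the default 25 µm spacing, an order of magnitude under the 1%
requirement).

## Known limitations

- The bundled geometry is a documented approximation; absolute shear values
  depend on the unknown true channel lengths, so only orderings and spans
  are asserted.
- The 2D depth-averaged transport domain cannot capture vertical
  concentration gradients near the channel floor/ceiling.
- P and D are assumed homogeneous (one value per device); per-segment
  heterogeneity and joint multi-parameter optimization are out of scope.
- Retention without tracking overestimates true adherence if new cells
  arrive between frames; with the pump stopped (as in the emulated assay)
  this effect is small.
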