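# dermaflux

Quantitative analysis pipeline for vascularized skin-on-a-chip (SoC) devices:
a bioprinted dermal construct with a perfusable channel network mimicking the
skin's superficial vascular plexus, endothelialized and perfused with
fluorescent dextran and labelled T cells. `dermaflux` replaces the manual
COMSOL + ImageJ workflow such devices are usually analyzed with by a tested,
scriptable Python pipeline, and ships a seeded synthetic-microscopy generator
so every quantification step can be validated against recorded ground truth.

It is aimed at microphysiological-systems and vascular-biology labs that need
reproducible numbers out of three assay families:

1. **Network hemodynamics.** The printed plexus is modelled as a channel graph
   of Hagen–Poiseuille resistors with conductance g = πd⁴/(128µL). Fixing the
   inlet volumetric flow Q and pinning the outlet pressure, the linear
   conductance system gives node pressures, signed segment flows, and wall
   shear stress τ = 32µ|Q|/(πd³) per segment (reported in dyn/cm²), plus a
   low/mid/high shear-zone classification with a verified mean-shear ordering.
2. **Endothelial-barrier transport and inverse estimation.** Dextran leaks
   from the perfused lumen (constant concentration C₀) across the endothelial
   barrier — a Robin condition J = P·(C₀ − C_wall) with permeability P (µm/s)
   — and diffuses through the hydrogel dermis, ∂C/∂t = D∇²C. The forward
   model is an explicit finite-difference solver validated against the
   closed-form semi-infinite solutions C₀·erfc(x/(2√(Dt))) (acellular limit)
   and its surface-conductance analogue (h = P/D). D is fitted first from
   acellular devices by least squares on the erfc solution at several
   distances from the vessel wall; P is then fitted with D held fixed by
   matching the simulated central-polygon trace to the measured one.
3. **T-cell trafficking quantification.** Time-lapse frames are rescaled to
   8-bit, thresholded (Otsu or fixed), and counted by connected components;
   retention %(t) = 100·N(t)/N(t₀) per region of interest (whole device or
   per shear zone), and infiltration depth is the Euclidean distance-transform
   distance of each extravascular cell centroid to the nearest vessel pixel.

## Worked example

Solve the bundled plexus geometry (6 mm footprint, 0.5 mm channels) at the
culture perfusion rate of 2.4 mL/min:

```bash
dermaflux hemodynamics --out shear.csv
```

`shear.csv` lists per-segment flow and shear. The zone summary (also written
to the provenance record) is

```
zone_mean_shear:  low 2.54   mid 5.55   high 13.5   (dyn/cm²)
ordering_ok: true
```

i.e. the vertical interconnects, outermost rails and innermost rails are
strictly ordered in mean wall shear and span a factor of ~5.3, covering the
physiological shear range of cutaneous vessels.

Estimate barrier permeability from a leakage trace (here a synthetic one whose
true P is 0.62 µm/s, with the gel diffusivity D = 16 µm²/s fitted beforehand
from acellular data):

```bash
dermaflux synth dextran --seed 1 --noise-sd 0 --spacing-um 46.875 --out synthetic/
# ... extract the central-polygon trace, then:
dermaflux fit-permeability --trace trace.csv --diffusivity 16 \
    --spacing-um 46.875 --out fit.json
```

prints

```
P = 0.62 um/s (sse 1.12e-10, converged True)
```

In Python the same loop is three calls:

```python
from dermaflux import default_domain, simulate_transport, TransportParams, fit_permeability

domain = default_domain(spacing_um=46.875)
series = simulate_transport(domain, TransportParams(d_um2_s=16.0, p_um_s=0.62))
fit = fit_permeability(series.times_s, series.roi_traces["central"], domain, 16.0)
print(fit.estimate)        # 0.6200...
```

## Layout

- `src/dermaflux/hemodynamics.py` — channel graph, flow solver, shear zoning
- `src/dermaflux/transport.py` — barrier-diffusion forward model and closed forms
- `src/dermaflux/inversion.py` — least-squares P and D estimation
- `src/dermaflux/trafficking.py` — thresholding, counting, retention, infiltration
- `src/dermaflux/synth.py` — seeded generators with recorded ground truth
- `src/dermaflux/io.py`, `cli.py` — formats (TIFF + JSON sidecar, ROI JSON,
  CSV traces) and the `dermaflux` command group
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices
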