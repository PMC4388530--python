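# bactrack

Automated single-bacterium motility tracking from microscopy frame series.

During a fermentation, the swimming speed of flagellated bacteria such as
*Bacillus amyloliquefaciens* tracks their metabolic state: velocity drops
into the diauxic shift, recovers afterwards, and collapses at the onset of
sporulation. `bactrack` implements the image-analysis chain that turns a
one-second series of phase-contrast frames (canonically 30 frames at
30 fps, 1280 × 960 px, 94.2 nm/px) into per-bacterium velocity statistics,
plus the two supporting calculations an automated sampling rig needs:
capillary shear-stress bounds (to guarantee sampling does not tear off
flagella) and dilution planning to the imaging cell density.

It is aimed at fermentation monitoring and microbial-motility labs that
record PNG frame series and want a tested, scriptable alternative to
vendor image-analysis GUIs.

## Method

For a series of images *A*₀…*A*₂₉ the pipeline computes, per frame, the
**sum-difference image**

> *B*ₖ = Σ_{j≠k} |*A*ₖ − *A*ⱼ| (component-wise),

which cancels everything static — background and undissolved particles in
turbid media — and highlights each swimmer at its frame-*k* position.
After subtracting twice the global pixel mean (noise floor), clipping
negatives and normalizing contrast to 0–255, bright 8-connected regions
are detected and reduced to seven characteristics: centre of mass x/y,
perimeter, area, orientation, length, width. Particles in consecutive
frames are linked by the **error matrix** *E* of weighted absolute feature
differences, *e*ᵢⱼ = Σ_c *w*_c |*f*_c(i) − *f*_c(j)|, solved as an optimal
one-to-one linear assignment (this is what prevents double assignments
when two bacteria cross); unmatched particles register as appearances and
disappearances, short interruptions are gap-closed, and spurious short
tracks are dropped. Each remaining frame-to-frame displacement becomes one
velocity vector, speed = ‖Δcm‖ · pixel size · fps, summarized as
mean ± SEM with the per-image bacteria count and a crowding QC flag
(tracking is rated for ≤ 15 bacteria per image). Stages are compared with
the two-sided Mann–Whitney U test; normality screening uses Shapiro–Wilk,
Anderson–Darling and Cramér–von Mises.

The rheology module evaluates Hagen–Poiseuille flow in a sampling
capillary: *u*_m = 4Q/(πD²), *u*(y) = 2*u*_m(1 − (2y/D)²),
γ̇ = 8*u*_m/D, τ = ηγ̇ and Re = *u*_m D/ν (laminar below 2300).
The sample-prep module computes the water mass to dilute a sample to the
imaging OD₆₀₀ (default 1.15) with a gravimetric pass/fail check.

A synthetic scene generator renders anti-aliased moving rods, static
debris and Gaussian noise with exact ground-truth tracks, so the whole
chain is testable without a microscope.

## Worked example

```python
import bactrack as bt
from bactrack.pipeline import run_pipeline_on_stack

spec = bt.SceneSpec(
    width_px=420, height_px=200, n_frames=30, noise_sd=0.0,
    bacteria=[bt.BacteriumSpec(start_xy=(50, 100), speed=28.26,
                               heading=0.0, heading_sd_per_step=0.0)],
    rng_seed=7)
stack, truth = bt.render_scene(spec)
result, particles, tracks = run_pipeline_on_stack(stack)
print(len(tracks), result.n_vectors,
      round(result.mean_velocity, 2), result.qc_flag)
```

prints

```
1 29 28.23 ok
```

one track, 29 velocity vectors, a mean of 28.23 µm/s (the rod moves
exactly 10 px/frame at 94.2 nm/px and 30 fps, i.e. 28.26 µm/s true speed,
recovered to 0.1%) and a passing crowding QC.
The same run from the shell:

```bash
bactrack scene generate --config scene.yaml --out frames/ --seed 7
bactrack track run frames/ --out results/
bactrack shear report --diameter-mm 0.5 --flow-ml-min 4
bactrack prep plan --od 2.3 --mass-g 10
```

`shear report` prints `u_m` 339.5 mm/s, `u_max` 679.1 mm/s, wall shear
rate 5432.5 s⁻¹, τ 3.91 Pa and Re 234.1 (laminar) for the 0.5 mm
capillary at the default fluid (η 0.72 mPa·s, ρ 993 kg/m³);
`prep plan` reports a dilution factor of 2.0 and 10 g of water to add.

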