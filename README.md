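# alveo4d

Quantitative analysis of 4D live-imaged alveologenesis — the postnatal
formation of the lung's gas-exchange units. Long-term oblique-plane
light-sheet movies of living lung slices show alveoli forming not by septal
subdivision but by epithelial cells clustering at contractile mesenchymal
rings, extruding 60–100 μm through them, and flattening from round AT2-like
cells into thin AT1 cells over roughly 42 hours. `alveo4d` implements the
computational side of that observation chain as a tested, reusable library:

* **preprocessing** — de-skew of sheared oblique-scan stacks (inverse affine
  resampling) and drift correction by accumulated phase cross-correlation;
* **segmentation** — local-mean thresholding (window = ⅓ of the imaging
  width along x), watershed splitting on the Euclidean distance transform,
  and marching-cubes surface meshes for per-cell volume V and area A;
* **morphometrics** — Wadell sphericity Ψ = π¹ᐟ³(6V)²ᐟ³/A, detection of
  round-to-flat transitions (onset, duration, completion), population
  flattening fractions, and rule-based scoring of alveologenesis events;
* **tracking** — optimal-assignment centroid linking with gating and gap
  bridging; per-track speed and directional processivity ρ = D/L;
* **ring analysis** — skeleton-graph detection of closed mesenchymal rings,
  equivalent-circle diameter d = 2√(A/π), contraction slopes, ring density;
* **vascular networks** — 3D thinning to filament graphs: branch points and
  per-segment arc lengths;
* **alveolar expansion model** — from boundary point clouds (t, x, y, z) to
  per-time polygons at a fixed plane z = Z with area Aᵢ, perimeter Pᵢ and
  complexity ratio Rᵢ = Aᵢ/Pᵢ.

Because multi-day microscopy volumes are enormous and not redistributable,
the package ships a first-class **scene simulator** that plants all of the
above dynamics with exact ground truth (trajectories, shape schedules, ring
diameters, drift walks, network topology) and renders them to voxel movies
with acquisition artifacts. Every analysis stage is validated by round trip
against what was planted.

## Worked example

```python
from alveo4d import simulate as sim, morphometrics as mm

trace = sim.sphericity_trace(duration=42.0, onset=20.0, noise_sd=0.03, seed=7)
event = mm.detect_flattening(trace)
print(event.onset_time, event.duration, event.completed)
# 19.21 44.39 True

cfg = sim.SceneConfig.p14_preset(seed=1)          # 200 cells, 24% flattening
truth = sim.build_scene(cfg)
events = [mm.detect_flattening(s) for s in truth.shape_series(noise_sd=0.03, seed=99)]
print(mm.flattening_fraction(events, cfg.n_epithelial))
# 24.0
```

The detector recovers the planted 42 h flattening period within a few
percent from a noisy single-cell sphericity trace, and the population
fraction (percentage of lineage-labelled cells completing the round-to-flat
transition) exactly on a noise-controlled synthetic P14 slice.

The `examples/` directory holds one short narrative script per capability
(scene simulation, registration round trip, flattening events, rings and
vessels, alveolar expansion, full pipeline); each prints the numbers it
computes and states what they mean. A thin CLI wraps the pipeline:
`alveo4d pipeline --config run.yaml`.

## Layout

```
src/alveo4d/        library modules (simulate, io, preprocess, segment,
                    tracking, morphometrics, rings, vessels, alveolus,
                    pipeline, cli)
tests/              pytest suite, including end-to-end acceptance checks
examples/           narrative scripts, one per capability
docs/methods.md     models, parameter choices, numerical notes, limitations
```
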