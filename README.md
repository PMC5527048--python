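# marrowniche

Spatial statistics and motility analysis of megakaryocytes (MKs) in bone
marrow volumes.

MKs — the large polyploid cells that release platelets into marrow
sinusoids — have classically been pictured as migrating from an endosteal
(bone-surface) niche toward the vessels as they mature.  Whole-bone 3D
imaging tells a different story: the marrow vasculature is so dense that the
typical intervascular gap (~43 µm) is about two MK diameters (~20 µm), most
MKs already touch a vessel, and tracked MKs barely move (subdiffusive,
α ≈ 0.65).  `marrowniche` packages the computational side of that analysis
for anyone who wants to run it on labeled volumes and tracks of their own —
or on synthetic geometry, since the original imaging data are not publicly
deposited.

The package provides:

* **`synthetic_data`** — label-level marrow geometry (connected sinusoid
  network with a target spacing, bone cortex shell, truncated-normal MK
  diameters, controllable vessel bias) and trajectories with prescribed
  anomalous-diffusion parameters (K_α, α), from stationary to ballistic.
* **`spatial_metrics`** — anisotropic Euclidean distance maps, MK–vessel and
  MK–bone edge distances, vessel-associated / bone-associated /
  intravascular classification, vessel-to-vessel spacing through
  intervascular centers, population summaries, and virtual 2D sectioning
  with its known distance-overestimation artifact.
* **`placement_sim`** — the two Monte-Carlo null models: **SimR** (all MKs
  placed uniformly at random in marrow) and **SimNVA** (observed
  vessel-associated MKs frozen as a scaffold, only the non-associated pool
  randomized without vessel or cell contact), with a Mann–Whitney
  comparison against the observed population.
* **`motion_analysis`** — time-averaged MSD, log-log fits of
  `MSD(τ) = 2 d K_α τ^α` (the familiar `4 K_α τ^α` in 2D), instantaneous
  velocities, motion classes (α < 1 subdiffusion, α ≈ 1 Brownian, α > 1
  superdiffusion), cohort summaries.
* **`pipeline_io`** — TIFF/CSV/JSON formats, Mann–Whitney/ANOVA plumbing
  with star coding, and `run_pipeline` chaining everything; the
  `marrowniche` CLI exposes each stage
  (`synth-volume`, `synth-tracks`, `analyze-volume`, `simulate`, `track`,
  `run`).

See `docs/methods.md` for the models, conventions, defaults, and their
rationale.

## Worked example

Generate a marrow volume under the reference conditions (43 µm target vessel
spacing, 80 MKs of 20.36 ± 8.19 µm placed with a 0.7 vessel bias), measure
it, and test both null models against it:

```python
import numpy as np
from marrowniche.synthetic_data import GeneratorConfig, synthesize_volume
from marrowniche.spatial_metrics import (annotate_population, summarize_population,
                                         vessel_to_vessel_distances, distance_map)
from marrowniche.placement_sim import sim_random, sim_nva, compare_scenarios

cfg = GeneratorConfig(seed=1)
grid, network, mks = synthesize_volume(cfg)
vm = distance_map(grid.vessel_mask, grid.spacing)
bm = distance_map(grid.bone_mask, grid.spacing)
_, ann = annotate_population(grid, mks, vessel_map=vm, bone_map=bm)
obs = summarize_population(ann, mks)
spacing = vessel_to_vessel_distances(grid, vessel_map=vm)
print(f"vessel spacing (median): {np.median(spacing):.1f} um")
print(f"MK diameter (mean +/- SD): {obs.diameter.mean:.1f} +/- {obs.diameter.sd:.1f} um")
print(f"VA fraction (3D, <=2 um): {obs.va_fraction:.2f}")

diam = np.array([o.equivalent_diameter_um for o in mks])
va = [o for o, a in zip(mks, ann) if a.vessel_associated]
nva_d = np.array([o.equivalent_diameter_um
                  for o, a in zip(mks, ann) if not a.vessel_associated])
sims = []
for rep in range(6):
    sims.append(sim_random(grid, diam, seed=100 + rep, vessel_map=vm, bone_map=bm))
    sims.append(sim_nva(grid, va, nva_d, seed=200 + rep, vessel_map=vm, bone_map=bm))
for c in compare_scenarios(obs, sims):
    print(f"{c.scenario}: VA {c.va_fraction_mean:.2f}+/-{c.va_fraction_sd:.2f}, "
          f"p(all distances)={c.p_all_distances:.2g}, "
          f"p(NVA)={c.p_nva_distances:.2f} -> {c.verdict}")
```

This prints:

```
vessel spacing (median): 44.0 um
MK diameter (mean +/- SD): 21.8 +/- 7.5 um
VA fraction (3D, <=2 um): 0.75
SimNVA: VA 0.75+/-0.00, p(all distances)=0.81, p(NVA)=0.05 -> SimNVA compatible
SimR: VA 0.17+/-0.04, p(all distances)=7.6e-19, p(NVA)=0.28 -> SimR rejected
```

Read: the realized scaffold hits the 43 µm spacing target and the MK size
distribution; 75% of the "observed" population touches a vessel.  Fully
random placement (SimR) produces far fewer vessel-associated cells and
significantly larger MK–vessel distances, so it is rejected — the observed
pool is vessel-biased.  Randomizing only the non-vessel-associated cells
around the frozen vessel-associated scaffold (SimNVA) is statistically
compatible with the observation: the "free" MKs look uniformly distributed,
i.e. nothing in the data requires directed migration toward vessels.

Trajectory analysis works the same way from the other end:

```python
from marrowniche.synthetic_data import TrajectoryConfig, simulate_trajectories
from marrowniche.motion_analysis import cohort_summary

trajs = simulate_trajectories(TrajectoryConfig(alpha=0.65, K_alpha=0.1, seed=2))
rep = cohort_summary(trajs, d=2, max_lag_fraction=0.25, reference_lag=10.0)
print(rep.alpha_median, rep.motion_classes)
```

which recovers a median exponent near the prescribed 0.65 and classifies the
cohort as predominantly subdiffusive.

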