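# lvstrain

Left-ventricular myocardial strain and strain-rate analysis from 2D
short-axis cardiac cine images, by hierarchical nonrigid registration
with optional endocardial/epicardial contour guidance.

Conventional global indices (ejection fraction, E/A ratio) are often
insensitive to early regional myocardial dysfunction; strain — local
deformation normalized to end diastole — can reveal it, for example in
early diabetic cardiomyopathy. `lvstrain` recovers the dense myocardial
displacement field of every cine frame relative to the end-diastolic
reference frame and turns it into radial strain and strain-rate curves
per AHA segment, without tagging or other extra acquisitions.

## Model

Each frame is registered to frame 0 (end diastole) with a hierarchical
transformation: a global affine part

```
(x', y')ᵀ = k R(θ) (x, y)ᵀ + (Δx, Δy)ᵀ ,    R(θ) = [[cos θ, sin θ], [−sin θ, cos θ]]
```

plus a local free-form deformation (FFD) defined by a lattice of
control-point displacements φᵢⱼ with spacing δ, interpolated by cubic
B-splines:

```
T_local(x, y) = Σₙ Σₘ Bₘ(u) Bₙ(v) φ_{i+m, j+n},     m, n = 0..3
```

combined additively as displacement fields, `T = T_global + T_local`.
Parameters are found by constant-gain gradient descent on

```
Cost = C_sim + λ · C_ICP
```

where `C_sim` is the mean of squared intensity differences between the
reference frame and the transform-resampled (cubic-spline) target
frame, and `C_ICP` ties the endo/epicardial contours of the two frames
together: the reference contour points move with the control-point
mesh, each target contour point is matched to its nearest propagated
point under the combined positional + curvature distance

```
d(M₁, M₂) = α₁ [(x₁−x₂)² + (y₁−y₂)²] + α₂ (k₁−k₂)² ,
```

and `C_ICP` is the sum of matched distances (closest-point matching
with curvature as an invariant feature). `λ = 0` recovers the plain
intensity-only method; `λ > 0` is the contour-guided variant, which is
what rescues tracking across weak edges where cine contrast vanishes.

Contours can be supplied as CSV or extracted with a gradient-vector-flow
(GVF) snake. Strain is Lagrangian Green strain `E = (FᵀF − I)/2` with
`F = I + ∇u` on the end-diastolic myocardium mask, projected radially
from the LV centroid (positive = thickening, negative = compression),
averaged per AHA segment (6 basal / 6 mid / 4 apical sectors), and
differentiated in time for strain rate.

Because no clinical data ship with the package, a synthetic beating
annulus phantom (`lvstrain.phantom`) provides the validation substrate:
analytically known displacement fields, exact contours, landmark
trajectories, closed-form radial strain, plus configurable weak-edge
arcs and hypokinetic sectors.

## Worked example

Register the peak-systolic frame of a contracting phantom (4 px peak
endocardial excursion, 1% noise) back to end diastole, with and without
the contour term, and compare against the analytic field:

```python
import numpy as np
from lvstrain import phantom as ph
from lvstrain.cost import CostConfig
from lvstrain.interp import pixel_grid
from lvstrain.registration import register_frame

spec = ph.PhantomSpec(contraction=1/3, thickening=0.25, noise_sigma=0.01)
cine, truth = ph.generate(spec)
t_peak = int(spec.systole_fraction * spec.frames)
mask = truth.myocardium_mask()
u_true = truth.displacement_field(t_peak).u
for lam in (0.0, 1.0):
    res = register_frame(cine.frames[0], cine.frames[t_peak],
                         contours_ref=truth.contours(0),
                         contours_target=truth.contours(t_peak),
                         cost_config=CostConfig(lam=lam))
    u = res.transform.displacement(pixel_grid(cine.frames[0].shape))
    epe = np.linalg.norm((u - u_true)[mask], axis=1).mean()
    print(f"lambda={lam:.0f}: mean endpoint error {epe:.3f} px "
          f"(final C_sim={res.c_sim:.5f}, C_ICP={res.c_icp:.3f})")
```

prints

```
lambda=0: mean endpoint error 0.152 px (final C_sim=0.00026, C_ICP=0.000)
lambda=1: mean endpoint error 0.075 px (final C_sim=0.00033, C_ICP=0.209)
```

The intensity-only method already recovers the 4 px contraction to
0.15 px mean error inside the myocardium; adding the contour term
(λ = 1) halves that. The same pipeline runs from the shell:

```bash
lvstrain phantom --out run/phantom --seed 1
lvstrain register --input run/phantom/frames --contours run/phantom/contours.csv \
    --lambda 1.0 --out run/reg
lvstrain strain --fields run/reg --contours run/phantom/contours.csv \
    --level mid --rv-angle 120 --out run/strain.csv
lvstrain report --strain-csv run/strain.csv --out run/curves.png
```

`run/strain.csv` holds tidy per-frame, per-segment radial strain (%)
and strain rate (1/s) curves, with the global mean as an extra
`segment = "global"` row; `report` plots them (segments in colour, the
global mean in black).

## Scope

2D short-axis analysis only: through-plane (longitudinal) motion is
not modelled, and frame-to-reference registration deliberately avoids
sequential pairwise accumulation and its error build-up. LV volumes and
ejection fraction are out of scope.
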