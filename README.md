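# mcatlas

Multi-channel diffeomorphic demons registration and 4D
Gompertz-parametrized atlas construction for developing-brain MRI.

## What this is for

Building a spatio-temporal atlas of the neonatal brain (37–44 weeks
postmenstrual age) requires aligning subjects across both structural
contrasts and diffusion fibre-orientation information, and then
modelling how every voxel's signal changes with age. `mcatlas` is a
library and CLI for researchers doing exactly that:

* **registration** of sets of co-aligned channels — T2w/T1w-like
  scalars, tissue masks, and orientation distribution functions (ODFs)
  stored as real even-order spherical-harmonic (SH) coefficients — with
  a symmetric multi-resolution demons scheme;
* **atlas construction**: age-windowed robust-average templates with
  per-window unbiasing transforms;
* **temporal modelling**: voxelwise Gompertz growth curves over the
  template series, warps and affines, giving a continuous 4D atlas;
* **analysis**: growth-rate parcellation of fast-maturing (transient)
  compartments, robust region statistics, and linear-model association
  with gestational age at birth under Bonferroni correction.

Everything is exercised on seeded synthetic phantoms with known ground
truth (deformations, Gompertz parameter maps, crossing-fibre SH
content), so the whole pipeline runs and is tested on a laptop.

## The model in brief

Scalar channels are compared with **LNCC** (local normalised
cross-correlation); ODF channels with **LAC** (local angular
correlation), a Pearson-type correlation accumulated over a cubic
neighbourhood `N(x)` and the SH coefficients of degree `l ≥ 2`:

    r_a(x) = <A,B>_x / ( <A>_x^{1/2} <B>_x^{1/2} )

with the coefficient images centred by their local means, so isotropic
(`l = 0`) content cannot influence the metric. Each metric yields a
symmetric pair of demons forces

    Λ_A = 2<A,B>/(<A><B>) (B − <A,B>/<A> A) · ∇A     (and mirrored Λ_B),

which are fused across channels by certainty weights `α̂ = |∇channel| /
max |∇channel|` and composed into two half-warps deforming fixed and
moving toward a midpoint. Template trajectories are fitted voxelwise
with the Gompertz sigmoid

    G(t) = (α − δ) exp(−exp(−γ (τ − t))) + δ,

whose rate `γ` (per week) and peak time `τ` (weeks PMA) are the maps of
interest: mean absolute rates across channels delineate transient
white-matter compartments, and `|τ − 40.5| ≥ 0.2` weeks flags early or
late maturation. See `docs/methods.md` for the full account.

## Worked example

Generate a phantom subject at 40 weeks whose deformation from its
template is known exactly, register it back using the T2w-like and ODF
channels together, and measure the endpoint error of the recovered
warp; then fit the growth model to a rising T1w-like trajectory:

```python
import numpy as np
from mcatlas import (PhantomSpec, make_phantom_subject, register_multichannel,
                     RegistrationConfig, fit_gompertz_series, gompertz)
from mcatlas.phantom import template_truth

spec = PhantomSpec(noise_sigma=0.0)                      # 48³, 1 mm, 2-voxel warp
truth = template_truth(spec)
subject, st = make_phantom_subject(spec, age=40.0, subject_seed=7, truth=truth)

warp, _ = register_multichannel(subject.subset(["t2w", "odf"]),
                                st.clean.subset(["t2w", "odf"]),
                                RegistrationConfig())
brain = truth.labels["brain"]
err = np.linalg.norm(warp.vectors - st.warp.vectors, axis=-1)
print(f"mean endpoint error: {err[brain].mean():.3f} voxels "
      f"(uncorrected: {np.linalg.norm(st.warp.vectors, axis=-1)[brain].mean():.3f})")

centers = np.arange(37.0, 44.01, 0.5)
fit = fit_gompertz_series(centers, gompertz(centers, 0.45, 0.70, 1.0, 40.5)[:, None])
print(f"alpha={fit.alpha[0]:.3f} delta={fit.delta[0]:.3f} "
      f"gamma={fit.gamma[0]:.3f}/week tau={fit.tau[0]:.2f} weeks R2={fit.r_squared[0]:.4f}")
```

This prints:

```
mean endpoint error: 0.390 voxels (uncorrected: 0.702)
alpha=0.450 delta=0.700 gamma=1.000/week tau=40.50 weeks R2=1.0000
```

The registration reduces the mean misalignment inside the brain from
0.70 voxels to 0.39 voxels, and the noiseless growth-curve fit returns
the generating parameters exactly: the signal rises from 0.45 to 0.70
with peak growth at 40.5 weeks.

The same operations are available from the shell —
`mcatlas make-phantom`, `register`, `build-atlas`, `fit-gompertz`,
`evaluate-atlas`, `parcellate`, `roi-stats`, `associate` — each taking
NIfTI volumes, tab-separated manifests and a YAML config.

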