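# renoseg

Kidney ROI segmentation and relative renal function quantification for
⁹⁹ᵐTc-DMSA renal scintigraphy.

## The problem

Static DMSA scintigraphy measures each kidney's share of tracer uptake —
the *relative renal function* (RF). The clinical-routine estimate combines
anterior and posterior planar count images with a background subtraction
and a geometric-mean attenuation correction. That correction assumes both
kidneys sit behind the same tissue thickness with homogeneous attenuation;
for an **ectopic (pelvic) kidney**, photons traverse bone (iliac bone,
lumbar spine) and a different anteroposterior thickness, so the planar RF
is biased. `renoseg` implements the alternative: segment each kidney ROI
directly in tomographic slices and count the activity inside — no
background or attenuation correction needed — together with the planar
baseline, the agreement statistics to compare them, and a seeded phantom
generator that provides ground truth.

## The model

Segmentation works on a user-chosen half of the image domain: Φs (contains
the kidney) and its complement Φs̄, from which a background intensity
model D is estimated by kernel density estimation. A binary labeling
L : Φs → {0,1} defines a region E = {L=1} that should *match* the
background model; the kidney is what remains. The energy is

    C(L) = −B(P_E, D) + γ·E(L),      B(f,g) = Σ_z √(f(z)·g(z)),

with P_E the KDE of region E, B the Bhattacharyya overlap coefficient, and
E(L) an inverse-distance-weighted boundary-length prior over neighboring
pixel pairs. Starting from E⁰ = Φs, a modular auxiliary bound on C is
minimized exactly by a binary min-cut at each step (shrink moves only),
guaranteeing a monotone energy descent in a handful of iterations; the
kidney mask is Φs \ E_opt. RF is then the percentage split of in-mask
counts.

The planar baseline implements
`Q_BC = Q_b − N_Qb·(Q_F/N_QF)` (background) and the geometric-mean
attenuation correction `Q_AC = √(C_ant·C_post)·e^{μT/2}`, which is exact
under the symmetric exponential attenuation model; evaluation uses Dice /
Jaccard overlap and Bland–Altman / intraclass-correlation agreement
statistics.

## Worked example

```python
import numpy as np
from renoseg import PhantomSpec, make_slice, segment_kidneys, dice

spec = PhantomSpec.make("normal", seed=1)     # 128×128, contrast 3, Poisson
image, truth = make_slice(spec)
result, masks = segment_kidneys(image, "two_kidneys")
pred = masks["right"] | masks["left"]
print(f"iterations: {result.iterations}")
print(f"energy: {result.energy_trace[0]:.4f} -> {result.energy:.4f}")
print(f"dice vs truth: {dice(pred, truth['right'] | truth['left']):.4f}")
```

prints

```
iterations: 1
energy: -0.9375 -> -0.9580
dice vs truth: 0.9854
```

One bound/min-cut iteration (plus a short single-flip polish) lowers the
energy from −0.9375 to −0.9580 and recovers the two kidney masks with a
Dice overlap of 0.985 against the generator's ground truth.

The same flow from the shell:

```bash
renoseg phantom --preset ectopic --seed 7 --out ph/
renoseg segment ph/slice.png --mode both --out ph/mask.png
renoseg metrics ph/mask_right.png ph/truth_right.png
renoseg pipeline --preset ectopic --seed 7 --out run/
```

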