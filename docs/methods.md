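# Methods

## Segmentation model

A scan slice is a grid of non-negative emission counts I over a domain M.
The user's side choice ("left kidney", "right kidney", "two kidneys")
splits M by a straight line into Φs, the part to segment, and Φs̄ = M \ Φs,
assumed kidney-free. Single-kidney modes use a vertical line, two-kidney
mode a horizontal one; the default line is the image midline and an
explicit index overrides it. Display convention: images are row-major with
origin top-left, and the patient's left kidney renders on the viewer's
right; this is one module constant (`PATIENT_LEFT_ON_VIEWER_RIGHT`) so the
convention can be flipped globally.

The background model D is the kernel density estimate of the intensities
in Φs̄ on a shared binning: 256 equal-width bins spanning [min, max] of the
whole image (a constant image degenerates to a single bin). The kernel is
Gaussian with bandwidth σ (default: twice the bin width — mild smoothing
of Poisson count noise without erasing the kidney/background contrast) or
a Dirac kernel, which reduces the KDE to the normalized histogram. Because
a continuous-kernel estimate does not sum to 1 on a discrete grid, each
bin vector is renormalized to total 1, which keeps the Bhattacharyya
coefficient B(f,g) = Σ√(f·g) inside [0, 1] with equality at 1 iff the
distributions coincide bin-wise.

A binary labeling L on Φs defines E = {L = 1}, the region whose density
P_E should match D; its complement in Φs is the kidney. The energy is

    C(L) = −B(P_E, D) + γ · E(L),
    E(L) = Σ_{neighbors x,y in Φs, L_x ≠ L_y} 1/dist(x, y),

with 8-connectivity by default (axial pairs weigh 1, diagonal pairs 1/√2;
4-connectivity is available). Pairs with an endpoint outside Φs are
ignored, since L is only defined on Φs.

### Choice of γ

The matching term is bounded in [−1, 0], so one pixel's leverage on it is
O(1/|Φs|), while each cut neighbor pair contributes O(1) to E(L). A useful
trade-off therefore needs γ of order 1/|Φs|; the default is γ = 1e-4,
which on 128×128 inputs makes the per-pixel matching gain and the
per-pair smoothness cost comparable. Much larger values (γ ≳ 0.1) make
the boundary prior dominate and return the trivial all-background
labeling (empty kidney, flagged by a warning).

## Optimization

The minimization runs shrink-only bound optimization from E⁰ = Φs:

1. With κ_x = Σ_z K_z(I_x), n(z) = Σ_{x∈E} K_z(I_x), W = Σ_{x∈E} κ_x and
   the current B = Σ_z √(D(z)·n(z))/√W, each pixel of E gets the modular
   removal cost

       c_x = (3/(2√W)) · Σ_z √(D(z)/n(z)) · K_z(I_x) − B·κ_x/(2W),

   derived from the chord bound √(n−s) ≥ √n − s/√n and
   (1−t)^{−1/2} ≥ 1 + t/2 with the multiplier capped at 3/2. The
   resulting auxiliary objective upper-bounds C on every labeling
   reachable by 1→0 flips and equals C at the current labeling (both
   properties are verified by exhaustive enumeration in the test suite).
2. The auxiliary objective — modular costs plus the γ-weighted pairwise
   term — is minimized exactly by a binary s-t min-cut
   (`scipy.sparse.csgraph.maximum_flow`; float capacities are scaled into
   an int32-safe integer range, and the source-side partition is read off
   the residual graph by BFS, which makes tie-breaking deterministic).
3. The true C is re-evaluated after each cut; a move is only accepted if
   it does not increase C, so the energy trace is non-increasing by
   construction, and E only ever shrinks. Iteration stops when the cut
   changes nothing, the decrease falls below ε = 1e-6, or after max_iter
   = 50 accepted cuts (in practice 1–2 suffice on phantoms). If a cut
   would empty E, the single pixel with the best removal cost is
   retained.
4. A final greedy single-flip (1→0) descent polishes the labeling, so at
   convergence no single-pixel removal can strictly decrease C.

A reference path (`method="sweep"`) performs only the greedy single-flip
descent and is used by the enumeration oracles in the tests.

The kidney mask is Φs \ E_opt; connected-component post-processing keeps
the largest component (single-kidney modes) or the two largest, assigned
right/left by centroid column under the display convention.

### A note on the energy's global optimum

Because P_E is renormalized, B is invariant to the size of E: any subset
of Φs whose histogram is proportional to D attains B = 1. With γ > 0 the
*global* minimizer of C is therefore a degenerate near-singleton pure-
background region (tiny boundary, perfect match). The shrink descent from
E⁰ = Φs intentionally lands in the non-degenerate local optimum that
keeps all model-matching pixels; exact agreement with exhaustive
enumeration is hence only checked at γ = 0, where the clean background/
kidney split is a true global minimizer on separated two-valued
instances.

## Quantification

Planar route (clinical baseline):

* Background: Q_BC = Q_b − N_Qb·(Q_F/N_QF). The raw operation may return
  a negative value on noisy inputs; the report-level pipeline clamps it
  to 0 and records a warning.
* Attenuation: the default mode is the geometric-mean correction
  √(C_ant·C_post)·e^{μT/2}, which exactly recovers the emission count
  when C_post = C₀e^{−μd} and C_ant = C₀e^{−μ(T−d)} (the depth d
  cancels). A `literal` mode reproduces the routine formula as sometimes
  printed, C_ant·C_post·e^{μd}, for comparison only — it is dimensionally
  counts-squared. The default μ is 1.43 cm⁻¹ as used in the clinical
  formula it reproduces; note this is roughly an order of magnitude above
  soft-tissue attenuation at 140 keV (≈0.15 cm⁻¹, the value the phantom
  projector uses), and it is configurable everywhere.
* RF: each side's percentage of the summed corrected counts; the two
  sides always total 100 exactly.

Tomographic route (the proposed method): raw voxel counts inside the
segmented per-slice kidney masks, no further correction — segmentation
already excludes background, and the reconstruction is assumed
attenuation-compensated. Kidney depth can be estimated from a mask as the
center-of-mass slice index times the slice spacing (stack axis =
anteroposterior, slice 0 most posterior); phantom studies use
generator-supplied depths, as the estimate is a documented best effort.

## Statistics

Dice 2|A∩M|/(|A|+|M|) and Jaccard |A∩M|/|A∪M| score mask overlap
(J = D/(2−D) identically). Method agreement uses Bland–Altman bias and
bias ± 1.96·sd limits (sample sd), Pearson r with the OLS line, and the
two-way random-effects absolute-agreement ICC — single measures ICC(A,1)
and average measures ICC(A,2) — computed from ANOVA mean squares with
F-based 95% confidence intervals. Zero-total-variance input is flagged
degenerate and reported as 1. The Spearman–Brown ordering
(average ≥ single) holds whenever the single-measure estimate is
non-negative.

## Phantom generator

Phantoms emulate what the method needs from a DMSA scan and nothing more:
elliptical high-uptake kidneys (uniform rate) over uniform background,
independent Poisson counting noise, a 20-slice anteroposterior stack
(10 mm spacing, 20 cm body) with an elliptical axial profile centered at
each kidney's depth, and planar projections attenuated exponentially along
each kidney's anterior/posterior path. Presets:

* `normal` — symmetric orthotopic kidneys, depths 7/5 cm, contrast 3
  (background 50, kidney 150 counts/pixel);
* `ectopic` — right kidney pelvic, depth 9 cm, effective thickness 16 cm
  vs the global 20 cm, and a bone insert adding e^{−0.25·3} extra
  posterior attenuation; true split (45, 55);
* `hydronephrotic` — ectopic geometry with a cold-center annular uptake
  and a ×1.6 peri-kidney background patch (urine stasis).

Per-side uptake rates are rescaled so the *expected* in-mask counts
realize the requested RF split exactly, making the truth known without
simulation error; a `noise=False` mode returns expected counts for
closed-form tests (e.g. the geometric-mean round trip is exact to 1e-9).
All sampling flows from the spec's single integer seed.

What the phantoms do **not** model: scatter, collimator blur and
distance-dependent resolution, anatomical background structure, SPECT
reconstruction artifacts, or patient motion. Passing phantom studies
therefore demonstrates the correctness and internal consistency of the
energy, optimizer and quantification machinery — not clinical-grade
performance on real scans, where contrast is lower and background is
structured. The hydronephrotic preset in particular is adversarial by
design: the elevated peri-kidney patch differs from the background model
and partially merges with the kidney region, which is exactly the failure
mode the original imaging problem exhibits.

## Study sizes and numerical choices

The shipped studies use 50 phantoms per preset for segmentation quality
and 20 volumes per arm for the RF comparison — enough that the reported
means are stable to well under the tolerances asserted, while a full
acceptance run stays in the minutes range on one CPU. Convergence uses an
absolute energy decrease of 1e-6; min-cut capacity quantization is at
worst ~1e-9 of the largest capacity and every accepted move re-checks the
exact energy, so descent is never an artifact of scaling. Degenerate
inputs (constant images, empty regions, zero-count sides) raise typed
errors rather than returning silent defaults.
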