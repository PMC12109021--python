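# Methods

## Scope and flow model

The package characterizes a pressure-driven perfusion loop whose sample
chamber holds a ~1 cm³ tissue and whose working point is interstitial-flow
velocities (≈1–5 μm/s, Re ≪ 1). Three simplifications frame everything
downstream:

* flow is steady, incompressible, Newtonian and fully developed in the
  chamber; entrance/exit acceleration at the inlet/outlet orifices, the
  retaining posts and the porous chamber walls are not modeled;
* in the creeping regime the axial momentum balance is the Poisson
  problem μ(∂²u/∂y² + ∂²u/∂z²) = dp/dx with no-slip walls;
* the drive-pressure budget treats hydrostatic heads quasi-statically:
  ΔP = P_d + (P_hs,fresh − P_hs,waste), with each head change computed as
  ρ·g·(volume transferred / bottle cross-section), g = 9.80665 m/s².

## Units and fixed constants

SI internally; psi, μL/s and μm/s at the interfaces, with 1 psi =
6894.757 Pa. Perfusate defaults are serum-supplemented DMEM at
incubation temperature: ρ = 1009 kg/m³, μ = 9.30 × 10⁻⁴ Pa·s.

Two geometry values deserve comment because they are knowingly
inconsistent and kept so:

* **Cross-sectional area A_c = 2.37 × 10⁻⁴ m²** (config default). The
  bioreactor's flow cross-section is not directly printed anywhere; this
  value is back-derived from the characterized working point
  (0.40 μL/s ↔ 1.69 μm/s) and is settable in config. It is larger than
  the 10 mm × 10 mm tissue chamber; `ChannelGeometry.area_consistent`
  records whether width × height matches A_c.
* **Hydraulic diameter D = 0.435, unit tag "as-printed"**. Used as a
  meter-scale magnitude in Re = ρuD/μ because only that reading
  reproduces the reference Re = 0.80 at 1 psi; it is physically
  inconsistent with the ~1 cm chamber (geometric 4A/P ≈ 0.01 m). The
  explicit tag keeps the choice visible rather than silently baked in.

Published flow tables for this class of system also mix two Reynolds
conventions between rows (mean-velocity at 1 psi, peak-velocity at 2–3
psi). The implementation computes Re from u_avg as the formula states and
additionally carries `Re_from_umax` in every output row so the
discrepancy is reported rather than resolved silently.

The peak-velocity column defaults to the circular-pipe convention
u_max = 2·u_avg (`table1` mode) because that is how such tables are
printed; `rect-duct` mode instead applies the computed duct ratio
(≈ 2.096 for a square chamber). SDs propagate through these linear scale
factors only — no higher-order error propagation is attempted, matching
how ± columns in bench tables scale.

## Duct profile solvers

**Series.** The classical solution over 0 ≤ y ≤ L_y, 0 ≤ z ≤ L_z,

u(y,z) = Σ_m Σ_n 16(−dp/dx)/(μπ⁴ · mn(m²/L_y² + n²/L_z²)) · sin(mπy/L_y) sin(nπz/L_z),

summed over odd m, n. "First 15 terms" is read as the first 15 odd
indices **per axis** (225 products); a `radial` ordering (15 pairs of
smallest m² + n²) exists for sensitivity analysis, since a double sum has
no canonical single-index ordering. At 15 terms/axis the square-duct peak
is converged to <10⁻⁴ relative — the truncation is not the accuracy
bottleneck.

**Finite-difference oracle.** The same Poisson problem on the same node
grid, 5-point Laplacian, solved directly (sparse LU) below 200 points per
axis and by conjugate gradients above, with the residual verified against
10⁻¹⁰·‖b‖ in both paths. It plays the role a full CFD run plays at the
bench: an independent numerical check on the analytical profile. The two
solvers agree to <10⁻³ of the peak on a 257² square-duct grid; the
agreement metric is normalized by the peak velocity because pointwise
relative error is ill-conditioned in the near-wall layer where u → 0.

**Back-calculation.** The problem is linear in dp/dx, so the gradient
producing a target u_max is obtained exactly by rescaling a unit-gradient
solution; the round trip is exact to solver precision by construction.
Returned gradients are negative (pressure falls along the flow).

**Wall shear stress.** τ_max = μ·max|∂u/∂n| over the four walls,
estimated by second-order one-sided differences on the solved grid
(≥33 points/axis enforced). The parallel-plate closed form 6μV/(L_y·L_z²)
is attached as a cross-check: the two agree within ~5% for wide ducts
(verified at 20:1 aspect ratio) but the closed form underestimates a
square duct's τ_max by ~36%, so it is never substituted for the
derivative estimate.

## Patch image quantification

Manual outlining in an image editor is replaced by a deterministic
surrogate: 3-class multi-Otsu thresholding (background/holes ∣ matrix ∣
spheroids), 8-connected labeling, and physical-unit minimum-area filters
(spheroids: 100 μm-diameter disc equivalent; holes: 50 μm). Choices that
keep the metrics well-defined:

* the **matrix** is the largest connected above-low-threshold component
  with interior dark regions filled, so "matrix area" means the area the
  gel originally covered;
* **holes** are dark regions strictly inside that mask; dark regions
  8-adjacent to anything outside the mask are edge indentations and are
  excluded, as are segmented spheroid pixels;
* **spheroid centers** are intensity-unweighted centroids, mirroring
  manual center-picking;
* pixel size is required metadata — nothing is inferred from the image.

Areas scale as pixel² and distances as pixel, verified by re-quantifying
2×-downsampled scenes.

## Viability gating and statistics

The dead threshold is the 1% empirical quantile (configurable) of the
ethanol-killed control's intensities, so ≥99% of the control is dead by
construction; events strictly below the threshold are live. The gate is
invariant under any strictly increasing rescaling applied jointly to
control and sample. Scatter-based doublet/debris exclusion is out of
scope — synthetic events are pre-filtered singlets.

Group tests use Welch's unequal-variance form with Welch–Satterthwaite
degrees of freedom (fractional df is what replicate-level viability
comparisons report); a pooled-variance Student variant sits behind a
flag. `welch_from_samples` is definitionally `welch_from_summary` on the
sample means and n−1 SDs, and both are cross-checked in the tests against
an independent scipy route.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed) and always emit ground
truth; recovery tests compare against that truth, not against any
biological claim.

* **Flow replicates**: zero-truncated Gaussians at the per-pressure
  mean ± SD of the characterized system (0.40 ± 0.19, 0.81 ± 0.0083,
  1.1 ± 0.040 μL/s), converted to scale masses via m = V·ρ·t with longer
  collection times at lower pressures.
* **Patch scenes**: an 8 mm circular matrix at 10 μm/pixel with bright
  ~500 ± 50 μm spheroids and dark holes totaling a configured fraction of
  the matrix area. Spheroids sit on a jittered triangular lattice whose
  pitch is the target mean spacing. A hard-core dart-throwing process was
  considered and rejected: the studied 24 h spacings (457 μm mean NN for
  ~500 μm spheroids) are at/below contact distance, which no hard-core
  Poisson process reaches at any density, whereas a lattice reaches
  near-touching spacing naturally. Non-overlap is then preserved by
  capping radii pairwise to keep a ≥3-pixel rendered gap (so
  segmentation cannot merge neighbors). The ground-truth hole fraction is
  the class-map fraction (hole pixels over matrix-footprint pixels),
  which is exactly what the quantifier is asked to recover. Scenario
  presets carry the studied group means (33.39% / 10.74% degraded;
  514.52 → 457.41 μm perfused, 530.85 → 655.32 μm static).
* **Degradation series**: hole areas grow geometrically per hour (capped
  at the matrix border and at 60% of matrix area; grown holes may merge,
  as tears do), spacing drifts linearly by rescaling positions about the
  patch center, and spheroids overtaken by a hole drop out of later
  frames — emulating spheroids falling out of the degraded gel.
* **Cytometry**: two log-normal intensity populations (live median 120,
  dead median 3000, σ = 0.4 in log space — log-normal being the
  conventional shape for fluorescence), with the killed control drawn
  entirely from the dead distribution.

None of this emulates real microscopy optics (no point-spread function,
no illumination gradients, no out-of-focus light) or real cytometry
artifacts (spillover, debris). Passing recovery tests therefore show the
*analysis* is correct and well-conditioned on clean trimodal images and
separated populations — not that it is robust to arbitrary real-world
image quality, where the overridable thresholds exist for a reason.

## Problem sizes and numerical defaults

Defaults used throughout the tests and the reproduction script: 101–257
grid points per axis for profiles (257² for the solver-agreement check),
1024² px patch frames with 40 spheroids, 10⁴ cytometry events with a
5×10³-event control, and three seeds for image-recovery checks. These
sizes put every quantity well inside its tolerance while keeping a full
run in seconds. Degenerate inputs are defined, not special-cased:
constant images yield zero spheroids and a full-frame matrix, a zero
pressure gradient yields an identically zero profile, a single replicate
reports SD 0 with an explicit flag, and equal groups give t = 0, p = 1.

## Known limitations

* The hydrostatic-sensitivity figure (psi per mL transferred) depends on
  bottle cross-sections, which are not part of the characterized
  system's public record; the budget reports the sensitivity for given
  areas rather than asserting any negligibility bound.
* τ_max has no published reference value for this system; it is
  validated only internally (grid refinement + wide-duct closed form).
* Welch df computed from summary statistics inherits the rounding of the
  printed SDs; see the test docstrings for where this bites at the
  fourth significant figure.
* The image pipeline assumes one connected matrix region per frame and
  single-channel input; multi-patch frames and stain-specific channel
  handling are out of scope.
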