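# Methods

`crownarch` turns per-tree airborne laser scanning (ALS) point clouds into
structural feature parameters, classifies tree species from them, and maps
each classified species onto one of four Hallé architecture models (HAMs)
— qualitative archetypes of trunk/branch organization and growth rhythm
(Massart, Rauh, Roux, Attim).  This note records the models, the
operational definitions, the numerical choices, and what the synthetic
test stands do and do not establish.

## Geometric scaffolding

**Stem axis.**  The first principal axis of the returns in the lowest 25%
of the height range, re-oriented upward.  If it tilts more than 30° from
vertical — typical when the lower crown rather than the trunk dominates
the slab — the estimate falls back to the vertical line through the
horizontal centroid (logged).  The crown frame then works with the
*vertical* line through the estimated stem footprint: extrapolating a
noisy PCA direction over a 20 m crown amplifies a degree of direction
error into metre-scale axis offsets, which corrupts every radius-based
parameter.

**Crown base.**  Automatic density scan: the lower edge of the lowest
0.5 m height slab whose return count reaches 5% of the maximum slab count,
scanning upward, with an absolute floor of 2 returns (a single return is
never evidence of crown; without the floor, the relative threshold
collapses below one count on sparse clouds and stray stem hits capture the
base).  A manual override is available for segmented data with known
bases.

**Voxels, sectors, layers.**  Crown returns (z at or above the crown
base) are binned into cubic voxels, default edge 0.5 m — half the 1 m
super-voxel used for the concentration parameter, adequate for
~10 points/m² data.  Bins are half-open `[min, max)` and the grid is
anchored at the crown's minimum corner (configurable `grid_origin` for
cross-tree-comparable or symmetric grids).  Occupied voxels are
partitioned into 8 azimuthal sectors around the stem axis (sector 1 =
[0°, 45°) from east, counter-clockwise) and into `n_layers` (default 8)
equal-thickness vertical layers; layer membership is clipped into range so
layer counts always sum to the occupied-voxel total.

**Volumes.**  The 3-D alpha shape is the union of Delaunay tetrahedra
with circumradius ≤ α (α = ∞ recovers the convex hull; coplanar input
yields volume 0 with a warning).  This construction is implemented
directly on `scipy.spatial.Delaunay`.

## Crown-internal (CI) parameters P1–P13

Heights that are normalized by the crown length Lc are measured from the
crown base, so the ratios land in [0, 1].  All spreads are population
(n-denominator) standard deviations.

- **P1 / P2** — mean over the 8 sectors of the sector's mean voxel-centre
  height (above crown base) / Lc, and mean distance to the axis / crown
  radius Rc.  Empty sectors are excluded from the outer mean (logged).
- **P3** — projected convex-hull area of the lower-third returns over the
  whole-crown projected area; 0 when fewer than 3 such returns.
- **P4** — largest fraction of crown returns inside any 1 m super-voxel
  (point fraction, not sub-voxel occupancy: observed values 0.1–0.25 are
  incompatible with the eighth-multiples occupancy would force).
- **P5 / P6** — population sd of the 8 per-sector values entering P1/P2.
- **P7** — occupied voxels inside the *stem space* (height ≤ Lc/3 and
  axis distance ≤ Rc/2, i.e. a cylinder of half the crown radius) over all
  occupied voxels.
- **P8** — whole-crown voxel-centroid height / Lc (a single centroid,
  deliberately distinct from P1's mean of sector means).
- **P9 / P10** — population sd of per-layer occupied-voxel counts, and
  the summed absolute adjacent-layer differences over the voxel total.
- **P11** — alpha-shape volume (α = 0.5 m) over convex-hull volume.
- **P12** — Σ₄ Cor(Sᵢ, Sᵢ₊₄) / Σ₈ Cor(Sᵢ, Sᵢ₊₁): opposite-sector over
  adjacent-sector Pearson correlation of per-layer voxel-count profiles; a
  zero-variance profile contributes 0 (logged); a vanishing denominator
  yields 0 with a warning.
- **P13** — P5/P6; when P6 ≤ 1e-9 (perfectly regular crowns) the value is
  the sentinel 0 with `p13_sentinel` set, rather than a crash or NaN.

## Tree-external (TE) parameters

- **Ht** = max(z) − DTM; **LcHt** = Lc/Ht; **LcD_EA** = Lc/D_EA.
- **D_EA** = 2·√(A_base/π): the diameter of the circle whose area equals
  the projected crown cover (the definition forces the 1/π).
- **Alpha** — least-squares fit of exp(−(h−u)²/2α²) to the per-layer
  point-count profile normalized to max 1.  A free amplitude (≈1 at the
  optimum) absorbs the sampling noise of the single peak bin, which would
  otherwise bias α ~10% low on 1,000-point histograms.  The fit uses
  Levenberg–Marquardt with the analytic Jacobian plus a Gauss–Newton
  polish of the stationarity condition (the surface is flat in α, so
  step-based stopping alone leaves ~1e-7 slack); non-convergence falls
  back to the profile's second moment with a warning.
- **llls_lhls_proxy / ls_lcs_proxy** — profile landmarks: the heights of
  the lowest/highest local maxima of the 3-bin-smoothed vertical density
  profile, and the relative height of the maximum-density layer.  The
  `_proxy` suffix marks them as package-defined operationalizations of
  qualitative "main part of growth" descriptors; both accept user-supplied
  landmark heights.
- **Gc** — mean occupied-voxel-centre height above ground.
- **P_L / LAI_proj** — occupied-cell area of a 0.5 m projection grid over
  the projected convex-hull area, averaged over the XZ and YZ planes
  (P_L), or on the XY plane (LAI_proj).  Cells straddling the hull rim can
  push the ratio marginally above 1 at coarse grids; `LAI_proj` is a
  projected coverage fraction, not a radiative-transfer leaf area index.

## Classification

A Wilks'-lambda MANOVA (Rao's F approximation, computed in-package so
that a singular within-class scatter can be retried with a 1e-8 ridge on
the SSCP diagonal) is reported as a gate on class separability; it warns
when p ≥ 0.05 or when underdetermined, and never blocks the pipeline.

Classification is a leave-one-out cross-validated SVM: per fold, features
are z-scored on the training trees only (no leakage), an RBF kernel with
C = 1 and γ = 1/#features (one-vs-one multi-class) is trained, and the
held-out tree predicted.  Hyperparameters are fixed rather than tuned per
subset: the exhaustive search evaluates up to 8,191 subsets and per-subset
tuning would multiply runtime while undermining comparability.  Rows are
canonically sorted internally, so reports are row-order independent.

The exhaustive subset search evaluates every unordered subset of the
requested sizes (counts equal binomial coefficients by construction); ties
between equal-accuracy subsets break towards the smaller subset, then
lexicographic column order.  Accuracy metrics: per-class recall and
precision, overall accuracy, and Cohen's κ = (p_o − p_e)/(1 − p_e).  Note
that a *consistent relabeling* (off-diagonal permutation confusion) is
total disagreement under this formula (κ ≤ 0); only diagonal confusions
score 1.  R²/RMSE follow the estimation-vs-reference convention: RMSE is
the root mean squared deviation, R² is computed against the OLS
regression of estimates on references about the estimate mean.

## Architecture-model identification

Identification is per species, not per tree: the centre (arithmetic mean)
of a species' distribution over a feature pair — default (P4, P7),
concentration vs stem-space occupancy — is compared with packaged
prototype centres.  The knowledge base (`data/ham_knowledge.yaml`) is an
expert input, not a fitted constant: prototypes encode the qualitative
low/moderate/high positions of the four models (Massart low P4 low P7,
Rauh high P4 low P7, Roux moderate P4 low P7, Attim low P4 high P7) at the
magnitudes typical of boreal crowns.  The default rule assigns the
nearest prototype after per-axis min–max scaling over the prototypes
(hence invariant to affine rescaling of either axis).  A strict quadrant
rule with user cut lines is also available, but three of the four models
sit at low P7, which a 2×2 quadrant layout cannot express — hence nearest
centre as the default.  Two species→model readings circulate for these
four boreal species and they disagree; the knowledge file records both
(`species_links: narrative / habit_table`) without silently reconciling
them.

The Gaussian divergence summary fits μ (mean) and σ (population sd) per
species × parameter on the predicted-label group (DP) and the true-label
group (GT), reporting Δμ% = (μ_GT − μ_DP)/μ_GT·100 and the analogue for
σ.  The sign convention is GT-minus-DP over GT, fixed and documented
here.  With small species groups and small σ values, a single
misclassified tree can produce large Δσ%; the summary is a transparency
instrument, not a bounded score.

## Synthetic stands

The generator exists so every stage is testable without field data.  Four
point-placement recipes emulate the archetypes' structural signatures:
tiered annular whorl discs in a conical envelope (Massart-like, spruce,
PA), tight off-axis upper-crown clusters over a short crown fraction
(Rauh-like, pine, PS), small branch tufts spread uniformly over the crown
height plus a thin populated stem sleeve (Roux-like, aspen, PT), and
near-uniform clumpy columnar fill (Attim-like, oak, QR).  Heights and
crown lengths are drawn from species-typical boreal ranges (spruce
17.6–28.4 m tall with crowns 14.0–27.4 m, pine 16.7–23.7 / 5.7–18.8,
aspen 20.4–26.0 / 11.6–20.1, oak 15.2–25.9 / 13.8–18.9); crown radii are
realistic choices (spruce 2.0–3.5 m through oak 3.0–5.0 m) since the
reference ranges cover only height and crown length.  Clouds are thinned
by Poisson subsampling over the projected-crown hull to ~10 points/m²,
given 0.1 m Gaussian noise, and accompanied by a sparse line of
under-crown stem returns.  The default stand is 9 PA / 14 PS / 7 PT /
10 QR = 40 trees.

Design details that matter and why:

- branch clusters/clumps sit at *balanced azimuths* around the trunk
  (phyllotactic balance); one-sided clusters would drag the centroid
  fallback of the axis estimator into the crown and corrupt radii;
- cluster extents are bounded (uniform, not Gaussian, in z for the pine
  tufts) so the crown top does not creep upward with sampling density;
- randomness is split into geometry/structure, crown-return and
  stem-return substreams, so one seed yields the same tree geometry at
  any sampling density (used by the density-stability tests);
- recipe geometry was calibrated, as a design step, until each archetype
  expressed its intended qualitative (P4, P7) signature at boreal
  magnitudes with multi-sigma species-centre margins to the prototype
  decision boundaries.

What the synthetic stands do **not** establish: they contain no occlusion,
no multi-return physics, no beam divergence, no understory or neighbouring
crowns, and their archetype separation is cleaner than real conspecific
variation.  Passing the closure tests shows the pipeline is internally
consistent and recovers planted structure; it does not certify real-data
accuracy.

## Problem sizes and tolerances

The test suite runs stands of 40 trees (~150–700 returns each) over 5
seeds for pipeline closure, 12 trees per archetype for density-stability
checks, 200 replicates for the MANOVA null calibration, and 1,000-point
profiles (5 replicates, mean) for Gaussian-spread recovery — the mean is
asserted within 5% because the Fisher bound for a Gaussian σ at n = 1,000
is a 2.2% relative sd, so a single draw cannot honestly meet 5% at every
seed.  Feature-oracle equivalence against the brute-force reference is at
1e-9 on a fixed 18-point cloud.  Degenerate inputs (coplanar volumes,
empty sectors, zero-variance profiles, constant columns, single-member
classes) warn or raise as documented above; none produce silent NaNs.

## Known limitations

- LAS support is a minimal uncompressed LAS 1.x reader (coordinates
  only); LAZ must be decompressed externally.
- The crown-base scan assumes an isolated, segmented tree; plot-level
  segmentation is out of scope.
- `Alpha` fits a single Gaussian; strongly bimodal crowns are summarized
  by their envelope width.
- The quadrant assignment rule is only meaningful for feature pairs with
  a genuine 2×2 prototype layout.
- Per-tree (rather than per-species) architecture assignment is out of
  scope, as are the remaining nineteen models of the full architecture
  scheme.
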