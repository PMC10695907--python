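# Methods

## Analysis model

A specimen is a connected bright phase in a darker background on an
isotropic voxel grid in `(z, y, x)` order. The analysis assumes (i) the
contrast between tissue and background is large against the noise (the
generator enforces contrast ≥ 6 noise SD, and segmentation quality is
validated at contrast-to-noise 30), (ii) voxels are isotropic, so a single
edge length parametrizes all geometry and the cubic structuring element is
meaningful, and (iii) each specimen is a single connected object.

### Segmentation

Region growing uses a *fixed* acceptance band: the mean μ and SD σ of the
`(2r+1)³` neighborhood around the seed define `[μ − kσ, μ + kσ]`, computed
once; the specimen is the connected component of in-band voxels containing
the seed. A fixed band makes the result deterministic and independent of
visit order, which adaptive-mean growing is not. With σ = 0 the band
degenerates to exact-value matching, which is well defined and occasionally
useful on noiseless data. Defaults: `tolerance_k = 3.5` (covers > 99.9% of
Gaussian-distributed tissue intensities, so in-tissue dropouts are rare,
single-voxel, and largely repaired by the closing step downstream),
`neighborhood_radius = 2` (125 voxels — enough for a stable SD estimate),
connectivity 26 (solid tissue should not fragment at corner contacts),
`min_component_voxels = 27` (drops sub-kernel speckle when labeling). A
seed whose neighborhood is truncated by the volume border is rejected
rather than padded: border statistics would be biased.

### Integrity ratios

All morphology is binary, with the full 27-voxel cube as the default
structuring element. Masks are padded with background on all faces before
each operation and cropped back, so the grid border behaves as open space:
dilation can grow outward and is then cropped, erosion sees background
beyond every face, and hole filling treats any background path to the
border as "open to the exterior". Biopsies are interior objects, so this is
the physically sensible convention; it also makes closing/opening exactly
idempotent, which the test suite asserts.

- *Inner integrity* = `n_seg / n_filled_inner` with the denominator from
  closing (one iteration) then hole filling, i.e. the specimen with all
  internal ruptures repaired: the closing seals cracks narrower than the
  kernel, hole filling fills every remaining enclosed void. The hole-fill
  step uses 6-connected background — the dual of 26-connected foreground —
  so voids cannot "leak" to the exterior through a diagonal gap.
- *Outer integrity* = `n_smoothed / n_filled_outer`: holes are filled
  first so internal damage cannot contaminate the surface measure, then one
  opening removes protrusions thinner than the kernel. Both ratios are
  oriented the same way (≤ 1, higher is better) so the two scales read
  identically. A specimen removed entirely by the opening reports outer
  integrity 0 with a warning flag rather than an error.
- *Volume* = `n_seg · a³ · 10⁻⁹` mm³ for voxel edge `a` in µm.
- *Compression* = median of the per-observer ordinal scores; for an even
  observer count the lower median is taken so the aggregate remains an
  attainable ordinal value. The protocol this models uses three observers.

### Group statistics

The Mann–Whitney U statistic is computed from midranks. The exact two-sided
p-value doubles the smaller of the two observed tails of the permutation
distribution, capped at 1. With ties the permutation distribution is *not*
symmetric, so both tails are evaluated directly; for tie-free data this
reduces to the textbook symmetric rule. The null distribution of the
rank sum is obtained by subset-sum dynamic programming over the doubled
midranks (doubling makes them integers), which is exact and cheap for any
case the enumeration cap admits; the cap (default 200,000 assignments,
C(24, 6) = 134,596 included by design) decides when the tie-corrected,
continuity-corrected normal approximation is used instead. If the
tie-corrected variance is zero (all pooled values identical) p = 1.
No multiple-testing adjustment is applied across the four features; the
per-feature p-values are reported as-is, which is a caveat for any formal
error-rate claim.

Set poolability is decided per feature by pairwise Mann–Whitney tests
between repeated acquisition sets within each group; any rejection at α
vetoes pooling. With several pairwise tests at α = 0.05 an occasional
false veto on truly poolable sets is expected (family-wise error ≈ 14% for
three sets); the decision record carries all p-values so this is auditable.

Cutting success is the per-animal percentage of cutting manoeuvres that
yielded a biopsy, summarized as mean ± sample (n−1) SD across animals;
procedural success is the percentage of animals with ≥ 6 biopsies and no
major complication.

## The phantom generator

The generator emulates what a bioptome does to tissue as seen by high
resolution µCT: an ellipsoidal specimen body; enclosed ellipsoidal voids
(rupture); planar slits of 1–2 voxels (thin cracks, designed to be sealed
by the 3×3×3 closing); one-voxel-thick axis-aligned surface spikes
(coarseness); spherical intensity boosts (pinch foci — grayscale only, the
mask is unchanged); then Gaussian noise. Intensities default to background
50, tissue 200, noise SD 5 on an 8-bit-like scale; only the
contrast-to-noise ratio of 30 matters.

Two choices make the analytic truth exact rather than approximate:

- The body is regularized at rasterization by one opening-of-closing with
  the default kernel. The body is then morphologically open and
  closing-neutral at the kernel scale, so on a defect-free phantom closing
  and opening change *nothing* (the identity tests assert exact equality),
  and on a defective one the measured deviations are attributable entirely
  to the designed defects.
- Defect voxel counts are taken from the actual rasterization, not from
  continuous-volume formulas, so overlaps and discretization are counted
  exactly. The expected inner integrity is `T / (T + V + C)` (tissue, wide
  voids, thin cracks): the cracks are closed by the kernel and therefore
  enter the repaired denominator exactly like voids do. Voids narrower
  than the kernel half-width are rejected as voids (they would be partly
  sealed by closing, breaking exactness) and must be modelled as cracks.

Cohort presets draw per-specimen parameters from damage profiles: the
gentle profile (control-like and B1-like: at most one small void, 0–1 short
spikes, 0–1 pinch foci; B1-like bodies are drawn larger) and the crushing
profile (B2-like: 2–4 voids of semi-axes 2.5–4.5 voxels, 1–2 cracks, 25–40
spikes of length 4–8, 1–2 pinch foci, same central body size as control but
wider spread). Specimen `i` of a cohort is generated entirely from seed
`base_seed + i`. Observer compression scores are simulated as the designed
severity (pinch count capped at 2) with 10% per-observer disagreement of
one level either way. The segmentation seed supplied with each phantom is
the tissue voxel deepest from any background (chessboard distance
transform, first maximum in C order) — deterministic and guaranteed clean
neighborhood statistics.

What the phantoms do *not* emulate: phase-contrast fringes, ring and
beam-hardening artifacts, myofiber texture, partial-volume gradients at the
tissue boundary, irregular (non-ellipsoidal) specimen shapes, and
observer behaviour beyond the simple disagreement model. Passing the
phantom suite therefore demonstrates that the measurement chain recovers
known structure under realistic contrast and noise — not that segmentation
parameters are optimal for any particular beamline's data. On real data the
region-growing tolerance, connectivity and kernel remain config knobs to be
set against expert segmentations.

Phantom grids default to 72×56×56 voxels with bodies of semi-axes roughly
24×14×14 voxels (≈ 2×10⁴ tissue voxels). These sizes keep the bundled demo
(42 specimens) and the 100-phantom validation suites comfortably fast while
leaving every feature several kernel widths large; all geometry is
specified in voxels, so conclusions transfer to larger grids unchanged.

## Degenerate inputs and tie-breaks

- Component labels are ordered by decreasing voxel count, ties broken by
  the lexicographically smallest `(z, y, x)` member voxel.
- Empty masks are errors for both integrity ratios (undefined), identity
  for morphology.
- Integrity ratios are undefined for empty masks; `outer = 0` plus a
  warning flag for masks annihilated by opening.
- Exact p-values on completely tied data return 1 in both branches.
- Region growing always includes the seed voxel, even if the fixed band
  excludes its intensity (possible when the neighborhood is heterogeneous).

## Known limitations

- The compression feature is observer-based by design; only aggregation is
  implemented, not automated pinch detection from density.
- Anisotropic voxels and grayscale morphology are out of scope.
- The in vivo success-rate records bundled with the package are synthetic
  (see `data/invivo_records_synthetic.csv`): plausible per-animal counts
  used to exercise the count arithmetic and the demo report, not
  measurements.
- The exact-test DP cost grows with the doubled-rank total; the assignment
  cap keeps the automatic branch well below a second, but a forced
  `method="exact"` on large samples is the caller's responsibility.
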