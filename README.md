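# biopsy3d

3D structural quality analysis of endomyocardial biopsy specimens from
volumetric grayscale imaging (e.g. synchrotron micro-CT at 2 µm isotropic
voxels).

Endomyocardial biopsies are millimetre-scale myocardial samples cut by a
forceps-tipped catheter (a *bioptome*). How gently a bioptome cuts shows up
in the 3D structure of the retrieved tissue: internal cracks and voids,
surface coarseness from the expulsion of the forceps, and dense "pinch"
foci (crush artefacts) at the contact sites. This package quantifies those
features per specimen and compares bioptome designs statistically — the
kind of analysis used to vet new MR-compatible bioptome prototypes against
a conventional clinical device.

## What it computes

For each specimen segmented from a grayscale volume (seeded region growing
with a fixed intensity band μ ± kσ estimated at the seed):

- **Volume** — `n_seg · a³` mm³ for voxel edge `a` (2 µm by default, so
  each voxel is 8 µm³).
- **Inner integrity** — `n_seg / n_filled_inner`, where the denominator is
  the voxel count after a 3×3×3 morphological closing (one iteration)
  followed by hole filling. Internal ruptures lower the ratio; 1 means no
  inner damage.
- **Outer integrity** — `n_smoothed / n_filled_outer`: the mask is
  hole-filled (so inner cracks cannot contribute), then surface-smoothed by
  a 3×3×3 opening. Surface protrusions and coarseness lower the ratio;
  1 means a smooth, cleanly cut surface.
- **Compression score** — the median of three observers' ordinal 0/1/2
  crush-artefact ratings.

Groups are compared per feature with a two-sided Mann–Whitney U test
(exact permutation distribution via rank-sum dynamic programming whenever
the assignment count permits, otherwise a tie-corrected normal
approximation with continuity correction). Helpers check whether repeated
acquisition sets may be pooled, and summarize in vivo procedural success
(≥ 6 biopsies per animal without major complication) and cutting success
(biopsies per cutting manoeuvre).

Because real bioptome-validation volumes are not generally available, the
package includes a phantom generator that rasterizes biopsy-like specimens
(ellipsoidal body, enclosed voids, thin cracks, one-voxel spikes, pinch
foci, additive Gaussian noise) with *exact* analytic ground truth for every
feature, plus group presets with designed damage contrasts for end-to-end
validation.

## Worked example

```sh
biopsy3d demo --out demo_out --base-seed 42
```

generates 18 "B1-like" (gentle cutter), 18 "B2-like" (crushing cutter) and
6 control-like phantoms, segments and measures each, and prints:

```text
per-group medians:
       volume_mm3  inner_integrity  outer_integrity
group
B1       0.000185         0.996779         0.999800
B2       0.000131         0.958139         0.989017
CN       0.000129         0.995176         0.999774
group comparisons vs control:
          feature group_a group_b  n_a  n_b  u_statistic  p_two_sided method  tie_corrected
       volume_mm3      B1      CN   18    6        108.0     0.000015  exact          False
compression_score      B1      CN   18    6         66.0     0.640405  exact           True
  inner_integrity      B1      CN   18    6         63.0     0.580522  exact          False
  outer_integrity      B1      CN   18    6         53.0     0.974442  exact           True
       volume_mm3      B2      CN   18    6         51.0     0.871170  exact          False
compression_score      B2      CN   18    6         98.0     0.000981  exact           True
  inner_integrity      B2      CN   18    6          0.0     0.000015  exact          False
  outer_integrity      B2      CN   18    6          0.0     0.000015  exact          False
```

Reading: the gentle design (B1) produces larger specimens (volume p ≪ 0.05,
U = 108 = complete separation above control) but is indistinguishable from
the control on compression, inner and outer integrity. The crushing design
(B2) matches control volume but scores significantly worse on compression
and both integrity ratios — its median inner integrity 0.958 means ~4% of
the repaired specimen volume was internal rupture. All eight tests used the
exact permutation branch (C(24, 6) = 134,596 assignments).

Other subcommands: `generate` (phantom cohorts as TIFF + truth JSON +
manifest), `measure` and `run` (YAML-configured pipelines over generated or
on-disk volumes), `compare` (group statistics from a feature CSV). Every
analysis parameter (region-growing tolerance, connectivity, structuring
element, exact-test cap, α) is an explicit config knob; `run.log` records
the voxel count at every morphological stage so any ratio can be
hand-verified.

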