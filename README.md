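# fiberalign

Local alignment vectors for quantifying fiber orientation order in
spatially heterogeneous fiber networks — e.g. collagen imaged by second
harmonic generation (SHG) microscopy around an invading tumor spheroid.

A single, global orientation statistic averages away exactly the structure
that matters in such images: fibers radiating from a spheroid are highly
ordered everywhere locally, yet nearly cancel globally. `fiberalign`
implements the local alignment vector method: extracted fiber polylines are
cut into equal-arclength segments, a grid of local sampling circles is laid
over each image slice, and within each circle the segment orientations
α ∈ [0°, 180°) are summarized by circular statistics on doubled angles:

- double each axial angle, θ = 2α;
- take the mean resultant vector MRV = (1/N) Σ (cos θᵢ, sin θᵢ);
- halve the MRV's angle, keep its length.

The resulting **alignment vector** has length in [0, 1] (1 = perfectly
aligned, 0 = isotropic) and an axial angle giving the dominant fiber axis.
Its length equals the 2-D nematic orientational order parameter μ — the
maximal eigenvalue of A = [[⟨cos 2α⟩, ⟨sin 2α⟩], [⟨sin 2α⟩, −⟨cos 2α⟩]] —
which the package computes independently (by eigendecomposition) as a
cross-check. Cells whose circle crosses the image border or the tumor
boundary, or holds too few segments, are excluded; the valid cells of a
z-stack are pooled into alignment distributions, the mean alignment, and
the strong-alignment ratio (fraction of cells above a threshold, default
0.7).

The package is for quantitative microscopists and mechanobiologists who
have per-fiber vertex output from extraction software (e.g. CT-FIRE) and
want spatially resolved order parameters; it also contains the in-silico
fiber generators used to validate the statistics on known ground truth.

## Worked example

From Python — three fibers at 30°, 40°, 50°:

```python
>>> import fiberalign as fa
>>> v = fa.alignment_vector([30.0, 40.0, 50.0])
>>> round(v.length, 4), round(v.axial_angle, 4)
(0.9598, 40.0)
>>> round(fa.orientational_order_parameter([30.0, 40.0, 50.0]), 4)
0.9598
```

The three orientations spread ±10° about 40°, so the alignment vector
points along 40° with length just under 1; the order parameter computed via
the orientation tensor agrees exactly. Two perpendicular fibers
(`[45.0, 135.0]`) give length 0: no axis dominates.

From the shell — simulate fibers radiating from a quarter-circle tumor
boundary, then analyze them:

```sh
$ fiberalign simulate-radial --seed 2 --out fibers.csv --boundary-out boundary.csv
wrote 500 fibers to fibers.csv
$ fiberalign analyze --fibers fibers.csv --boundaries boundary.csv --out-dir results
mean alignment 0.9974, strong ratio 1.0000 (6263 valid cells); outputs in results
```

The 512×512 grid holds 10,609 sampling positions; 6,263 survive the
image-border, tumor-boundary and minimum-fiber exclusions, and at zero
angular noise essentially every local circle sees perfectly ordered radial
fibers — mean alignment 0.997, strong-alignment ratio 1.0. The global
alignment of the same fibers is only ≈ 0.64 (orientations 0°–90° partially
cancel), which is precisely the failure of global averaging the local
method fixes. `results/` contains the per-cell vector-field table, the
normalized alignment distribution, and a JSON summary; add `--plot` for
quiver and 3-D figures, and see `fiberalign sweep` for the sampling-circle
radius sweep.

Fiber tables are plain CSV (`fiber_id, z_index, vertex_index, x, y`, one
row per vertex); `fiberalign.io.read_ctfire_mat` imports CT-FIRE MAT files
into the same form.

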