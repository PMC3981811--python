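# tubequant

Automated, label-free quantification of endothelial **tube-formation-assay
(TFA)** images.

Endothelial cells plated on Matrigel self-organize into capillary-like tube
networks within 24–48 h; quantifying those networks (how much tube, how
branched) is the standard readout of endothelial function in angiogenesis
studies. Manual tracing is slow and operator-dependent. `tubequant` analyzes
plain bright-field TIFFs — no fluorescent labels — and reports, per image:

* **total tube length** *L* (µm),
* **total tube area** *A* (µm²),
* **number of branch points** (consolidated network junctions),
* **average tube thickness** *T = A / L* (µm).

The same chain, restricted to the non-black field of view, also quantifies
vessels in retinal fundus photographs.

## Method

For each image the pipeline runs:

1. **Grayscale conversion** — the R, G, B planes are averaged per pixel and
   the result linearly rescaled to the source intensity range.
2. **Tube detection** — Canny edge detection (high spatial derivative) marks
   tube borders; edge points within `canny_connect` px are connected; the
   mask is dilated and contracted (`canny_connect`, `dilate` closings);
   enclosed false-negative holes `< fill` px are filled and false-positive
   specks `< clean` px cleared. The result is the binary *tube edges* mask.
3. **Skeletonization** — topology-preserving thinning reduces the mask to a
   one-pixel backbone (component counts and Euler characteristic preserved);
   endpoint spurs are trimmed by up to `clip` px, stopping at branch points
   (`clip = Inf` iterates to a fixed point, deleting branch-free tubes).
4. **Metrics** — length sums skeleton adjacencies (1 px per
   horizontal/vertical pair, **1.414** px per diagonal pair) × `scale`
   (µm/px). Skeleton pixels with ≥ 3 neighbors are branch pixels; those
   within `radius` px are spatially averaged into single branch points.
   Edge-mask objects overlapping the skeleton by ≥ `overlap` px contribute
   their area; thickness is area over length.

The eight parameters (`scale, canny_connect, dilate, fill, clean, clip,
overlap, radius`) form a **profile**: tune once on a representative image
("sandbox" mode), save as JSON, then batch-analyze a whole study with no
further input. See `docs/methods.md` for the model details and assumptions.

A **phantom** module renders in-silico tube networks (bars, rotated bars,
T/Y/X junctions, grids, curves, salt-and-pepper-noise variants) whose total
length and junction count are known analytically from the segment geometry —
an independent ground truth for validating the pipeline.

## Worked example

```bash
# write the 22-image noiseless validation suite plus ground_truth.csv
tubequant phantom suite --out phantoms --seed 0 --scale 1.0 --no-noisy

# a profile tuned for 5-px phantom strokes at 1 µm/px
tubequant profile init tuned.json --scale 1.0 --canny 3 --dilate 2 \
    --fill 300 --clean 700 --clip 0 --overlap 5 --radius 30

# sandbox mode: one image
tubequant analyze single phantoms/xcross.tif --profile tuned.json
```

prints

```
file:            xcross.tif
total length:    1202.24 um
total area:      7653.00 um^2
branch points:   1
avg thickness:   6.366 um
```

The `xcross` phantom is two 600-px bars crossing at 45°: true length
1200 µm (recovered within 0.2%), one junction (exact). Thickness reflects
the detected mask, i.e. the 5-px stroke plus a ~2-px edge halo. Batch mode
writes one CSV row per image (`--save-images` adds the overlay TIFFs that
record how each image was interpreted):

```bash
tubequant analyze batch phantoms --profile tuned.json --out results
head -4 results/report.csv
```

```
file,length_um,area_um2,n_nodes,thickness_um,error
asterisk.tif,2410.2439999999997,16057.0,1,6.661981110626145,
blank.tif,0.0,0.0,0,0.0,
box.tif,1591.796,11184.0,0,7.026025948048619,
```

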