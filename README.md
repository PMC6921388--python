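# zdiskseg

Automated segmentation of cardiomyocyte **Z-disks** from serial
electron-microscopy image stacks (SBF-SEM / FIB-SEM), with rule-based
refinement, pixel-wise validation metrics and a synthetic striated-muscle
fixture generator.

Z-disks bound the sarcomere, the contractile unit of striated muscle, and
appear in longitudinal EM sections as narrow bright vertical lines — only
1–2 px wide at 50 nm voxels — with weak contrast against the rest of the
cell. `zdiskseg` segments them slice by slice without any training data,
for microscopists who need a 3-D Z-disk model from a stack in minutes
rather than the many hours a trained pixel classifier costs.

## Method

Each slice `I` passes through three stages:

1. **Pre-processing.** A clipped linear contrast stretch
   `I' = clip(255 · (I − min) / (max − min), 0, 255)` with `max` placed at
   the average of the myofibril and Z-disk intensity means
   (`(55.57 + 63.57)/2 = 59.57 → max = 59` for SBF-SEM), so myofibrils and
   Z-disks saturate white while I-bands stay mid-grey; then Gaussian
   smoothing (σ = 1.2, or σ = 2 for FIB-SEM).
2. **Segmentation.** The directional 3×3 Sobel templates
   `T_RE = T_x` and `T_LE = −T_x` respond to the rising (dark→bright) and
   falling flank of the Z-disk line respectively. Each binarized response
   (per-slice Otsu on the strictly positive values by default) is extended
   one pixel toward its bright side and the two masks are intersected:
   only structures with a rising and a falling edge within ~1 px of each
   other — narrow bright lines — survive. Wide stripes and narrow dark
   bands drop out.
3. **Refinement.** The horizontal templates `T_LME = T_y`, `T_UME = −T_y`
   find the upper and lower cell-membrane edges; after a 2×2 erosion
   (weak edges) and removal of fixed background-interface patterns, a
   rule-based tracker follows each membrane column by column (window
   radius 10, look-ahead radius 20), bridging gaps shorter than 10 columns
   horizontally and longer ones by linear interpolation. Candidates are
   kept only inside the traced band; dense 5×5 clusters are subtracted;
   in the FIB-SEM regime the final mask is dilated with a disk-shaped
   structuring element.

Validation is pixel-wise against annotated masks:
`accuracy = (TP+TN)/(TP+TN+FP+FN)`, `specificity = TN/(TN+FP)`,
`sensitivity = TP/(TP+FN)`.

## Worked example

```
$ zdiskseg synth --out fix --seed 3 --slices 3 --drift 1
$ zdiskseg segment fix/image.tif --out fix/pred.tif --preset sbfsem
$ zdiskseg validate fix/pred.tif fix/zdisk_truth.tif
accuracy: 99.29%
specificity: 99.98%
sensitivity: 79.00%
tp: 5650
tn: 208816
fp: 32
fn: 1502
```

The first command writes a 3-slice synthetic SBF-SEM-like stack (vertical
sarcomere stripes, curved membranes, planted artifacts) with its ground
truth. The second runs the full pipeline with the SBF-SEM preset
(max = 59, σ = 1.2, no dilation) and prints a run report that tallies the
directional convolutions (2 per slice) and intersections (1 per slice).
The third compares prediction and truth pixel by pixel: here 5650 of the
7152 true Z-disk pixels are recovered (sensitivity 79 %) with only 32
false positives in ~215 k pixels.

The same API is available in Python:

```python
import zdiskseg as z
stack = z.read_stack("stack.tif")
masks, report = z.run_pipeline(stack, z.sbfsem_preset())
z.write_mask_stack(masks, "zdisks.tif")
```

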