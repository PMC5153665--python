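# sogseg

Segmentation and object analysis of genetically labelled structures in
volume electron microscopy (SBEM / FIB-SEM) image stacks.

Genetically encoded EM labels — miniSOG-driven DAB photo-oxidation followed
by osmium staining — render targeted structures (mitochondria, the cytosol
of single neurons) at a distinct intensity range against textured neuropil.
`sogseg` re-implements, as a tested and scriptable pipeline, the
computer-assisted procedures used to extract such structures from labelled
fly-brain volumes:

* **bulk segmentation** — closed-range thresholding `lo ≤ I(v) ≤ hi` of the
  whole volume, 3D connected-component extraction (6/18/26-connectivity),
  a minimum-size filter (cutoff `< 10` voxels / `< 0.0002 µm³` at the binned
  SBEM geometry) removing non-specific background signal, and an
  intensity-variance filter `Var[I | object] > V_max` removing highly
  contrasted membrane segments;
* **seed segmentation** — region growing from a point seed placed at the
  cell body, constrained to an intensity range: the ROI is the connected
  component of the thresholded mask containing the seed. An iterative trial
  series holds the upper bound at a common maximum and lowers the lower
  bound by a fixed step, each step a fraction (0.2–0.4%) of the volume's
  *true range* (observed max − min), yielding nested ROIs `ROI₁ ⊆ ROI₂ ⊆ …`
  that progressively incorporate distal neurites, then crossovers and other
  contrasted structures (e.g. trachioles);
* **object analysis** — per-object voxel-count and physical volume,
  intensity statistics, centroid, principal axes from the eigen-decomposition
  of the second central moment tensor of the voxel-centre cloud (axis length
  `2·√(5λ)`, the solid-ellipsoid convention), aspect ratio (major/minor),
  major-axis orientation, and a normalised volume index for volume-coded
  display;
* **pre-processing** — non-local means denoising (σ = 5 on 8-bit data in the
  original workflow), physically scaled Gaussian smoothing, and 3×3×1
  in-plane binning by block mean;
* **synthetic phantoms** — since the original specimens are not deposited,
  generators reproduce their statistical structure (anisotropic SBEM voxels
  of 6.3 × 6.3 × 50 nm and 10.5 × 10.5 × 25 nm, near-isotropic ~10 nm
  FIB-SEM voxels, labelled ellipsoids/neurite trees, sub-cutoff speckle,
  high-variance membrane fragments, branch-point signal drop-off, crossover
  cells, trachioles) with exact ground truth, so every stage is testable by
  parameter recovery.

The package is aimed at microscopists and image analysts who want the
selection criteria of a segmentation to be an explicit, replayable record
rather than an interactive session: every filter logs what it removed and
why, and the whole pipeline is byte-reproducible given a seed.

## Worked example

```python
import sogseg as sg

spec = sg.mito_sbem_spec(grid_shape=(128, 128, 128), rng_seed=11)
vol, truth = sg.make_mitochondria_phantom(spec, n_objects=12, n_speckle=60,
                                          n_membrane_fragments=8)
labels, log = sg.bulk_segment(vol, spec.separating_range(),
                              min_voxels=10, min_volume_um3=0.0002,
                              max_variance=(4 * spec.label_sd) ** 2)
print(f"objects after filters: {labels.n_objects}")
for rec in log.records:
    print(f"  {rec.filter_name}: removed {len(rec.removed_ids)} ({rec.reason})")
records = sg.rank_by_volume(sg.compute_features(labels, vol))
smallest, largest = records[0], records[-1]
print(f"volumes span {smallest.volume_um3:.4f}-{largest.volume_um3:.4f} um^3")
report = sg.evaluate_against_truth(labels, truth, "mitochondria", iou_threshold=0.5)
print(f"precision {report.object_precision:.2f}, recall {report.object_recall:.2f}")
```

prints

```
objects after filters: 12
  min_size: removed 60 (voxel count < 10)
  min_size: removed 0 (physical volume < 0.0002 um^3)
  intensity_variance: removed 8 (population intensity variance > 400.0)
volumes span 0.0251-0.1678 um^3
precision 1.00, recall 1.00
```

The phantom contained 12 labelled mitochondria, 60 speckles and 8 membrane
fragments: the size filter removed exactly the speckles (all below 10
voxels), the variance filter exactly the fragments (bimodal intensities),
and every mitochondrion was recovered one-to-one at IoU ≥ 0.5.

The same stages are available as a CLI:

```sh
sogseg simulate --preset mito-sbem --seed 1 --out volume.tif --truth truth.h5
sogseg preprocess --in volume.tif --nlm-sigma 5 --bin 1,1,1 --out pre.tif
sogseg segment-bulk --in pre.tif --lo 190 --hi 255 --min-voxels 10 \
    --min-volume-um3 0.0002 --max-variance 400 --out labels.h5 --log filters.json
sogseg segment-seed --in pre.tif --seed 60,128,56 --hi 255 --lo-start 190 \
    --step-frac 0.003 --n-trials 12 --out trials.h5 --curve curve.csv
sogseg analyze --labels labels.h5 --in pre.tif --out features.csv
sogseg evaluate --labels labels.h5 --truth truth.h5 --class mitochondria \
    --iou 0.5 --out report.json
```

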