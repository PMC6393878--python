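# neuroseg

Fully automatic gray/white-matter (and tumor) segmentation for 2-D brain-MRI
slices, plus a synthetic phantom generator and a Dice-coefficient validation
harness.

The pipeline:

1. **Threshold** the slice (Otsu by default, or a fixed level).
2. **Skull stripping** — the bright skull outline is detected with a
   deterministic elliptical Hough transform (coarse grid over center,
   semi-axes and rotation, refined once at 1 px / 2°) and everything outside
   the outline, shrunk inward by a margin, is removed. If accumulator support
   is too low the code falls back to convex-hull stripping.
3. **Fuzzy c-means clustering** (c = 3, m = 2) of the in-brain pixel
   intensities with deterministic percentile initialization; a crisp k-means
   engine is available as a baseline.
4. **Tissue labeling** by sorted cluster centers (CSF < GM < WM on
   T1-weighted contrast).
5. **Connected-region postprocessing** — 8-connectivity component labeling,
   largest component per tissue, mask overlay onto the original intensities,
   and boundary-contour extraction.

Tumor mode reuses the front end, then re-clusters the brightest tissue
cluster (c = 2) to separate the hyperintense lesion from white matter;
candidates covering more than 25% of the brain area are flagged implausible.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (surrogate phantom
benchmark, membership-formula hand checks, naive-loop FCM oracle
equivalence, exhaustive connected-component enumeration, skull-strip
parameter recovery, noise-degradation monotonicity, ablation ordering).

## CLI

```sh
# synthetic phantoms with ground-truth masks
neuroseg phantom --n 5 --seed 0 --noise-sigma 0.05 --outdir out/phantoms

# segment one slice (NIfTI, PNG, TIFF, JPEG, or DICOM with pydicom)
neuroseg segment --mode gm-wm --input slice.png --outdir out/seg
neuroseg segment --mode tumor --input tumor_slice.png --outdir out/tumor

# Dice report: automatic masks vs one or more reference mask directories
neuroseg validate --auto out/seg --ref expert1/ --ref expert2/ --outdir out/val

# method-comparison table (raw k-means / plain FCM / full pipeline)
neuroseg compare --n 5 --seed 0 --noise-sigma 0.05 --outdir out/cmp
```

Exit codes: 0 ok, 2 usage error, 3 skull-detection failure, 4 degenerate
clustering.

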