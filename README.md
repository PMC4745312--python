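# cellcull

Automated selection of analysis-suitable cells from stained smear slide-maps.

Nanoscale spectroscopic cytology (e.g. partial wave spectroscopy) measures
statistical properties of cell structure that are exquisitely sensitive to
sample quality: a cell is only usable if it is **isolated, unfolded, free of
debris and smooth in texture**. On a real buccal smear most detected objects
are not — they are debris-covered, folded or overlapping — and picking the
good ones by hand is slow, subjective and operator-dependent. `cellcull`
automates that triage:

1. **slide-map assembly** — stitch raster-scanned tiles, correct uneven
   illumination with a blank background image (flat-field division);
2. **segmentation** — bicubic half-resolution reduction, H-minima/H-maxima
   contrast flattening, Sobel + Laplacian-of-Gaussian edge detection,
   morphological cleanup, connected-component extraction;
3. **features** — shape (eccentricity `sqrt(1 − b²/a²)`, solidity `A/H`),
   histogram (normalized variance `σ²/μ²`, normalized kurtosis
   `E[(x−μ)⁴]/σ⁴`, entropy `−Σ p log₂ p`), and texture (mask-restricted
   co-occurrence energy `Σ M²ᵢⱼ` at offset 5 in eight directions, Gabor
   response variance averaged over four orientations), plus a wider registry
   of standard descriptors;
4. **feature selection** — a nonparametric weighted Fisher criterion
   `F = trace(S_w⁻¹ S_b)` built from inverse-distance weighted class means,
   searched by sequential floating forward selection;
5. **classification** — an rbf-kernel SVM (`exp(−‖xᵢ−xⱼ‖²/2σ²)`) tuned by
   10-fold cross-validation, with kNN and random-forest baselines;
6. **evaluation** — error rate, suitable-cell sensitivity, threshold-sweep
   ROC and trapezoid AUC, stratified percentile bootstrap confidence
   intervals, and a leave-one-out overtraining audit.

Because annotated smear slide-maps are not redistributable, the package ships
a seeded synthetic generator (`cellcull.synthetic`) that renders stained
elliptical cells, the three unsuitable phenotypes and a smooth illumination
gradient, with exact ground truth — every stage is testable offline. See
`docs/methods.md` for the models and all defaults.

## Worked example

```sh
python examples/04_benchmark.py
```

runs a reduced end-to-end benchmark (200 training / 100 testing rendered
objects, 7 selected features, rbf-SVM with a small tuning grid) and prints:

```
selected features: gabor_variance_lowfreq, sd_green, normalized_variance, ratio_red_blue, euler_number, local_minima_density, gray_p75
test error rate:  0.000
test sensitivity: 1.000 (90% CI 1.000-1.000)
test AUC:         1.0000 (90% CI 1.0000-1.0000)
classifier test errors: {'svm_rbf': 0.0, 'svm_linear': 0.0, 'svm_polynomial': 0.0, 'knn': 0.0, 'rf': 0.0}
```

Sensitivity is suitable-cell recall at the default decision threshold; AUC is
the probability a random suitable object outscores a random unsuitable one.
On the synthetic phenotypes the classes are essentially fully separable, so
errors sit at zero — the run demonstrates the machinery, not real-smear
accuracy (see the methods note). Other narrative examples:
`01_simulate_scene.py` (scene generation), `02_segment_scene.py`
(segmentation recall against ground truth), `03_feature_selection.py`
(criterion and floating search on planted data).

A thin CLI mirrors the stages:

```sh
cellcull simulate --seed 1 --outdir scene/
cellcull map --tiles scene/ --grid 2x2 --background scene/background.tif --out map.tif
cellcull segment --map map.tif --out objects.json
cellcull featurize --objects objects.json --map map.tif --out features.csv
cellcull select-features --features features.csv --n 7 --out trace.json
cellcull train --features features.csv --out model.joblib
cellcull evaluate --model model.joblib --features features.csv --out report.json
cellcull benchmark --seed 1 --outdir bench/
```

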