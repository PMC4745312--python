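"""End-to-end synthetic benchmark tying all stages together.

The default benchmark mirrors the study design the package targets: a
training database of 1000 objects and a testing database of 360 objects, half
of each suitable cells, rendered by the synthetic generator at its default
parameters. Two modes are available:

* ``objects`` (default) -- objects are rendered directly from ground truth
  and featurized, isolating the classification stages from segmentation
  noise;
* ``pipeline`` -- full scenes are generated, segmented, matched against
  ground truth for labels, and then featurized.

The run is deterministic in its seed: generator, CV folds, label shuffling
and bootstrap all derive sub-seeds from one seed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, evaluation, features, selection, synthetic
from .segmentation import (ObjectRecord, SegmentationConfig,
                           match_to_ground_truth, segment_slidemap)
from .slidemap import stitch_tiles


@dataclass
class BenchmarkResult:
    trace: selection.SelectionTrace
    classifier: classify.TrainedClassifier
    report: evaluation.EvalReport
    train_table: "object"  # pandas DataFrame
    test_table: "object"
    selected_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "trace": self.trace.to_dict(),
            "report": self.report.to_dict(),
            "svm_params": dict(self.classifier.params),
        }


def _truth_object_record(phenotype: str, oid: int, rng: np.random.Generator,
                         radius_range=(18.0, 36.0), sd_suitable=2.0,
                         sd_unsuitable=8.0) -> ObjectRecord:
    from .slidemap import to_grayscale

    sd = sd_suitable if phenotype == "suitable" else sd_unsuitable
    radius = rng.uniform(*radius_range)
    crop, mask = synthetic.render_cell(phenotype, radius, sd, rng)
    return ObjectRecord(
        object_id=oid, mask=mask,
        bbox=(0, 0, mask.shape[0], mask.shape[1]),
        boundary=np.empty((0, 2), dtype=int),
        crop=crop, gray_crop=to_grayscale(crop),
        label="suitable" if phenotype == "suitable" else "unsuitable",
    )


def generate_object_dataset(n_suitable: int, n_unsuitable: int, seed: int,
                            unsuitable_mix=(1 / 3, 1 / 3, 1 / 3),
                            radius_range=(18.0, 36.0), sd_suitable=2.0,
                            sd_unsuitable=8.0) -> list[ObjectRecord]:
    """Render labeled objects straight from ground truth (no segmentation)."""
    ss = np.random.SeedSequence(seed)
    pheno_rng = np.random.default_rng(ss.spawn(1)[0])
    phenos = ["suitable"] * n_suitable
    if n_unsuitable:
        phenos += [str(p) for p in pheno_rng.choice(
            synthetic.UNSUITABLE_PHENOTYPES, size=n_unsuitable,
            p=np.asarray(unsuitable_mix))]
    streams = ss.spawn(1 + len(phenos))[1:]
    return [
        _truth_object_record(p, oid, np.random.default_rng(s),
                             radius_range, sd_suitable, sd_unsuitable)
        for oid, (p, s) in enumerate(zip(phenos, streams))
    ]


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_benchmark(seed: int = 0, n_train: int = 1000, n_test: int = 360,
                  n_features: int = 7, registry: str = "full",
                  method: str = "svm", kernel: str = "rbf", folds: int = 10,
                  grid: dict | None = None, bootstrap: int = 1000,
                  shuffle_labels: bool = False, mode: str = "objects",
                  scene_spec: synthetic.SceneSpec | None = None,
                  seg_config: SegmentationConfig | None = None
                  ) -> BenchmarkResult:
    """Simulate, featurize, select features, train and evaluate.

    ``shuffle_labels`` is the negative control: it permutes the labels of
    both databases, destroying every label-object association, so the
    evaluated AUC has a tight chance-level null. (Permuting only the training
    labels is not a usable control here: the rendered classes form separable
    clusters, so a classifier fit to permuted labels still ranks by cluster,
    with a random sign -- the null is bimodal rather than centered.)
    """
    root = np.random.SeedSequence(seed)
    data_ss, shuffle_ss, cv_ss, boot_ss = root.spawn(4)

    if mode == "objects":
        train_objs = generate_object_dataset(
            n_train // 2, n_train - n_train // 2, seed=_sub_seed(data_ss))
        test_objs = generate_object_dataset(
            n_test // 2, n_test - n_test // 2,
            seed=_sub_seed(data_ss.spawn(1)[0]))
        train_table = features.compute_feature_table(train_objs, registry)
        test_table = features.compute_feature_table(test_objs, registry)
    elif mode == "pipeline":
        if scene_spec is None:
            raise ValueError("pipeline mode needs a SceneSpec")
        train_table, test_table = _pipeline_tables(
            scene_spec, seg_config or SegmentationConfig(), registry,
            n_train, n_test, _sub_seed(data_ss))
    else:
        raise ValueError("mode must be 'objects' or 'pipeline'")

    if shuffle_labels:
        rng = np.random.default_rng(shuffle_ss)
        train_table = train_table.copy()
        train_table["label"] = rng.permutation(train_table["label"].to_numpy())
        test_table = test_table.copy()
        test_table["label"] = rng.permutation(test_table["label"].to_numpy())

    trace = selection.stepwise_select(train_table, n_features)
    feats = trace.selected
    clf = classify.train(train_table[feats + ["label"]], method=method,
                         kernel=kernel, grid=grid, folds=folds,
                         seed=_sub_seed(cv_ss))
    report = evaluation.evaluate(clf, test_table[feats + ["label"]],
                                 B=bootstrap, seed=_sub_seed(boot_ss))
    return BenchmarkResult(trace=trace, classifier=clf, report=report,
                           train_table=train_table, test_table=test_table,
                           selected_features=feats)


def _pipeline_tables(spec, seg_config, registry, n_train, n_test, seed):
    """Build labeled feature tables by segmenting synthetic scenes."""
    import pandas as pd

    tables = []
    needed = n_train + n_test
    scene_seed = seed
    collected = 0
    while collected < needed:
        sp = synthetic.SceneSpec(**{**_spec_dict(spec), "seed": scene_seed})
        tiles, background, truth = synthetic.generate_slide_scene(sp)
        slide = stitch_tiles(tiles, (sp.tile_rows, sp.tile_cols))
        records = segment_slidemap(slide, background, seg_config)
        matches, _ = match_to_ground_truth(records, truth, iou_threshold=0.5)
        matched = []
        for ri, ti, _iou in matches:
            rec = records[ri]
            rec.label = truth.objects[ti].label
            matched.append(rec)
        if matched:
            tables.append(features.compute_feature_table(matched, registry))
            collected += len(matched)
        scene_seed += 1
    table = pd.concat(tables, ignore_index=True)
    return table.iloc[:n_train], table.iloc[n_train:n_train + n_test]


def _spec_dict(spec):
    import dataclasses
    return dataclasses.asdict(spec)


def compare_classifiers(result: BenchmarkResult, seed: int = 0,
                        grid: dict | None = None, folds: int = 10
                        ) -> dict[str, float]:
    """Test error of rbf/linear SVM, kNN(k=3) and RF on the same features."""
    feats = result.selected_features
    sub_train = result.train_table[feats + ["label"]]
    sub_test = result.test_table[feats + ["label"]]
    errors = {}
    for name, kwargs in (
        ("svm_rbf", {"method": "svm", "kernel": "rbf"}),
        ("svm_linear", {"method": "svm", "kernel": "linear"}),
        ("svm_polynomial", {"method": "svm", "kernel": "polynomial"}),
        ("knn", {"method": "knn"}),
        ("rf", {"method": "rf"}),
    ):
        clf = classify.train(sub_train, grid=grid, folds=folds, seed=seed,
                             **kwargs)
        errors[name] = evaluation.error_rate(
            classify.predict(clf, sub_test), sub_test["label"])
    return errors
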