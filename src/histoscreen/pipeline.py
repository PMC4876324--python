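"""End-to-end experiment orchestration on synthetic cohorts.

``run_experiment`` wires the stages together the way the two screening
experiments are shaped:

* ``percentile_screening`` (biopsy-style): preprocess -> balanced patch
  sampling -> CNN training with early stopping -> dense likelihood maps ->
  cumulative-histogram percentile scores (operating percentile selected on
  the validation cohort) -> slide-level ROC with bootstrap CIs.
* ``lesion_detection`` (sentinel-node-style): the same front end, an
  optional hard-negative boosting round, then component detection, FROC at
  the lesion level, and max-component slide scores with ROC.

Test slides are touched only by the final evaluation; percentile selection
and boosting see training/validation data exclusively.  All randomness is
derived from ``config.seed`` via named substreams, so identical configs
reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .errors import ConfigurationError, HistoscreenError
from .evaluation import (
    METASTASIS_CLASSES,
    auc_metric,
    bootstrap,
    froc,
    lesions_from_labeled_mask,
    match_detections,
    roc,
    specificity_at_sensitivity,
)
from .detection import DetectionConfig, detect_lesions, slide_score_from_detections
from .model import (
    CNNConfig,
    build_cnn,
    infer_likelihood_map,
    to_fully_convolutional,
    train,
)
from .patches import (
    BoostConfig,
    LabeledPatch,
    PatchSpec,
    augment_patch,
    extract_patch,
)
from .preprocess import BinaryMask, optical_density, tissue_mask
from .scoring import (
    DEFAULT_PERCENTILE_GRID,
    cumulative_histogram,
    percentile_score,
    select_percentile,
)
from .synthetic import SlideSimSpec, SyntheticSlide, generate_cohort

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: cohort sizes, stage configs, evaluation settings."""

    mode: str = "lesion_detection"  # or "percentile_screening"
    seed: int = 0
    n_train_pos: int = 14
    n_train_neg: int = 14
    n_val_pos: int = 6
    n_val_neg: int = 6
    n_test_pos: int = 10
    n_test_neg: int = 10
    slide_template: SlideSimSpec = field(default_factory=SlideSimSpec)
    patch_px: int = 128
    target_mpp: float | None = None  # None: analyse at the native resolution
    patches_per_slide_per_class: int = 12
    val_patches_per_slide_per_class: int = 8
    cnn: CNNConfig = field(default_factory=lambda: CNNConfig(max_epochs=8))
    boost: BoostConfig | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    percentiles: tuple = (0.5, 0.9)
    percentile_grid: tuple = DEFAULT_PERCENTILE_GRID
    sensitivity_target: float = 0.999
    n_bootstrap: int = 1000
    included_classes: tuple = METASTASIS_CLASSES
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("percentile_screening", "lesion_detection", "both"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if min(self.n_train_pos, self.n_val_pos) < 1 or min(
            self.n_train_neg, self.n_val_neg
        ) < 1:
            raise ConfigurationError("train and val splits need both classes")
        if self.n_test_pos < 1 or self.n_test_neg < 1:
            raise ConfigurationError("test split needs both classes")

    @property
    def analysis_mpp(self) -> float:
        return self.target_mpp or self.slide_template.microns_per_pixel


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


class _Stage:
    """Re-raise stage errors with the stage name attached."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, HistoscreenError):
            raise type(exc)(f"[stage {self.name}] {exc}") from exc
        return False


def _preprocess(slide: SyntheticSlide, analysis_mpp: float):
    """Tissue + annotation masks at the analysis resolution."""
    from .patches import resample_to_mpp

    native = slide.spec.microns_per_pixel
    img = resample_to_mpp(slide.image, native, analysis_mpp)
    tis = tissue_mask(optical_density(img), microns_per_pixel=analysis_mpp)
    f = int(round(analysis_mpp / native))
    ann = slide.annotation_mask
    if f > 1:
        h, w = ann.shape
        ann = (
            ann[: (h // f) * f, : (w // f) * f]
            .reshape(h // f, f, w // f, f)
            .mean(axis=(1, 3))
            >= 0.5
        )
    ann_mask = BinaryMask(
        values=np.asarray(ann, dtype=np.uint8),
        microns_per_pixel=analysis_mpp,
        role="annotation",
    )
    return tis, ann_mask


def _sample_class_centers(eligible: np.ndarray, n: int, rng) -> list[tuple[int, int]]:
    from .errors import SamplingError

    if len(eligible) < n:
        raise SamplingError(
            f"requested {n} centers but only {len(eligible)} eligible"
        )
    pick = rng.choice(len(eligible), size=n, replace=False)
    return [(int(eligible[i][1]), int(eligible[i][0])) for i in pick]


def _gather_patches(
    slides,
    masks,
    analysis_mpp: float,
    patch_px: int,
    n_pos_per_pos_slide: int,
    seed: int,
    augment: bool,
):
    """Class-balanced patch arrays across a split.

    Cancer patches come from positive slides (``n_pos_per_pos_slide``
    each); the same total number of benign patches is spread evenly over
    every slide in the split.
    """
    from .patches import _eligible_centers

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half = patch_px // 2
    spec = PatchSpec(target_mpp=analysis_mpp, patch_px=patch_px, n_per_class=1)

    pos_slides = [s for s in slides if s.slide_label == 1]
    total_pos = n_pos_per_pos_slide * len(pos_slides)
    n_slides = len(slides)
    neg_quota = [total_pos // n_slides] * n_slides
    for i in range(total_pos % n_slides):
        neg_quota[i] += 1

    patches: list[LabeledPatch] = []
    for i, slide in enumerate(slides):
        tis, ann = masks[slide.slide_id]
        ann_b = ann.astype_bool()
        tis_b = tis.astype_bool()
        simg = slide.as_slide_image()
        if slide.slide_label == 1:
            pool = _eligible_centers(ann_b, half)
            for cx, cy in _sample_class_centers(pool, n_pos_per_pos_slide, rng):
                px = extract_patch(simg, (cx, cy), spec)
                patches.append(LabeledPatch(px, 1, slide.slide_id, (cx, cy)))
        pool = _eligible_centers(tis_b & ~ann_b, half)
        for cx, cy in _sample_class_centers(pool, neg_quota[i], rng):
            px = extract_patch(simg, (cx, cy), spec)
            patches.append(LabeledPatch(px, 0, slide.slide_id, (cx, cy)))

    if augment:
        patches = [v for p in patches for v in augment_patch(p)]
    X = np.stack([p.pixels for p in patches])
    y = np.array([p.label for p in patches], dtype=np.int64)
    return X, y


def _config_fingerprint(config: "ExperimentConfig") -> str:
    payload = {
        "template": dataclasses.asdict(config.slide_template),
        "cnn": dataclasses.asdict(config.cnn),
        "boost": dataclasses.asdict(config.boost) if config.boost else None,
        "patch_px": config.patch_px,
        "mpp": config.analysis_mpp,
        "seed": config.seed,
        "n_train": [config.n_train_pos, config.n_train_neg],
        "patches": config.patches_per_slide_per_class,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _infer_maps(trained, slides, masks, analysis_mpp, config):
    """Likelihood maps for a list of slides, cached on disk when out_dir set."""
    dense = to_fully_convolutional(trained)
    cache_dir = None
    if config.out_dir is not None:
        cache_dir = Path(config.out_dir) / "maps" / _config_fingerprint(config)
        cache_dir.mkdir(parents=True, exist_ok=True)
    maps = {}
    for slide in slides:
        if cache_dir is not None:
            path = cache_dir / f"{slide.slide_id}.tif"
            if path.exists():
                maps[slide.slide_id] = hio.load_likelihood_map(path)
                continue
        tis, _ = masks[slide.slide_id]
        lmap = infer_likelihood_map(dense, slide.as_slide_image(), tis, analysis_mpp)
        maps[slide.slide_id] = lmap
        if cache_dir is not None:
            hio.save_likelihood_map(lmap, cache_dir / f"{slide.slide_id}.tif")
    return maps


def _summary(value: float, boot) -> dict:
    return {"value": float(value), **boot.as_dict()}


def run_experiment(config: ExperimentConfig, slides: dict | None = None) -> dict:
    """Run one full experiment; returns a JSON-serializable metrics report.

    ``slides`` may supply pre-built ``{"train": [...], "val": [...],
    "test": [...]}`` cohorts of :class:`SyntheticSlide`; they must be
    disjoint by slide id.  Otherwise cohorts are generated from
    ``config.slide_template`` with split-specific seeds.
    """
    seeds = _subseeds(config.seed, 8)
    analysis_mpp = config.analysis_mpp

    with _Stage("simulate"):
        if slides is None:
            slides = {}
            for name, n_pos, n_neg, sd in (
                ("train", config.n_train_pos, config.n_train_neg, seeds[0]),
                ("val", config.n_val_pos, config.n_val_neg, seeds[1]),
                ("test", config.n_test_pos, config.n_test_neg, seeds[2]),
            ):
                tmpl = dataclasses.replace(config.slide_template, seed=sd)
                cohort = generate_cohort(n_pos, n_neg, tmpl)
                for s in cohort:
                    s.slide_id = f"{name}_{s.slide_id}"
                slides[name] = cohort
        ids = [s.slide_id for split in slides.values() for s in split]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("train/validation/test splits overlap")

    with _Stage("preprocess"):
        masks = {
            s.slide_id: _preprocess(s, analysis_mpp)
            for split in slides.values()
            for s in split
        }

    with _Stage("sample_patches"):
        Xtr, ytr = _gather_patches(
            slides["train"], masks, analysis_mpp, config.patch_px,
            config.patches_per_slide_per_class, seeds[3], augment=True,
        )
        Xva, yva = _gather_patches(
            slides["val"], masks, analysis_mpp, config.patch_px,
            config.val_patches_per_slide_per_class, seeds[4], augment=False,
        )

    with _Stage("train"):
        cnn_cfg = dataclasses.replace(config.cnn, seed=seeds[5])
        trained = train(build_cnn(cnn_cfg), (Xtr, ytr), (Xva, yva), cnn_cfg)

    if config.boost is not None:
        with _Stage("boost"):
            from .patches import _eligible_centers

            train_maps = _infer_maps(
                trained, slides["train"], masks, analysis_mpp, config
            )
            rng = np.random.default_rng(np.random.SeedSequence(seeds[6]))
            half = config.patch_px // 2
            spec = PatchSpec(target_mpp=analysis_mpp, patch_px=config.patch_px)
            from .patches import MISCLASSIFICATION_CUTOFF

            # one balanced weighted draw over a cross-slide candidate pool
            cand_slide: list = []
            cand_center: list = []
            cand_label: list = []
            cand_lik: list = []
            for slide in slides["train"]:
                tis, ann = masks[slide.slide_id]
                ann_b, tis_b = ann.astype_bool(), tis.astype_bool()
                lmap = train_maps[slide.slide_id]
                for label, pool_mask in ((1, ann_b), (0, tis_b & ~ann_b)):
                    pool = _eligible_centers(pool_mask, half)
                    if len(pool) == 0:
                        continue
                    k = min(len(pool), 4 * config.patches_per_slide_per_class)
                    for cx, cy in _sample_class_centers(pool, k, rng):
                        cand_slide.append(slide)
                        cand_center.append((cx, cy))
                        cand_label.append(label)
                        cand_lik.append(float(lmap.values[cy, cx]))
            cand_label = np.array(cand_label)
            cand_lik = np.array(cand_lik)
            extra: list[LabeledPatch] = []
            for label in (0, 1):
                sel = np.flatnonzero(cand_label == label)
                lik = cand_lik[sel]
                wrong = (
                    lik >= MISCLASSIFICATION_CUTOFF
                    if label == 0
                    else lik < MISCLASSIFICATION_CUTOFF
                )
                w = np.where(wrong, config.boost.boost_factor, 1.0)
                pick = rng.choice(
                    len(sel), size=config.boost.n_additional_per_class,
                    replace=True, p=w / w.sum(),
                )
                for i in pick:
                    slide = cand_slide[sel[i]]
                    center = cand_center[sel[i]]
                    px = extract_patch(slide.as_slide_image(), center, spec)
                    extra.append(LabeledPatch(px, label, slide.slide_id, center))
            extra_aug = [v for p in extra for v in augment_patch(p)]
            Xb = np.concatenate([Xtr, np.stack([p.pixels for p in extra_aug])])
            yb = np.concatenate(
                [ytr, np.array([p.label for p in extra_aug], dtype=np.int64)]
            )
            cnn_cfg2 = dataclasses.replace(config.cnn, seed=seeds[5] + 1)
            trained = train(build_cnn(cnn_cfg2), (Xb, yb), (Xva, yva), cnn_cfg2)

    with _Stage("infer"):
        test_maps = _infer_maps(trained, slides["test"], masks, analysis_mpp, config)
        val_maps = None
        if config.mode in ("percentile_screening", "both"):
            val_maps = _infer_maps(trained, slides["val"], masks, analysis_mpp, config)

    test_labels = np.array([s.slide_label for s in slides["test"]])
    report: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "n_slides": {k: len(v) for k, v in slides.items()},
        "training": {
            "stopped_epoch": trained.stopped_epoch,
            "best_epoch": trained.best_epoch,
            "best_val_error": min(trained.history["val_error"]),
        },
    }

    if config.mode in ("percentile_screening", "both"):
        with _Stage("score"):
            val_list = [val_maps[s.slide_id] for s in slides["val"]]
            val_tis = [masks[s.slide_id][0] for s in slides["val"]]
            val_labels = [s.slide_label for s in slides["val"]]
            p_auc, _ = select_percentile(
                val_list, val_tis, val_labels, criterion="auc",
                grid=config.percentile_grid,
            )
            p_spec, _ = select_percentile(
                val_list, val_tis, val_labels, criterion="spec_at_sens",
                grid=config.percentile_grid,
                sensitivity_target=config.sensitivity_target,
            )

            def test_scores(p: float) -> np.ndarray:
                return np.array(
                    [
                        percentile_score(
                            cumulative_histogram(
                                test_maps[s.slide_id], masks[s.slide_id][0]
                            ),
                            p,
                        ).score
                        for s in slides["test"]
                    ]
                )

        with _Stage("evaluate"):
            scores_auc = test_scores(p_auc)
            scores_spec = test_scores(p_spec)
            cohort_auc = np.column_stack([scores_auc, test_labels])
            boot_auc = bootstrap(
                auc_metric, cohort_auc, n_samples=config.n_bootstrap, seed=seeds[7]
            )

            def spec_metric(arr):
                r = roc(arr[:, 0], arr[:, 1].astype(int))
                return specificity_at_sensitivity(r, config.sensitivity_target)

            cohort_spec = np.column_stack([scores_spec, test_labels])
            boot_spec = bootstrap(
                spec_metric, cohort_spec, n_samples=config.n_bootstrap,
                seed=seeds[7] + 1,
            )
            report["percentile_screening"] = {
                "selected_percentile_auc": p_auc,
                "selected_percentile_spec": p_spec,
                "auc": _summary(roc(scores_auc, test_labels).auc, boot_auc),
                "specificity_at_sensitivity": _summary(
                    spec_metric(cohort_spec), boot_spec
                ),
                "sensitivity_target": config.sensitivity_target,
                # reference operating points at the conventional percentiles
                "auc_at_percentile": {
                    str(p): roc(test_scores(p), test_labels).auc
                    for p in config.percentiles
                },
            }
    if config.mode in ("lesion_detection", "both"):
        with _Stage("detect"):
            assignments = []
            scores = []
            n_components = 0
            for s in slides["test"]:
                comps = detect_lesions(test_maps[s.slide_id], config.detection)
                n_components += len(comps)
                lesions = lesions_from_labeled_mask(
                    s.lesion_labels, analysis_mpp, slide_id=s.slide_id
                )
                assignments.append(match_detections(comps, lesions))
                scores.append(slide_score_from_detections(comps))
            scores = np.array(scores)

        with _Stage("evaluate"):
            curve = froc(assignments, config.included_classes)
            sens1 = curve.sensitivity_at(1.0)
            sens2 = curve.sensitivity_at(2.0)
            boot_s1 = bootstrap(
                lambda a: froc(a, config.included_classes).sensitivity_at(1.0),
                assignments, n_samples=config.n_bootstrap, seed=seeds[7],
            )
            boot_s2 = bootstrap(
                lambda a: froc(a, config.included_classes).sensitivity_at(2.0),
                assignments, n_samples=config.n_bootstrap, seed=seeds[7] + 1,
            )
            cohort_auc = np.column_stack([scores, test_labels])
            boot_auc = bootstrap(
                auc_metric, cohort_auc, n_samples=config.n_bootstrap,
                seed=seeds[7] + 2,
            )

            def spec_metric(arr):
                r = roc(arr[:, 0], arr[:, 1].astype(int))
                return specificity_at_sensitivity(r, config.sensitivity_target)

            boot_spec = bootstrap(
                spec_metric, cohort_auc, n_samples=config.n_bootstrap,
                seed=seeds[7] + 3,
            )
            report["lesion_detection"] = {
                "n_test_components": n_components,
                "slide_auc": _summary(roc(scores, test_labels).auc, boot_auc),
                "specificity_at_sensitivity": _summary(
                    spec_metric(cohort_auc), boot_spec
                ),
                "froc_sensitivity_at_1fp": _summary(sens1, boot_s1),
                "froc_sensitivity_at_2fp": _summary(sens2, boot_s2),
                "sensitivity_target": config.sensitivity_target,
            }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
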