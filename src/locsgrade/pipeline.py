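"""End-to-end orchestration: synthetic data -> features -> split -> train ->
evaluate, with a fully logged, serializable configuration.

The pipeline runs both branches of the grading system on the synthetic
dataset: slit-beam images feed the nuclear branch (bright-spot suppression,
lens localization, fuzzy colour proportions, NO and NC graders) and
retro-illumination images feed the cortical/posterior branch (circle
segmentation, highlight filling, lesion binarization, Hough-line and contour
features, C and P graders).  Every run writes its resolved configuration,
per-type feature CSVs, trained models and evaluation reports into a run
directory; identical configurations and seeds reproduce all of these
byte-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import imgcore, nuclear_features, nuclear_preproc, retro_features, \
    retro_preproc, synthgen
from .grader import (AnnConfig, AnnModel, EvalReport, GradeLabel, evaluate,
                     predict_grade, split_dataset, train_ann)
from .imgcore import FeatureVector, RgbImage, to_gray
from .nuclear_features import NuclearFeatureConfig, nuclear_feature_vector
from .retro_features import (HoughLineConfig, cortical_line_features,
                             lesion_binarize, posterior_contour_features)
from .retro_preproc import RetroPreprocConfig, segment_eyeball

logger = logging.getLogger("locsgrade")


@dataclass(frozen=True)
class NuclearPreprocConfig:
    suppress_threshold: int = 250
    binarize_threshold: Optional[int] = None   # None -> Otsu
    stride: int = 2
    expand_factor: float = 1.1


@dataclass(frozen=True)
class LesionBinarizeConfig:
    block: Optional[int] = None                # None -> width/8, odd
    offset_c: float = 5.0
    fill_holes: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of one pipeline run, with defaults."""

    n_per_grade: int = 30
    seed: int = 1
    split_ratio: float = 0.7
    stratify: bool = True
    write_images: bool = False
    nuclear_preproc: NuclearPreprocConfig = NuclearPreprocConfig()
    nuclear_features: NuclearFeatureConfig = NuclearFeatureConfig()
    retro_preproc: RetroPreprocConfig = RetroPreprocConfig(sample_n=800)
    lesion: LesionBinarizeConfig = LesionBinarizeConfig()
    hough_lines: HoughLineConfig = HoughLineConfig()
    ann: AnnConfig = AnnConfig()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Strict construction: unknown keys are rejected at every level."""
        def build(dc_type, d):
            known = {f.name: f for f in fields(dc_type)}
            unknown = set(d) - set(known)
            if unknown:
                raise ValueError(
                    f"unknown config keys for {dc_type.__name__}: "
                    f"{sorted(unknown)}")
            kwargs = {}
            for name, value in d.items():
                ftype = known[name].type
                sub = _SUBCONFIGS.get(name)
                if sub is not None and isinstance(value, dict):
                    kwargs[name] = build(sub, value)
                elif isinstance(value, list):
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)
        return build(cls, data)


_SUBCONFIGS = {
    "nuclear_preproc": NuclearPreprocConfig,
    "nuclear_features": NuclearFeatureConfig,
    "retro_preproc": RetroPreprocConfig,
    "lesion": LesionBinarizeConfig,
    "hough_lines": HoughLineConfig,
    "ann": AnnConfig,
}


# ---------------------------------------------------------------------------
# single-image feature extraction (shared by pipeline and CLI)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NuclearLocalization:
    bbox: nuclear_preproc.BoundingBox
    ellipse: nuclear_preproc.EllipseRegion
    expanded: nuclear_preproc.EllipseRegion


def locate_lens(img: RgbImage,
                cfg: NuclearPreprocConfig = NuclearPreprocConfig()
                ) -> NuclearLocalization:
    """Slit-beam preprocessing chain up to the localized lens ellipse."""
    sup = nuclear_preproc.suppress_bright_spots(img, cfg.suppress_threshold)
    binary = nuclear_preproc.dynamic_threshold_binarize(
        to_gray(sup), threshold=cfg.binarize_threshold)
    bbox = nuclear_preproc.approximate_lens_bbox(binary)
    ellipse = nuclear_preproc.max_inscribed_white_ellipse(binary, bbox,
                                                          stride=cfg.stride)
    expanded = nuclear_preproc.expand_ellipse(ellipse, cfg.expand_factor,
                                              img.shape)
    return NuclearLocalization(bbox, ellipse, expanded)


def extract_nuclear_features(img: RgbImage,
                             pre: NuclearPreprocConfig = NuclearPreprocConfig(),
                             feat: NuclearFeatureConfig = NuclearFeatureConfig()
                             ) -> FeatureVector:
    """Full nuclear branch for one image: localization + colour proportions."""
    loc = locate_lens(img, pre)
    sup = nuclear_preproc.suppress_bright_spots(img, pre.suppress_threshold)
    crop, mask = nuclear_preproc.crop_lens(sup, loc.expanded)
    return nuclear_feature_vector(crop, mask, feat)


def extract_retro_features(img: RgbImage, cataract_type: str,
                           pre: RetroPreprocConfig = RetroPreprocConfig(),
                           lesion: LesionBinarizeConfig = LesionBinarizeConfig(),
                           lines: HoughLineConfig = HoughLineConfig()
                           ) -> FeatureVector:
    """Full retro branch for one image (``cataract_type`` 'C' or 'P')."""
    if cataract_type not in ("C", "P"):
        raise ValueError("retro features are defined for types 'C' and 'P'")
    seg = segment_eyeball(img, pre)
    binary = lesion_binarize(to_gray(seg.crop), seg.circle,
                             block=lesion.block, offset_c=lesion.offset_c,
                             fill_holes=lesion.fill_holes)
    if cataract_type == "C":
        return cortical_line_features(binary, seg.circle, lines)
    return posterior_contour_features(binary, seg.circle)


def extract_features(item: synthgen.DatasetItem,
                     cfg: PipelineConfig) -> FeatureVector:
    ctype = item.label.cataract_type
    if ctype in ("NO", "NC"):
        return extract_nuclear_features(item.image, cfg.nuclear_preproc,
                                        cfg.nuclear_features)
    return extract_retro_features(item.image, ctype, cfg.retro_preproc,
                                  cfg.lesion, cfg.hough_lines)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _features_frame(rows: List[Tuple[str, int, FeatureVector]]) -> pd.DataFrame:
    width = len(rows[0][2])
    data = {
        "id": [r[0] for r in rows],
        "grade": [r[1] for r in rows],
    }
    for j in range(width):
        data[f"f{j}"] = [r[2].values[j] for r in rows]
    return pd.DataFrame(data)


def _ann_seed(seed: int, type_idx: int) -> int:
    ss = np.random.SeedSequence([int(seed), 9000 + type_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(cfg: PipelineConfig, out_dir) -> Dict[str, EvalReport]:
    """Execute both branches end to end; returns one report per type.

    Writes into ``out_dir``: ``config.json`` (the resolved configuration),
    ``features_<T>.csv``, ``model_<T>.json``, ``report_<T>.json`` and
    ``report_<T>.txt`` for each type T, and ``pipeline.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path) -> Dict[str, EvalReport]:
    (out / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=1, sort_keys=True) + "\n")

    logger.info("stage synth: generating dataset (n_per_grade=%d, seed=%d)",
                cfg.n_per_grade, cfg.seed)
    items = synthgen.gen_dataset(cfg.n_per_grade, seed=cfg.seed)
    if cfg.write_images:
        synthgen.write_dataset(items, out / "images")

    logger.info("stage features: extracting %d images", len(items))
    by_type: Dict[str, List[Tuple[str, int, FeatureVector, GradeLabel]]] = {}
    failures = 0
    for it in items:
        try:
            fv = extract_features(it, cfg)
        except imgcore.LocsGradeError as exc:
            failures += 1
            logger.warning("feature extraction failed for %s: %s",
                           it.item_id, exc)
            continue
        by_type.setdefault(it.label.cataract_type, []).append(
            (it.item_id, it.label.grade, fv, it.label))
    if failures:
        logger.warning("stage features: %d/%d images failed extraction",
                       failures, len(items))

    reports: Dict[str, EvalReport] = {}
    for ti, ctype in enumerate(synthgen._TYPE_ORDER):
        rows = by_type.get(ctype, [])
        if not rows:
            raise imgcore.DataError(f"no usable images for type {ctype}")
        frame = _features_frame([(r[0], r[1], r[2]) for r in rows])
        frame.to_csv(out / f"features_{ctype}.csv", index=False,
                     float_format="%.10g")

        logger.info("stage split: type %s, %d items", ctype, len(rows))
        train, test = split_dataset(
            rows, ratio=cfg.split_ratio, seed=cfg.seed,
            stratify_key=(lambda r: r[1]) if cfg.stratify else None)
        logger.info("stage split: type %s -> %d train / %d test",
                    ctype, len(train), len(test))

        logger.info("stage train: type %s", ctype)
        ann_cfg = dataclasses.replace(cfg.ann, seed=_ann_seed(cfg.seed, ti))
        model = train_ann(np.array([r[2].values for r in train]),
                          [r[3] for r in train], ann_cfg)
        (out / f"model_{ctype}.json").write_text(model.to_json() + "\n")
        logger.info("stage train: type %s final loss %.6f",
                    ctype, model.final_loss)

        logger.info("stage evaluate: type %s", ctype)
        preds, raws = [], []
        for r in test:
            lab, raw = predict_grade(model, r[2].values)
            preds.append(lab)
            raws.append(raw)
        report = evaluate([r[3] for r in test], preds, raws)
        (out / f"report_{ctype}.json").write_text(report.to_json() + "\n")
        (out / f"report_{ctype}.txt").write_text(report.text_table() + "\n")
        logger.info("stage evaluate: type %s accuracy %.4f macro AUC %.4f",
                    ctype, report.accuracy, report.macro_auc)
        reports[ctype] = report
    return reports
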