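"""End-to-end pipeline orchestration over a run directory.

Stages run in workflow order (synth slide generation, tissue segmentation,
patching, stub featurization, cross-validated training, evaluation, heatmap
rendering). Each stage writes its standard artifacts under the run's output
directory and is skipped on re-runs when its outputs already exist (unless
forced). The resolved config is serialized into the run directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bags as bags_mod
from . import cohort as cohort_mod
from .config import RunConfig, derive_seed
from .heatmap import HeatmapParams, overlay, save_heatmap_png, scores_to_map
from .preprocess import SegmentationParams, extract_patch_grid, segment_tissue, select_level
from .slide import ArraySlide
from .synthetic import SynthBagConfig, generate_bags, generate_toy_slide
from .train import cross_validate, default_train_config, fold_results_frame

STAGE_ORDER = ("synth", "segment", "patch", "featurize", "train", "eval", "heatmap")

# saturated tissue colors per risk tier so stub-encoded toy slides are separable
_TIER_COLORS = {0: (216, 140, 170), 1: (150, 120, 200), 2: (120, 60, 110)}


def _slide_cohort(config: RunConfig, n_slides: int, size: int = 512):
    """Toy slides with tier-dependent stain colors plus their case records."""
    seed = derive_seed(config.seed, "synth")
    rng = np.random.default_rng(seed)
    tiers = np.array([0, 1, 2] * (n_slides // 3 + 1))[:n_slides]
    slides, records = [], []
    for i, tier in enumerate(tiers):
        cx = size / 2 + rng.uniform(-40, 40)
        cy = size / 2 + rng.uniform(-40, 40)
        img, _ = generate_toy_slide(
            size, size,
            ellipses=[((cx, cy), (size * 0.32, size * 0.24), _TIER_COLORS[int(tier)])],
            artifact_specks=3,
            seed=seed + i,
        )
        slides.append(ArraySlide(img))
        records.append(cohort_mod.CaseRecord(case_id=f"toy_{i:03d}", tier=int(tier)))
    return slides, records


def run_pipeline(stages, config: RunConfig, force: bool = False, log=print) -> dict:
    """Execute a subset of pipeline stages; returns a dict of artifacts."""
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in set(stages)]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    artifacts: dict = {}

    needs_images = {"segment", "patch", "featurize"} & set(stages)
    if needs_images or "synth" in stages:
        if config.encoder.kind == "synthetic_bags":
            pass  # bags generated directly in the train stage
        else:
            slides, records = _slide_cohort(config, config.synth.n_cases)
            artifacts["slides"], artifacts["records"] = slides, records

    bag_dir = out / "bags"
    manifest_path = out / "manifest.csv"

    if {"segment", "patch", "featurize"} & set(stages):
        bag_dir.mkdir(exist_ok=True)
        if manifest_path.exists() and not force:
            log(f"skip featurize: {manifest_path} exists (use force to redo)")
        else:
            seg_params = SegmentationParams(
                target_downsample=config.preprocess.target_downsample,
                patch_size=config.preprocess.patch_size,
                tissue_coverage_min=config.preprocess.tissue_coverage_min,
                use_morph_gradient=config.preprocess.use_morph_gradient,
                min_region_area=50,
                min_hole_area=50,
            )
            encoder = bags_mod.make_stub_encoder(
                config.encoder.kind, config.encoder.dim, seed=derive_seed(config.seed, "featurize")
            )
            for slide, rec in zip(artifacts["slides"], artifacts["records"]):
                level = select_level(slide.level_downsamples, seg_params.target_downsample)
                ds = slide.level_downsamples[level]
                mask = segment_tissue(
                    slide.read_level(level), seg_params,
                    level=level, downsample=ds, slide_dims_level0=slide.dimensions,
                )
                grid = extract_patch_grid(mask, seg_params)
                if len(grid) == 0:
                    raise RuntimeError(f"{rec.case_id}: empty patch grid after segmentation")
                bag = bags_mod.encode_slide(
                    slide, grid, encoder, rec.case_id, rec.tier,
                    batch_size=config.encoder.batch_size,
                )
                bags_mod.write_bag(bag, bag_dir / f"{rec.case_id}.h5")
                rec.slide_path = str(bag_dir / f"{rec.case_id}.h5")
            cohort_mod.write_manifest(artifacts["records"], manifest_path)
            log(f"featurized {len(artifacts['records'])} slides -> {bag_dir}")

    if "train" in stages or "eval" in stages:
        if manifest_path.exists():
            records = cohort_mod.load_manifest(manifest_path)
            bags = [bags_mod.read_bag(r.slide_path) for r in records]
        else:  # pure feature-bag path: synthesize statistical bags directly
            cfg = SynthBagConfig(
                n_cases=config.synth.n_cases,
                dim=config.synth.dim,
                effect_size=config.synth.effect_size,
                signal_fraction=config.synth.signal_fraction,
                bag_size_range=(config.synth.bag_min, config.synth.bag_max),
                seed=derive_seed(config.seed, "synth"),
            )
            bags, _ = generate_bags(cfg)
        artifacts["bags"] = bags
        metrics_path = out / "fold_metrics.csv"
        if metrics_path.exists() and not force:
            log(f"skip train: {metrics_path} exists (use force to redo)")
            artifacts["fold_metrics"] = pd.read_csv(metrics_path)
        else:
            overrides = {
                k: v for k, v in {
                    "lr": config.train.lr,
                    "max_epochs": config.train.max_epochs,
                    "early_stop_patience": config.train.early_stop_patience,
                    "loss_kind": config.train.loss_kind,
                }.items() if v is not None
            }
            overrides["weight_decay"] = config.train.weight_decay
            overrides["warmup_epochs"] = min(config.train.warmup_epochs,
                                             overrides.get("max_epochs", 100))
            tcfg = default_train_config(config.model.kind, **overrides)
            result = cross_validate(
                config.model.kind, bags, k=config.train.folds,
                seed=derive_seed(config.seed, "train"), train_config=tcfg,
            )
            frame = fold_results_frame(result["reports"])
            frame.to_csv(metrics_path, index=False)
            agg = {k: {"mean": m, "sd": s} for k, (m, s) in result["aggregate"].items()}
            (out / "aggregate_metrics.json").write_text(json.dumps(agg, indent=2))
            for i, hist in enumerate(result["histories"]):
                hist.to_csv(out / f"history_fold{i}.csv", index=False)
            artifacts["cv"] = result
            artifacts["fold_metrics"] = frame
            artifacts["bags"] = bags
            log(f"cross-validation done: mean accuracy "
                f"{result['aggregate']['accuracy'][0]:.3f}, mean AUC {result['aggregate']['auc'][0]:.3f}")

    if "heatmap" in stages:
        if "cv" not in artifacts and not (out / "fold_metrics.csv").exists():
            raise RuntimeError("heatmap stage needs a completed train stage (no checkpoint/run found)")
        bags = artifacts.get("bags")
        if bags is None:
            raise RuntimeError("heatmap stage requires bags from the same run")
        bag = bags[0]
        model = artifacts["cv"]["last_model"] if "cv" in artifacts else None
        if model is None:
            from .train import build_model

            model = build_model(config.model.kind, bags[0].dim, seed=derive_seed(config.seed, "train"))
        hm_params = HeatmapParams(
            render_downsample=config.heatmap.render_downsample,
            overlay_alpha=config.heatmap.overlay_alpha,
            mode=config.heatmap.mode,
        )
        attn = model.forward(bag, mode="eval")[1]
        scores = attn.weights if attn.weights.ndim == 1 else attn.weights[:, 0]
        heat = scores_to_map(scores, bag.coords, bag.patch_size, hm_params)
        if "slides" in artifacts:
            from skimage.transform import resize

            slide_img = artifacts["slides"][0].read_level(0)
            small = np.clip(
                resize(slide_img, (*heat.shape, 3), preserve_range=True), 0, 255
            ).astype(np.uint8)
            rendered = overlay(heat, small, hm_params)
        else:
            rendered = overlay(heat, np.full((*heat.shape, 3), 240, dtype=np.uint8), hm_params)
        save_heatmap_png(out / "heatmap.png", rendered)
        artifacts["heatmap"] = heat
        log(f"heatmap written to {out / 'heatmap.png'}")

    return artifacts
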