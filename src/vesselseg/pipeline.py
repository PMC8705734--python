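"""End-to-end orchestration: data -> preprocess -> sample -> train ->
predict -> evaluate, emitting metrics.json, logs, and the config echo."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, derive_stage_seed, effective_config_yaml
from .infer import binarize, predict_image
from .io import load_drive_split
from .metrics import evaluate_segmentation
from .model import build_network
from .preprocess import preprocess_pipeline
from .sampler import sample_patches, split_train_val
from .synthetic import generate_dataset, write_drive_layout
from .train import train

logger = logging.getLogger("vesselseg")

__all__ = ["run_pipeline"]


def _load_data(cfg: RunConfig, out_dir: Path):
    """Return (train, test) lists of (image, label, fov) triples."""
    if cfg.pipeline.data_dir is not None:
        data_dir = Path(cfg.pipeline.data_dir)
        if not data_dir.is_dir():
            raise FileNotFoundError(
                f"pipeline.data_dir {data_dir} does not exist and synthesis is disabled"
            )
        train_pairs, test_pairs = load_drive_split(data_dir)
        to_triples = lambda pairs: [
            (img, lab, img.fov_mask if img.fov_mask is not None else np.ones(lab.shape, np.uint8))
            for img, lab in pairs
        ]
        return to_triples(train_pairs), to_triples(test_pairs)
    synth_seed = derive_stage_seed(cfg.seed, "synth")
    n = cfg.pipeline.n_train + cfg.pipeline.n_test
    samples = generate_dataset(n, cfg.synth, seed=synth_seed)
    tr, te = samples[: cfg.pipeline.n_train], samples[cfg.pipeline.n_train :]
    write_drive_layout(tr, out_dir / "data" / "training")
    write_drive_layout(te, out_dir / "data" / "test")
    return (
        [(s.image, s.vessels, s.fov) for s in tr],
        [(s.image, s.vessels, s.fov) for s in te],
    )


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage in order; artifacts are written under ``out_dir``.

    Returns the pooled metrics dict (also written to ``metrics.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "effective_config.yaml").write_text(effective_config_yaml(cfg))

    stage = "data"
    try:
        train_data, test_data = _load_data(cfg, out_dir)

        stage = "preprocess"
        logger.info("preprocessing %d training images", len(train_data))
        train_units = [preprocess_pipeline(img, cfg.preprocess) for img, _, _ in train_data]

        stage = "sample"
        patch_seed = derive_stage_seed(cfg.seed, "sampler")
        ps = sample_patches(
            train_units,
            [lab.vessels for _, lab, _ in train_data],
            n_total=cfg.sampler.n_total,
            patch_size=cfg.sampler.patch_size,
            seed=patch_seed,
            source_ids=[img.image_id for img, _, _ in train_data],
        )
        tr_set, val_set = split_train_val(ps, cfg.sampler.val_fraction, seed=patch_seed)

        stage = "train"
        model = build_network(cfg.model, seed=derive_stage_seed(cfg.seed, "init"))
        ckpt_dir = cfg.train.checkpoint_dir or str(out_dir / "checkpoints")
        train_cfg = type(cfg.train)(
            **{
                **cfg.train.__dict__,
                "checkpoint_dir": ckpt_dir,
                "seed": derive_stage_seed(cfg.seed, "train"),
            }
        )
        model, log = train(model, tr_set, val_set, train_cfg)
        log.to_csv(out_dir / "train_log.csv")

        stage = "predict+evaluate"
        probs, preds, golds, fovs = [], [], [], []
        per_image = {}
        for img, lab, fov in test_data:
            u = preprocess_pipeline(img, cfg.preprocess)
            pm = predict_image(
                model,
                u,
                fov,
                patch_size=cfg.sampler.patch_size,
                stride=cfg.infer.stride,
                batch_size=cfg.infer.batch_size,
            )
            mask = binarize(pm, cfg.infer.threshold)
            m = fov > 0
            probs.append(pm.values[m])
            preds.append(mask[m])
            golds.append(lab.vessels[m])
            per_image[img.image_id] = evaluate_segmentation(pm.values, mask, lab.vessels, fov)

        prob = np.concatenate(probs)
        pred = np.concatenate(preds)
        gold = np.concatenate(golds)
        pooled = evaluate_segmentation(prob, pred, gold)
        result = {"pooled": pooled, "per_image": per_image}
        (out_dir / "metrics.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return result
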