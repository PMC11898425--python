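"""End-to-end encrypted-domain classification pipeline.

One :class:`RunConfig` drives the full four-stage workflow:

1. obtain images (generate phantoms or load a PNG folder + labels CSV),
2. encrypt every image with a permutation cipher (Baker or Arnold; or no
   cipher, as the plaintext baseline),
3. extract backbone features from the encrypted images and train the
   fully-connected head on the training split,
4. evaluate on the held-out split and emit the metrics table.

A single master seed deterministically fans out into per-stage seeds
(dataset, cipher key, backbone filters, classifier init/shuffling), so
identical configs reproduce identical artifacts and stages stay
reproducible when run standalone.  By default images are resized *before*
encryption so the encrypted folder can be decrypted back bit-exactly;
``paper_order=True`` encrypts first and resizes afterwards instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import cipher as cc
from . import phantoms as ph
from .backbone import BackboneSpec, extract_features, preprocess
from .classifier import DnnConfig, predict, save_model, train
from .metrics import (
    MetricsReport,
    compute_metrics,
    confusion_from_predictions,
    format_table,
    results_table,
    write_metrics_csv,
)

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "stage_seeds",
    "run_pipeline",
    "compare_ciphers",
    "PipelineResult",
]

log = logging.getLogger("scramblenet")

STAGES = ("data", "cipher", "features", "train", "evaluate")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML.

    ``scheme`` is "baker", "arnold" or "none" (plaintext baseline).
    ``key_spec`` optionally pins the cipher key: for Baker a dict
    ``{"parts": [...], "rounds": r}``; for Arnold
    ``{"matrix": [a,b,c,d], "iterations": t}``.  When absent, a key is
    drawn from the cipher-stage seed.
    """

    phantoms: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    data_dir: str | None = None  # folder of PNGs + labels.csv, overrides phantoms
    scheme: str = "baker"
    key_spec: dict | None = None
    paper_order: bool = False
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    dnn: DnnConfig = field(default_factory=DnnConfig)
    test_fraction: float = 0.2
    metrics_mode: str = "positive"
    save_encrypted: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.scheme not in ("baker", "arnold", "none"):
            raise ConfigError(f"unknown cipher scheme {self.scheme!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError("test_fraction must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        obj = {
            "phantoms": asdict(self.phantoms),
            "data_dir": self.data_dir,
            "scheme": self.scheme,
            "key_spec": self.key_spec,
            "paper_order": self.paper_order,
            "backbone": asdict(self.backbone),
            "dnn": asdict(self.dnn),
            "test_fraction": self.test_fraction,
            "metrics_mode": self.metrics_mode,
            "save_encrypted": self.save_encrypted,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        try:
            phant = obj.get("phantoms", {})
            for key in ("lesion_uplift", "lesion_radius_frac"):
                if key in phant and isinstance(phant[key], list):
                    phant[key] = tuple(phant[key])
            dnn = obj.get("dnn", {})
            if "hidden" in dnn and isinstance(dnn["hidden"], list):
                dnn["hidden"] = tuple(dnn["hidden"])
            return cls(
                phantoms=ph.PhantomSpec(**phant),
                data_dir=obj.get("data_dir"),
                scheme=obj.get("scheme", "baker"),
                key_spec=obj.get("key_spec"),
                paper_order=bool(obj.get("paper_order", False)),
                backbone=BackboneSpec(**obj.get("backbone", {})),
                dnn=DnnConfig(**dnn),
                test_fraction=float(obj.get("test_fraction", 0.2)),
                metrics_mode=obj.get("metrics_mode", "positive"),
                save_encrypted=bool(obj.get("save_encrypted", False)),
                seed=int(obj.get("seed", 42)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc


def stage_seeds(master_seed: int) -> dict:
    """Deterministically derive one sub-seed per stage from the master seed.

    Uses numpy's SeedSequence spawning; every derived seed is < 2**31 so it
    can be passed anywhere a small positive int is expected.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


@dataclass
class PipelineResult:
    """Artifacts of one run: the report plus paths written under out_dir."""

    report: MetricsReport
    table: "object"  # pandas DataFrame
    key: object
    out_dir: Path | None
    model: object = None


def _make_key(scheme: str, n: int, key_spec: dict | None, seed: int):
    if scheme == "none":
        return None
    if key_spec is None:
        if scheme == "baker":
            return cc.random_baker_key(n, seed=seed)
        rng = np.random.default_rng(seed)
        return cc.ArnoldParams(iterations=int(rng.integers(1, 8)))
    if scheme == "baker":
        return cc.validate_baker_key(
            key_spec["parts"], n, rounds=int(key_spec.get("rounds", 1))
        )
    a, b, c, d = key_spec["matrix"]
    params = cc.ArnoldParams(a, b, c, d, iterations=int(key_spec.get("iterations", 1)))
    params.check_invertible(n)
    return params


def _encrypt_dataset(
    dataset: ph.ImageDataset, scheme: str, key, size: int, paper_order: bool
) -> ph.ImageDataset:
    """Stage 1+2 geometry: resize-then-encrypt (default) or encrypt-then-resize."""
    out = []
    table = None
    for rec in dataset:
        img = rec.image
        if paper_order:
            if scheme != "none":
                if table is None or table.n != img.shape[0]:
                    table = cc.build_permutation(key, img.shape[0])
                img = cc.apply_permutation(img, table)
            img = np.round(preprocess(img, size=size) * 255).astype(np.uint8)
        else:
            img = np.round(preprocess(img, size=size) * 255).astype(np.uint8)
            if scheme != "none":
                if table is None or table.n != size:
                    table = cc.build_permutation(key, size)
                img = cc.apply_permutation(img, table)
        out.append(img)
    return dataset.with_images(out)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the four stages and (optionally) persist artifacts.

    When *out_dir* is given the run directory receives: the resolved config
    (``config.yaml``), the cipher key (``key.json``), the per-epoch training
    curve (``training_curve.csv``), the model directory, the lossless
    metrics CSV and a plain-text log.  Re-running an identical config
    reproduces an identical metrics CSV.
    """
    seeds = stage_seeds(cfg.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    # Stage: data
    try:
        if cfg.data_dir is not None:
            dataset = ph.load_image_folder(cfg.data_dir)
        else:
            dataset = ph.make_dataset(
                cfg.phantoms, test_fraction=cfg.test_fraction, seed=seeds["data"]
            )
    except Exception as exc:
        raise StageError("data", exc) from exc

    size = cfg.backbone.input_size

    # Stage: cipher
    try:
        key = _make_key(cfg.scheme, size, cfg.key_spec, seeds["cipher"])
        if out is not None and key is not None:
            cc.save_key(key, out / "key.json")
        encrypted = _encrypt_dataset(dataset, cfg.scheme, key, size, cfg.paper_order)
        if out is not None and cfg.save_encrypted:
            ph.save_dataset(encrypted, out / "encrypted")
    except Exception as exc:
        raise StageError("cipher", exc) from exc

    # Stage: features
    try:
        bspec = BackboneSpec(
            architecture=cfg.backbone.architecture,
            weights=cfg.backbone.weights,
            reduction=cfg.backbone.reduction,
            input_size=size,
            seed=seeds["features"],
        )
        feats = extract_features(encrypted.images, bspec)
    except Exception as exc:
        raise StageError("features", exc) from exc

    train_mask = np.array([r.split == "train" for r in encrypted])
    labels = encrypted.labels

    # Stage: train
    try:
        dcfg = DnnConfig(
            hidden=cfg.dnn.hidden,
            epochs=cfg.dnn.epochs,
            batch_size=cfg.dnn.batch_size,
            learning_rate=cfg.dnn.learning_rate,
            optimizer=cfg.dnn.optimizer,
            seed=seeds["train"],
        )
        model = train(feats[train_mask], labels[train_mask], dcfg)
        if out is not None:
            save_model(model, out / "model")
            curve = "epoch,loss,accuracy\n" + "".join(
                f"{e},{l:.6f},{a:.6f}\n" for e, l, a in model.history
            )
            (out / "training_curve.csv").write_text(curve)
    except Exception as exc:
        raise StageError("train", exc) from exc

    # Stage: evaluate
    try:
        _, hard = predict(model, feats[~train_mask])
        confusion = confusion_from_predictions(
            labels[~train_mask], hard, positive=ph.TUMOR
        )
        report = compute_metrics(confusion, mode=cfg.metrics_mode)
        name = f"{cfg.backbone.architecture}+dnn"
        table = results_table([(name, cfg.scheme, report)])
        if out is not None:
            write_metrics_csv(table, out / "metrics.csv")
            (out / "run.log").write_text(
                f"scheme={cfg.scheme} seed={cfg.seed}\n"
                f"confusion tp={confusion.tp} fp={confusion.fp} "
                f"fn={confusion.fn} tn={confusion.tn}\n" + format_table(table) + "\n"
            )
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    log.info("run complete: scheme=%s accuracy=%.4f", cfg.scheme, report.accuracy)
    return PipelineResult(report=report, table=table, key=key, out_dir=out, model=model)


def compare_ciphers(
    cfg: RunConfig,
    schemes: Sequence[str] = ("none", "baker", "arnold"),
    out_dir: str | Path | None = None,
):
    """Run the pipeline once per cipher scheme with shared data and seeds.

    The master seed (hence dataset, split membership, backbone filters and
    classifier init) is identical across schemes, so rows differ only in
    the cipher.  Returns the combined results DataFrame.
    """
    if len(schemes) == 0:
        raise ConfigError("need at least one scheme to compare")
    rows = []
    for scheme in schemes:
        sub = RunConfig(
            phantoms=cfg.phantoms,
            data_dir=cfg.data_dir,
            scheme=scheme,
            key_spec=cfg.key_spec if scheme == cfg.scheme else None,
            paper_order=cfg.paper_order,
            backbone=cfg.backbone,
            dnn=cfg.dnn,
            test_fraction=cfg.test_fraction,
            metrics_mode=cfg.metrics_mode,
            seed=cfg.seed,
        )
        sub_out = None if out_dir is None else Path(out_dir) / scheme
        result = run_pipeline(sub, sub_out)
        name = f"{cfg.backbone.architecture}+dnn"
        rows.append((name, scheme, result.report))
    table = results_table(rows)
    if out_dir is not None:
        write_metrics_csv(table, Path(out_dir) / "comparison.csv")
    return table
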