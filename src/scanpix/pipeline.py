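"""End-to-end orchestration: simulate/ingest -> encode -> train -> evaluate.

Every intermediate product is persisted (cohort CSV, encoded PNGs plus an
index CSV carrying labels, split manifest, metrics JSON) and a run manifest
records the master seed, the per-stage sub-seeds and a hash of the full
configuration.  Re-running with an identical configuration skips stages
whose recorded config hash matches and whose outputs still exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import encoding as enc
from . import fixation_io as fio
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | ingest
    out_dir: str = "scanpix_run"
    input_csv: str | None = None  # required in ingest mode
    n_adults: int = 18
    n_children: int = 16
    seed: int = 0
    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    encoding: enc.EncodingConfig = field(default_factory=enc.EncodingConfig)
    training: clf.TrainConfig = field(default_factory=lambda: clf.DESK_TRAIN_CONFIG)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.input_csv:
            raise ValueError("ingest mode requires input_csv")
        if self.mode == "synthetic" and min(self.n_adults, self.n_children) < 1:
            raise ValueError("synthetic mode needs at least one subject per class")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub_cls in (
            ("simulation", syn.SimulationConfig),
            ("encoding", enc.EncodingConfig),
            ("training", clf.TrainConfig),
        ):
            if key in raw:
                sub = dict(raw[key])
                for tup_key in ("screen_dims", "grid_dims", "lead_time_windows",
                                "lag_set_mi", "lag_set_li"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                raw[key] = sub_cls(**sub)
        cfg = cls(**raw)
        if seed is not None:
            cfg = _reseed(cfg, seed)
        return cfg

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _reseed(cfg: PipelineConfig, master_seed: int) -> PipelineConfig:
    """Fan the master seed out into per-stage sub-seeds (< 2**31)."""
    sim_seed, split_seed, train_seed = (
        int(s) % (2**31) for s in np.random.SeedSequence(master_seed).generate_state(3)
    )
    return dataclasses.replace(
        cfg,
        seed=master_seed,
        simulation=dataclasses.replace(cfg.simulation, seed=sim_seed),
        training=dataclasses.replace(cfg.training, seed=train_seed),
    )


def make_config(seed: int, **overrides) -> PipelineConfig:
    """Default pipeline configuration with per-stage sub-seeds from ``seed``."""
    return _reseed(PipelineConfig(**overrides), seed)


def _split_seed(cfg: PipelineConfig) -> int:
    return int(np.random.SeedSequence(cfg.seed).generate_state(3)[1]) % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _manifest_path(out_dir: Path) -> Path:
    return out_dir / "run_manifest.json"


def _load_manifest(out_dir: Path) -> dict:
    p = _manifest_path(out_dir)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(out_dir: Path, manifest: dict) -> None:
    _manifest_path(out_dir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_done(manifest: dict, stage: str, cfg_hash: str, outputs: list[Path]) -> bool:
    rec = manifest["stages"].get(stage)
    return (
        rec is not None
        and rec.get("config_hash") == cfg_hash
        and all(Path(p).exists() for p in rec.get("outputs", []))
        and all(p.exists() for p in outputs)
    )


def encode_cohort(
    scanpaths: list[fio.Scanpath],
    config: enc.EncodingConfig,
    out_dir: str | Path | None = None,
) -> list[enc.EncodedImageSet]:
    """Validate and encode every scanpath; optionally persist PNGs + index."""
    image_sets = []
    index_rows = []
    for sp in scanpaths:
        validated, _ = fio.validate_records(sp)
        iset = enc.encode_scanpath(validated, config)
        image_sets.append(iset)
        if out_dir is not None:
            for p in enc.write_image_set(iset, out_dir):
                index_rows.append({
                    "subject": iset.subject,
                    "stimulus": iset.stimulus,
                    "label": iset.label or "",
                    "kind": p.stem.rsplit("_", 1)[-1],
                    "file": p.name,
                })
    if out_dir is not None:
        pd.DataFrame(index_rows).to_csv(Path(out_dir) / "index.csv", index=False)
    return image_sets


def load_encoded_dir(image_dir: str | Path) -> list[enc.EncodedImageSet]:
    """Rebuild image sets from a directory written by :func:`encode_cohort`."""
    image_dir = Path(image_dir)
    index = pd.read_csv(image_dir / "index.csv", dtype=str, keep_default_na=False)
    sets: dict[tuple[str, str], dict] = {}
    for _, row in index.iterrows():
        key = (row["subject"], row["stimulus"])
        entry = sets.setdefault(key, {"label": row["label"] or None})
        entry[row["kind"]] = enc.read_image(image_dir / row["file"])
    return [
        enc.EncodedImageSet(
            pi=e["PI"], mi=e["MI"], li=e["LI"],
            subject=subj, stimulus=stim, label=e["label"],
        )
        for (subj, stim), e in sets.items()
    ]


def save_model(model: clf.TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    return path


def load_model(path: str | Path) -> clf.TrainedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run simulate/ingest -> encode -> split -> train -> evaluate.

    Returns a dict of product paths plus the metrics report.  Any stage
    failure aborts with the stage name and cause; products of completed
    stages are retained for debugging.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest = _load_manifest(out_dir)
    manifest.update({
        "config": config.to_jsonable(),
        "config_hash": cfg_hash,
        "master_seed": config.seed,
        "stage_seeds": {
            "simulation": config.simulation.seed,
            "split": _split_seed(config),
            "training": config.training.seed,
        },
    })

    cohort_csv = out_dir / "cohort.csv"
    image_dir = out_dir / "images"
    split_path = out_dir / "split_manifest.json"
    model_path = out_dir / "model.pkl"
    metrics_path = out_dir / "metrics.json"

    def finish(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "config_hash": cfg_hash,
            "outputs": [str(p) for p in outputs],
        }
        _save_manifest(out_dir, manifest)
        logger.info("stage %s done: %s", stage, [p.name for p in outputs])

    # --- acquire ---------------------------------------------------------
    try:
        if config.mode == "ingest":
            cohort_csv = Path(config.input_csv)
            scanpaths = fio.read_fixation_table(cohort_csv)
        elif _stage_done(manifest, "simulate", cfg_hash, [cohort_csv]):
            logger.info("stage simulate skipped (up to date)")
            scanpaths = fio.read_fixation_table(cohort_csv)
        else:
            scanpaths = syn.generate_cohort(
                config.n_adults, config.n_children, config.simulation
            )
            fio.write_fixation_table(scanpaths, cohort_csv)
            finish("simulate", [cohort_csv])
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # --- encode ----------------------------------------------------------
    try:
        if _stage_done(manifest, "encode", cfg_hash, [image_dir / "index.csv"]):
            logger.info("stage encode skipped (up to date)")
            image_sets = load_encoded_dir(image_dir)
        else:
            image_sets = encode_cohort(scanpaths, config.encoding, image_dir)
            finish("encode", [image_dir / "index.csv"])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("encode", e) from e

    # --- split -----------------------------------------------------------
    try:
        dataset = clf.build_dataset(image_sets)
        train_set, test_set = clf.split_dataset(
            dataset, config.training.split_fraction, seed=_split_seed(config)
        )
        split_manifest = {
            "train_groups": sorted({f"{s.subject}|{s.stimulus}" for s in train_set.samples}),
            "test_groups": sorted({f"{s.subject}|{s.stimulus}" for s in test_set.samples}),
        }
        split_path.write_text(json.dumps(split_manifest, indent=2, sort_keys=True))
        finish("split", [split_path])
    except Exception as e:  # noqa: BLE001
        raise StageError("split", e) from e

    # --- train -----------------------------------------------------------
    try:
        if _stage_done(manifest, "train", cfg_hash, [model_path]):
            logger.info("stage train skipped (up to date)")
            model = load_model(model_path)
        else:
            model = clf.train_classifier(train_set, config.training)
            save_model(model, model_path)
            finish("train", [model_path])
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e

    # --- evaluate --------------------------------------------------------
    try:
        counts = clf.evaluate_classifier(model, test_set)
        report = clf.compute_metrics(counts)
        metrics_path.write_text(
            json.dumps(report.rounded() | {"raw": report.to_dict()},
                       indent=2, sort_keys=True)
        )
        finish("evaluate", [metrics_path])
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    return {
        "cohort_csv": cohort_csv,
        "image_dir": image_dir,
        "split_manifest": split_path,
        "model": model_path,
        "metrics": metrics_path,
        "report": report,
    }
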