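"""End-to-end orchestration: generate -> restore -> features -> train ->
explain -> embed, driven by one JSON-serializable config.

A single master seed fans out deterministically to every stage (scene
generation, train/test split, model fitting, permutation repeats, UMAP), so
rerunning the same config reproduces every deterministic artifact bit for
bit.  Each run writes a manifest listing the artifacts it produced together
with a hash of the config that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ml import SplitSpec, run_matrix, split, train_evaluate
from .restore import WaveletSpec
from .synth import SceneConfig, generate_dataset, write_dataset
from .texture import GlcmSpec, extract_features

log = logging.getLogger("ppsw")

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class RunConfig:
    n_per_class: int = 30
    scene: SceneConfig = field(default_factory=SceneConfig)
    variants: tuple[str, ...] = ("u", "dftmod_ppsw")
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    glcm: GlcmSpec = field(default_factory=GlcmSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    models: tuple[str, ...] = ("random_forest",)
    targets: tuple[str, ...] = ("density", "media")
    seed: int = 0
    n_estimators: int | None = None
    rpca_downscale: int = 2
    output_dir: str = "ppsw_run"
    write_images: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("scene", SceneConfig), ("wavelet", WaveletSpec),
                         ("glcm", GlcmSpec), ("split", SplitSpec)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        for key in ("variants", "models", "targets"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, default=str))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("data", "split", "model", "perm", "embed")
    state = ss.generate_state(len(names)) % (2**31)
    return {n: int(s) for n, s in zip(names, state)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest.

    Stage order: synthetic data generation, per-variant feature extraction,
    model training/evaluation, SHAP summary + bias, raw vs SHAP embeddings.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "seeds": seeds, "artifacts": []}

    def _artifact(path: Path, frame: pd.DataFrame | None = None):
        if frame is not None:
            with open(path, "w") as fh:
                fh.write(f"# config_hash={chash}\n")
                frame.to_csv(fh, index=False)
        manifest["artifacts"].append(str(path))

    save_config(config, out / "run_config.json")
    manifest["artifacts"].append(str(out / "run_config.json"))
    manifest["artifacts"].append(str(out / "run.log"))

    stage = "generate"
    try:
        log.info("stage=%s seed=%d", stage, seeds["data"])
        scene = dataclasses.replace(config.scene, seed=seeds["data"])
        images = generate_dataset(config.n_per_class, scene, seed=seeds["data"])
        if config.write_images:
            _artifact(write_dataset(images, out / "images"))

        stage = "features"
        tables: dict[str, pd.DataFrame] = {}
        density = [li.density_label for li in images]
        media = [li.media_label for li in images]
        for variant in config.variants:
            log.info("stage=%s variant=%s", stage, variant)
            table = extract_features(
                [li.image for li in images],
                density_labels=density,
                media_labels=media,
                variant=variant,
                spec=config.glcm,
                wavelet_spec=config.wavelet,
                rpca_downscale=config.rpca_downscale,
            )
            path = out / f"features_{variant}.csv"
            _artifact(path, table)
            tables[variant] = table

        stage = "train"
        split_spec = dataclasses.replace(config.split, seed=seeds["split"])
        results = run_matrix(
            tables,
            targets=config.targets,
            models=config.models,
            seed=seeds["model"],
            split_spec=split_spec,
            n_estimators=config.n_estimators,
        )
        _artifact(out / "results.csv", results)

        stage = "explain"
        from .explain import embed, shap_bias, shap_summarize, silhouette

        explain_out: dict = {}
        if "random_forest" in config.models and "density" in config.targets:
            summaries = {}
            for variant in config.variants:
                train, test = split(tables[variant], split_spec)
                res = train_evaluate(
                    train, test, "random_forest", "density",
                    seed=seeds["model"], n_estimators=config.n_estimators,
                )
                summaries[variant] = (shap_summarize(res, test), test)
            if len(config.variants) >= 2:
                a, b = config.variants[0], config.variants[1]
                bias = shap_bias(summaries[b][0], summaries[a][0], variant_a=b, variant_b=a)
                explain_out["bias"] = {
                    "variant_a": bias.variant_a,
                    "variant_b": bias.variant_b,
                    "per_class": bias.per_class_bias,
                }

            stage = "embed"
            variant = config.variants[-1]
            summary, test = summaries[variant]
            from .ml import feature_matrix

            x_test, _ = feature_matrix(test)
            labels = test["density_label"].to_numpy()
            nn = min(15, len(labels) - 1)
            e_raw = embed(x_test, labels, "raw_features", seed=seeds["embed"], n_neighbors=nn)
            e_shap = embed(
                summary.sample_vectors(), labels, "shap_values",
                seed=seeds["embed"], n_neighbors=nn,
            )
            emb_frame = pd.DataFrame(
                {
                    "raw_x": e_raw.coords[:, 0], "raw_y": e_raw.coords[:, 1],
                    "shap_x": e_shap.coords[:, 0], "shap_y": e_shap.coords[:, 1],
                    "density_label": labels,
                }
            )
            _artifact(out / "embeddings.csv", emb_frame)
            explain_out["silhouette_raw"] = silhouette(e_raw)
            explain_out["silhouette_shap"] = silhouette(e_shap)
        manifest["explain"] = explain_out
        (out / "explain.json").write_text(json.dumps(explain_out, indent=2))
        manifest["artifacts"].append(str(out / "explain.json"))
    except Exception as exc:
        log.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"].append(str(manifest_path))
    log.removeHandler(handler)
    return manifest
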