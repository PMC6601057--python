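"""End-to-end orchestration: images -> features -> ranking -> evaluation.

Ties the stages together under a single serializable configuration so a
run is reproducible from (config, seed), and provides single-image
classification against a trained model bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from PIL import Image

from . import synthetic
from .features import extract_all
from .models import (SplitSpec, EvalSummary, evaluate_repeated, train_model,
                     stratified_split)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .selection import rank_features


@dataclass
class RunConfig:
    """Full parameterization of one end-to-end run."""

    seed: int = 0
    simulate: bool = True
    n_per_class: int = 20
    profile: str = "strong"
    image_size: tuple[int, int] = (256, 256)
    in_dir: str | None = None
    manifest: str | None = None
    out_dir: str = "results"
    algorithms: tuple[str, ...] = ("RF", "SVM", "MLP", "FUZZYW")
    n_repetitions: int = 50
    train_fraction: float = 0.70
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        d["algorithms"] = list(d["algorithms"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_manifest_images(in_dir: str | Path, manifest_path: str | Path):
    """Read (image, row) pairs from a directory + CSV manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    images = []
    for _, row in manifest.iterrows():
        path = Path(in_dir) / f"image_{int(row.image_id):04d}.png"
        pixels = np.asarray(Image.open(path).convert("RGB"))
        images.append(synthetic.LabeledImage(
            pixels=pixels, degree=row.degree,
            sample_id=int(row.sample_id), image_id=int(row.image_id)))
    return images, manifest


def save_images(images, manifest: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for im in images:
        Image.fromarray(im.pixels).save(out / f"image_{im.image_id:04d}.png")
    manifest.to_csv(out / "manifest.csv", index=False)


def extract_features_table(images, config: PreprocessConfig | None = None,
                           progress=None) -> pd.DataFrame:
    """Preprocess + 25-feature extraction for a list of labeled images."""
    rows = []
    for im in images:
        try:
            enhanced = preprocess_pipeline(im.pixels, config)
            fv = extract_all(enhanced)
        except Exception as exc:
            raise RuntimeError(f"image {im.image_id}: {exc}") from exc
        row = {"image_id": im.image_id, "sample_id": im.sample_id,
               "degree": im.degree}
        row.update({f"f{k}": fv[k] for k in range(1, 26)})
        rows.append(row)
        if progress is not None:
            progress(im.image_id)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, EvalSummary]:
    """Execute simulate? -> preprocess -> extract -> rank -> evaluate.

    Writes features.csv, ranking.json, per-algorithm metrics and error
    maps, and a run report carrying the config and its hash, under
    ``config.out_dir``.  Returns the per-algorithm evaluation summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        images, manifest = synthetic.generate_dataset(
            config.n_per_class, config.seed, profile=config.profile,
            image_size=config.image_size)
    else:
        if config.in_dir is None or config.manifest is None:
            raise ValueError("in_dir and manifest required unless simulating")
        images, manifest = load_manifest_images(config.in_dir, config.manifest)

    features = extract_features_table(images, config.preprocess)
    features.to_csv(out / "features.csv", index=False)

    ranking = rank_features(features)
    (out / "ranking.json").write_text(json.dumps({
        "scores": {str(k): v for k, v in sorted(ranking.scores.items())},
        "retained": ranking.retained,
        "config_hash": config.config_hash,
    }, indent=2))

    spec = SplitSpec(train_fraction=config.train_fraction,
                     n_repetitions=config.n_repetitions, seed=config.seed)
    summaries: dict[str, EvalSummary] = {}
    report = {"config": config.to_dict(), "config_hash": config.config_hash,
              "n_images": len(images), "retained": ranking.retained,
              "algorithms": {}}
    for algo in config.algorithms:
        summary = evaluate_repeated(features, algo, spec,
                                    feature_numbers=ranking.retained)
        summaries[algo] = summary
        summary.per_repetition.to_csv(
            out / f"metrics_{algo.lower()}.csv", index=False)
        summary.error_map.to_csv(
            out / f"error_map_{algo.lower()}.csv", index=False)
        report["algorithms"][algo] = {
            "mean": summary.metrics_mean, "std": summary.metrics_std,
            "most_misclassified":
                summary.most_misclassified["image_id"].tolist(),
        }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return summaries


def train_bundle(features: pd.DataFrame, algorithm: str, retained: list[int],
                 seed: int, config_hash: str = "") -> dict:
    """Fit one tuned model on the full feature table for later inference."""
    X = features[[f"f{k}" for k in retained]].to_numpy(dtype=np.float64)
    y = features["degree"].to_numpy()
    model = train_model(algorithm, X, y, seed=seed)
    return {"model": model, "algorithm": algorithm.upper(),
            "retained": retained, "config_hash": config_hash}


def save_bundle(bundle: dict, path: str | Path) -> None:
    joblib.dump(bundle, path)


def load_bundle(path: str | Path) -> dict:
    return joblib.load(path)


def classify_image(image_path: str | Path, bundle: dict,
                   config: PreprocessConfig | None = None):
    """Grade one image with a trained bundle.

    Returns (degree, FeatureVector) so the prediction can be audited
    against the raw descriptor.
    """
    pixels = np.asarray(Image.open(image_path).convert("RGB"))
    enhanced = preprocess_pipeline(pixels, config)
    fv = extract_all(enhanced)
    x = np.array([[fv[k] for k in bundle["retained"]]])
    degree = str(np.asarray(bundle["model"].predict(x)).item())
    return degree, fv
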