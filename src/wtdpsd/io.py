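"""Dataset loading and top-level pipeline orchestration.

A dataset is a directory with one subdirectory per class (``HC``, ``AD``,
``MCI``) of 8-bit grayscale PNGs (any raster Pillow reads is accepted;
color inputs are converted to luminance with the ITU-R 601 weights that
Pillow's ``"L"`` mode applies).  Class-name-to-label coding is fixed as
HC=1, AD=2, MCI=3 and stored in every manifest.

``pipeline_run`` executes the whole chain — decompose, describe, reduce,
classify, evaluate — and writes every artifact with a provenance block
(config hash, seed, wavelet, lambda, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .classify import CLASS_NAMES, ExperimentConfig, run_experiment
from .reduce import fit_pca, scree_table
from .synthetic import SyntheticSpec, generate
from .tdpsd import FeatureConfig, extract_features, feature_table, flag_table
from .wavelet import ImageSample

logger = logging.getLogger("wtdpsd")

CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES, start=1)}


@dataclass
class DatasetManifest:
    """Ordered records of (path, id, label) with the fixed label coding."""

    records: pd.DataFrame  # columns: path, id, label, label_code
    class_names: tuple = CLASS_NAMES

    def labels(self) -> np.ndarray:
        return self.records["label_code"].to_numpy()


def _read_grayscale(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)


def load_dataset(
    root_dir: Union[str, Path], class_names: tuple = CLASS_NAMES
) -> tuple[DatasetManifest, list[ImageSample]]:
    """Load a class-per-subdirectory image tree.

    Ordering is stable: classes in declared order, filenames sorted within
    each class.  Missing or empty class directories raise an error naming
    the class; unreadable files raise an error naming the file.
    """
    root = Path(root_dir)
    records = []
    images: list[ImageSample] = []
    for name in class_names:
        class_dir = root / name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"class directory missing: {name!r} ({class_dir})")
        files = sorted(
            p for p in class_dir.iterdir() if p.is_file() and not p.name.startswith(".")
        )
        if not files:
            raise FileNotFoundError(f"class directory empty: {name!r} ({class_dir})")
        for path in files:
            try:
                pixels = _read_grayscale(path)
            except Exception as exc:
                raise OSError(f"unreadable image file: {path}") from exc
            image_id = f"{name}/{path.stem}"
            images.append(ImageSample(pixels, label=name, id=image_id))
            records.append(
                {
                    "path": str(path),
                    "id": image_id,
                    "label": name,
                    "label_code": CLASS_CODES[name],
                }
            )
    manifest = DatasetManifest(records=pd.DataFrame(records), class_names=class_names)
    ids = manifest.records["id"]
    if ids.duplicated().any():
        raise ValueError(f"duplicate image ids: {ids[ids.duplicated()].tolist()}")
    return manifest, images


@dataclass
class PipelineConfig:
    """Everything one end-to-end run depends on.

    Exactly one of ``data_dir`` (a class-per-subdirectory tree) or
    ``synthetic`` (an in-memory cohort spec) provides the images.
    """

    data_dir: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    features: FeatureConfig = field(default_factory=FeatureConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    out_dir: str = "wtdpsd_out"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "data_dir": self.data_dir,
                "synthetic": asdict(self.synthetic) if self.synthetic else None,
                "features": asdict(self.features),
                "experiment": {
                    **asdict(self.experiment),
                    "classifiers": list(self.experiment.classifiers),
                },
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    import sklearn
    import pywt

    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "seed": config.experiment.seed,
        "wavelet_name": config.features.wavelet_name,
        "boundary_mode": config.features.boundary_mode,
        "lambda": config.features.lam,
        "zero_tolerance": config.features.zero_tolerance,
        "versions": {
            "wtdpsd": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "pywavelets": pywt.__version__,
        },
    }


def extract_feature_table(
    images: list[ImageSample], config: FeatureConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor extraction over a cohort -> (features, guard-flag events)."""
    vectors = [extract_features(img, config) for img in images]
    n_flagged = sum(1 for v in vectors if v.flags)
    if n_flagged:
        logger.info("guard flags fired on %d of %d images", n_flagged, len(vectors))
    return feature_table(vectors), flag_table(vectors)


def pipeline_run(config: PipelineConfig) -> dict[str, str]:
    """Run decompose -> describe -> reduce -> classify -> evaluate.

    Writes features, flags, scree data, per-classifier reports, the summary
    table and a provenance block into ``config.out_dir``; returns the
    artifact paths.  Any stage failure aborts with a stage-labeled message,
    retaining artifacts written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    provenance = _provenance(config)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        t = stage("load")
        if (config.data_dir is None) == (config.synthetic is None):
            raise ValueError("exactly one of data_dir or synthetic must be set")
        if config.data_dir is not None:
            manifest, images = load_dataset(config.data_dir)
            labels = manifest.labels()
        else:
            images, _ = generate(config.synthetic)
            labels = np.array([CLASS_CODES[img.label] for img in images])
        timings["load"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"[stage: load] {exc}") from exc

    try:
        t = stage("features")
        features, flags = extract_feature_table(images, config.features)
        fpath = out / "features.csv"
        features.to_csv(fpath, index=False)
        flags.to_csv(out / "flags.csv", index=False)
        artifacts["features"] = str(fpath)
        artifacts["flags"] = str(out / "flags.csv")
        timings["features"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"[stage: features] {exc}") from exc

    X = features.drop(columns=["image_id", "label"]).to_numpy()

    try:
        t = stage("reduce")
        # cohort-level fit for the scree report; the experiment refits per fold
        pca = fit_pca(
            X,
            n_components=config.experiment.n_components,
            standardize=config.experiment.standardize,
        )
        pca.save(out / "pca_model")
        scree_table(pca).to_csv(out / "scree.csv", index=False)
        artifacts["pca_model"] = str(out / "pca_model.json")
        artifacts["scree"] = str(out / "scree.csv")
        timings["reduce"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"[stage: reduce] {exc}") from exc

    try:
        t = stage("classify")
        reports, summary = run_experiment(X, labels, config.experiment)
        summary.to_csv(out / "summary.csv", index=False)
        artifacts["summary"] = str(out / "summary.csv")
        report_payload = {kind: r.to_dict() for kind, r in reports.items()}
        confusion_text = "\n\n".join(
            f"{kind}\n{r.confusion_text()}" for kind, r in reports.items()
        )
        (out / "confusion.txt").write_text(confusion_text + "\n")
        artifacts["confusion"] = str(out / "confusion.txt")
        timings["classify"] = time.perf_counter() - t
    except Exception as exc:
        raise RuntimeError(f"[stage: classify] {exc}") from exc

    payload = {
        "provenance": provenance,
        "timings_s": timings,
        "n_images": len(images),
        "guard_flag_events": int(len(flags)),
        "reports": report_payload,
    }
    (out / "reports.json").write_text(json.dumps(payload, indent=2))
    artifacts["reports"] = str(out / "reports.json")
    return artifacts
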