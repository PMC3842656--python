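"""Image and table I/O, pipeline configuration, and the end-to-end pipeline.

B-scans are read from 8-bit PNG/TIFF, headerless RAW (row-major, geometry
from the config) or DICOM (pixel payload only).  Feature tables are CSV with
a fixed ``image_id, label, split, w1..w20`` header; contours are per-column
CSV; models are JSON.  Every table/model file embeds the hash of the config
that produced it, so outputs are traceable to their parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import features, morphology, preprocess
from .classify import CARTree
from .features import FEATURE_NAMES
from .morphology import ConditionalParams
from .preprocess import RPEContour
from .synthetic import LabelledDataset

log = logging.getLogger("choroidtex")

__all__ = [
    "PipelineConfig",
    "read_bscan",
    "write_bscan",
    "read_contour",
    "write_contour",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
    "process_bscan",
    "run_pipeline",
    "write_dataset",
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    The two thresholds both called ``p_r`` in the method description are
    distinct here: ``p_r_rpe`` (0.9) controls the RPE candidate cluster and
    ``p_r_bin`` (0.5) the binarization of the opened residual images.
    """

    rows: int = 256
    cols: int = 1024
    median_size: int = 3
    p_r_rpe: float = 0.9
    mean_mask_size: int = 30
    p_r_bin: float = 0.5
    scales: tuple[int, ...] = (3, 5, 7, 9, 11)
    p_we: float = 0.0
    p_wd: float = 0.0
    p_mn: float = 0.5
    n_rounds: int = 3
    morphology_order: str = "as-printed"
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_r_rpe <= 1.0:
            raise ValueError("p_r_rpe must be in (0, 1]")
        if not 0.0 < self.p_r_bin < 1.0:
            raise ValueError("p_r_bin must be in (0, 1)")
        ConditionalParams(self.p_we, self.p_wd, self.p_mn, self.n_rounds)

    def conditional_params(self) -> ConditionalParams:
        return ConditionalParams(self.p_we, self.p_wd, self.p_mn, self.n_rounds)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)

    def to_toml(self, path: str | Path) -> None:
        lines = ["[pipeline]"]
        for k, v in self.to_dict().items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, list):
                lines.append(f"{k} = [{', '.join(str(x) for x in v)}]")
            else:
                lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data["pipeline"])

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_bscan(path: str | Path, config: PipelineConfig | None = None) -> np.ndarray:
    """Read a single-channel 8-bit B-scan from PNG/TIFF/RAW/DICOM.

    RAW files are headerless row-major uint8 with geometry from the config;
    a byte-count mismatch is a hard error.  Multi-channel inputs are reduced
    by luminance averaging with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".raw":
        if config is None:
            raise ValueError("RAW input needs a config with rows/cols geometry")
        expected = config.rows * config.cols
        data = np.fromfile(path, dtype=np.uint8)
        if data.size != expected:
            raise ValueError(
                f"RAW size mismatch for {path.name}: expected {expected} bytes "
                f"({config.rows}x{config.cols}), got {data.size}")
        return data.reshape(config.rows, config.cols)
    if suffix in (".dcm", ".dicom"):
        import pydicom

        arr = pydicom.dcmread(path).pixel_array
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel input reduced by luminance "
                      "averaging", stacklevel=2)
        arr = arr.mean(axis=2)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255)
    return arr.astype(np.uint8)


def write_bscan(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def write_contour(path: str | Path, contour: RPEContour,
                  config: PipelineConfig | None = None) -> None:
    """One line per column: column index, row index, flagged(0/1)."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()}\n")
        fh.write("column,row,flagged\n")
        for n, (r, f) in enumerate(zip(contour.rows, contour.flagged)):
            fh.write(f"{n},{int(r)},{int(f)}\n")


def read_contour(path: str | Path) -> RPEContour:
    df = pd.read_csv(path, comment="#")
    return RPEContour(rows=df["row"].to_numpy(),
                      flagged=df["flagged"].to_numpy().astype(bool))


def save_scale_stack(out_dir: str | Path, stack, params: ConditionalParams,
                     config: PipelineConfig | None = None) -> Path:
    """Persist a scale stack as per-scale PNGs plus a JSON sidecar.

    Binary and refined maps round-trip exactly (0/255 PNGs); opened images
    are stored 8-bit after min-max scaling with the range recorded in the
    sidecar, so they reload approximately.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {
        "scales": list(stack.scales),
        "p_we": params.p_we, "p_wd": params.p_wd,
        "p_mn": float(np.mean(params.p_mn)), "n_rounds": params.n_rounds,
        "opened_range": {},
    }
    if config is not None:
        sidecar["config_hash"] = config.hash()
    for size in stack.scales:
        for kind in ("binary", "refined"):
            write_bscan(out_dir / f"{kind}_{size}.png",
                        getattr(stack, kind)[size] * 255)
        opened = stack.opened[size]
        lo, hi = float(opened.min()), float(opened.max())
        sidecar["opened_range"][str(size)] = [lo, hi]
        scaled = np.zeros_like(opened) if hi == lo else (opened - lo) / (hi - lo)
        write_bscan(out_dir / f"opened_{size}.png", np.rint(scaled * 255))
    (out_dir / "stack.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir / "stack.json"


def load_scale_stack(in_dir: str | Path):
    from .morphology import ScaleStack

    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "stack.json").read_text())
    stack = ScaleStack(scales=tuple(sidecar["scales"]))
    for size in stack.scales:
        stack.binary[size] = (read_bscan(in_dir / f"binary_{size}.png") > 127
                              ).astype(np.uint8)
        stack.refined[size] = (read_bscan(in_dir / f"refined_{size}.png") > 127
                               ).astype(np.uint8)
        lo, hi = sidecar["opened_range"][str(size)]
        raw = read_bscan(in_dir / f"opened_{size}.png").astype(np.float64) / 255.0
        stack.opened[size] = raw * (hi - lo) + lo
    return stack


# ---------------------------------------------------------------------------
# feature tables and models
# ---------------------------------------------------------------------------

FEATURE_HEADER = ("image_id", "label", "split") + FEATURE_NAMES


def write_features(path: str | Path, table: pd.DataFrame,
                   config: PipelineConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()}\n")
        table.to_csv(fh, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_model(path: str | Path, tree: CARTree,
               config: PipelineConfig | None = None) -> None:
    payload = tree.to_dict()
    if config is not None:
        payload["config_hash"] = config.hash()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> CARTree:
    return CARTree.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def process_bscan(image: np.ndarray, config: PipelineConfig | None = None,
                  return_intermediates: bool = False):
    """Run one B-scan through the whole analysis chain to its feature vector.

    median filter → RPE detection → flattening → brightness correction →
    multiscale filter bank with conditional refinement → 20 features.
    """
    if config is None:
        config = PipelineConfig()
    flat, contour = preprocess.preprocess_bscan(
        image, median_size=config.median_size, p_r=config.p_r_rpe)
    corrected = morphology.brightness_correction(flat, config.mean_mask_size)
    stack = morphology.build_scale_stack(
        corrected, scales=config.scales, params=config.conditional_params(),
        p_r_bin=config.p_r_bin, order=config.morphology_order)
    w = features.extract_features(stack, corrected)
    if return_intermediates:
        return w, {"contour": contour, "flattened": flat,
                   "corrected": corrected, "stack": stack}
    return w


def run_pipeline(inputs, config: PipelineConfig | None = None,
                 labels=None, splits=None,
                 model: CARTree | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Process a batch of images into a feature table.

    ``inputs`` is a list of file paths, ``(image_id, array)`` pairs, or a
    :class:`LabelledDataset`.  A failing image is logged and skipped; the
    list of failed ids is returned alongside the table so callers (the CLI)
    can exit non-zero.  With a ``model``, a ``predicted`` column is added.
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(inputs, LabelledDataset):
        labels = inputs.labels
        splits = inputs.split_assignment
        inputs = [(f"phantom_{i:04d}", img) for i, img in enumerate(inputs.images)]
    rows = []
    failed: list[str] = []
    for i, item in enumerate(inputs):
        if isinstance(item, (str, Path)):
            image_id = Path(item).stem
            try:
                image = read_bscan(item, config)
            except Exception as exc:  # noqa: BLE001 - per-image isolation
                log.error("failed to read %s: %s", item, exc)
                failed.append(str(item))
                continue
        else:
            image_id, image = item
        try:
            w = process_bscan(image, config)
        except Exception as exc:  # noqa: BLE001
            log.error("pipeline failed on %s: %s", image_id, exc)
            failed.append(str(image_id))
            continue
        row = {"image_id": image_id,
               "label": labels[i] if labels is not None else "",
               "split": splits[i] if splits is not None else ""}
        row.update({name: w[k] for k, name in enumerate(FEATURE_NAMES)})
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(FEATURE_HEADER))
    if model is not None and len(table):
        table["predicted"] = model.predict(table[list(FEATURE_NAMES)].to_numpy())
    return table, failed


def write_dataset(dataset: LabelledDataset, out_dir: str | Path,
                  config: PipelineConfig | None = None) -> Path:
    """Write phantom PNGs, contour CSVs and the sidecar manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, contour, label, split, spec) in enumerate(
            zip(dataset.images, dataset.contours, dataset.labels,
                dataset.split_assignment, dataset.specs)):
        name = f"phantom_{i:04d}"
        write_bscan(out_dir / f"{name}.png", img)
        write_contour(out_dir / f"{name}_contour.csv", contour)
        records.append({"filename": f"{name}.png", "label": label, "split": split,
                        "seed": spec.seed, "contour_file": f"{name}_contour.csv"})
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()}\n")
        pd.DataFrame(records).to_csv(fh, index=False)
    return manifest
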