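"""File interfaces: multi-page TIFF, ground-truth JSON sidecars, cohort
manifests, and YAML configuration round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mitoquant.image_quant import SegmentationConfig
from mitoquant.micrograph import Micrograph
from mitoquant.synthetic_data import CohortDesign, GroundTruth, SynthImageParams

MANIFEST_COLUMNS = ("image_id", "animal_id", "PINK1", "POLG", "muscle", "image_path")


def save_micrograph_tiff(path, micrograph: Micrograph) -> None:
    """Write a multi-page 16-bit TIFF, one page per channel (green, red[, label]).

    The pixel size and channel order are stored in the image description as
    JSON so the file round-trips without a sidecar.
    """
    channels = micrograph.channels()
    stack = np.stack([np.asarray(c) for c in channels.values()]).astype(np.uint16)
    meta = {
        "pixel_size_um": micrograph.pixel_size_um,
        "channels": list(channels.keys()),
        "bit_depth": micrograph.bit_depth,
        "image_id": micrograph.image_id,
    }
    # one grayscale page per channel (a 3-plane stack would otherwise be
    # guessed as planar RGB)
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )


def load_micrograph_tiff(path, pixel_size_um: float | None = None) -> Micrograph:
    """Read a multi-page TIFF written by :func:`save_micrograph_tiff`.

    Plain TIFFs without the JSON description are accepted when
    ``pixel_size_um`` is supplied; pages are then taken as green, red
    (and label if a third page exists).
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    channels = meta.get("channels", ["green", "red", "label"][: len(stack)])
    px = meta.get("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError(f"{path}: no pixel size in TIFF metadata and none supplied")
    chan_map = dict(zip(channels, stack))
    if "green" not in chan_map or "red" not in chan_map:
        raise ValueError(f"{path}: TIFF must contain green and red channels, got {channels}")
    return Micrograph(
        green=chan_map["green"],
        red=chan_map["red"],
        label=chan_map.get("label"),
        pixel_size_um=float(px),
        bit_depth=int(meta.get("bit_depth", 16)),
        image_id=str(meta.get("image_id", Path(path).stem)),
    )


def _mask_to_rle(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    # run-length encoding starting with the length of the initial False run
    changes = np.flatnonzero(np.diff(flat))
    runs = np.diff(np.concatenate(([0], changes + 1, [flat.size]))).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def _rle_to_mask(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in rle["runs"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)


def save_ground_truth_json(path, truth: GroundTruth) -> None:
    data = {
        "puncta": [[float(a), float(b), float(c)] for a, b, c in truth.puncta],
        "tissue_mask": _mask_to_rle(truth.tissue_mask),
        "population_mask": (
            _mask_to_rle(truth.population_mask) if truth.population_mask is not None else None
        ),
        "tissue_area_mm2": truth.tissue_area_mm2,
        "true_count": truth.true_count,
        "true_occupied_fraction": truth.true_occupied_fraction,
        "merged_count": truth.merged_count,
    }
    Path(path).write_text(json.dumps(data))


def load_ground_truth_json(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    puncta = [tuple(p) for p in data["puncta"]]
    from mitoquant.synthetic_data import _rasterize_disks  # local: avoids cycle at import

    tissue = _rle_to_mask(data["tissue_mask"])
    return GroundTruth(
        puncta=puncta,
        tissue_mask=tissue,
        population_mask=(
            _rle_to_mask(data["population_mask"]) if data["population_mask"] else None
        ),
        tissue_area_mm2=data["tissue_area_mm2"],
        true_count=data["true_count"],
        true_occupied_fraction=data["true_occupied_fraction"],
        merged_count=data["merged_count"],
        puncta_mask=_rasterize_disks(tissue.shape, puncta),
    )


def write_cohort(items, out_dir) -> pd.DataFrame:
    """Write a simulated cohort to disk: TIFFs, ground-truth JSONs, manifest CSV.

    Returns the manifest table (one row per image with genotype factors and
    image path) and writes it to ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for micro, truth, labels in items:
        img_path = out_dir / f"{labels['image_id']}.tif"
        save_micrograph_tiff(img_path, micro)
        save_ground_truth_json(out_dir / f"{labels['image_id']}.truth.json", truth)
        rows.append({**labels, "image_path": str(img_path)})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in ("image_id", "animal_id", "image_path") if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return manifest


_CONFIG_TYPES = {
    "image_params": SynthImageParams,
    "cohort_design": CohortDesign,
    "segmentation": SegmentationConfig,
}


def save_config_yaml(path, obj) -> None:
    """Write a params/design/config dataclass to YAML, keyed by its kind."""
    for key, cls in _CONFIG_TYPES.items():
        if isinstance(obj, cls):
            Path(path).write_text(yaml.safe_dump({key: obj.to_dict()}, sort_keys=False))
            return
    raise TypeError(f"unsupported config object {type(obj).__name__}")


def load_config_yaml(path):
    """Load a YAML config written by :func:`save_config_yaml`.

    A bare mapping (no kind key) is interpreted as a SegmentationConfig,
    which is the common hand-written case for the CLI.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    for key, cls in _CONFIG_TYPES.items():
        if key in data:
            return cls.from_dict(data[key])
    return SegmentationConfig.from_dict(data)
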