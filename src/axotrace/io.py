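"""Readers/writers and small utilities: TIFF images and masks, JSON/CSV
artifacts, YAML configuration, Z-stack flattening, and on-disk layout of
synthetic studies.

All result serialization is deterministic: JSON keys are sorted, CSVs use
"\\n" line endings and Python's round-tripping float repr, and no file
carries timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import NoDataError
from .retina import RetinaImage, DetectionParams
from .colliculus import SCSection
from .phantoms import PhantomTruth, SectionStack, ProjectionPhantom

__all__ = [
    "flatten_zstack",
    "read_image",
    "write_image",
    "load_retina",
    "load_sc_sections",
    "write_truth",
    "read_truth",
    "PipelineConfig",
    "write_retina_phantom",
    "write_sc_stack",
    "write_study",
    "write_json",
    "write_csv",
    "read_csv",
]


def flatten_zstack(stack: np.ndarray) -> np.ndarray:
    """Collapse a Z-stack to one plane by per-pixel maximum intensity.

    Single-plane (2-D) input is returned unchanged. Maximum projection
    preserves bright somata, which is all the downstream detector needs.
    """
    stack = np.asarray(stack)
    if stack.size == 0:
        raise NoDataError("empty stack")
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise NoDataError("stack must be 2-D or 3-D")
    if stack.shape[0] == 0:
        raise NoDataError("stack has no planes")
    return stack.max(axis=0)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(path, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(array))


def load_retina(image_path, mask_path, pixel_size_um: float) -> RetinaImage:
    """Read an image + nonzero-means-tissue mask pair as a RetinaImage.

    3-D image files are flattened by maximum-intensity projection.
    """
    pixels = flatten_zstack(read_image(image_path))
    mask = read_image(mask_path) != 0
    return RetinaImage(pixels=pixels, pixel_size_um=pixel_size_um, mask=mask)


def load_sc_sections(manifest_csv) -> list[SCSection]:
    """Read a per-section manifest into SCSection objects.

    The CSV needs columns ``image, roi, background, rostrocaudal_index``
    and optionally ``flip`` (0/1); paths are relative to the manifest.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    base = manifest_csv.parent
    sections = []
    for _, row in df.iterrows():
        sections.append(SCSection(
            pixels=read_image(base / row["image"]),
            roi_mask=read_image(base / row["roi"]) != 0,
            background_roi=read_image(base / row["background"]) != 0,
            rostrocaudal_index=int(row["rostrocaudal_index"]),
            flip=bool(row.get("flip", 0)),
        ))
    return sections


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_csv(path, df: pd.DataFrame) -> None:
    # %.17g round-trips every IEEE double exactly
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_csv(path) -> pd.DataFrame:
    # the default fast parser is lossy in the last ulp; round_trip is exact
    return pd.read_csv(path, float_precision="round_trip")


def write_truth(path, truth: PhantomTruth) -> None:
    write_json(path, truth.to_jsonable())


def read_truth(path) -> PhantomTruth:
    with open(path) as fh:
        return PhantomTruth.from_jsonable(json.load(fh))


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, YAML-serializable.

    Every parameter used by a run is echoed into the run log; nothing is a
    silent default.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    pixel_size_um: float = 1.5
    tile_um: float = 100.0
    min_sector_mm2: float = 0.05
    background_k: float = 2.0
    n_bins: int = 100
    alpha: float = 0.05
    render_maps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = DetectionParams(**raw.pop("detection", {}))
        return cls(detection=det, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def to_jsonable(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# on-disk phantom layout


def write_retina_phantom(out_dir, image: RetinaImage, truth: PhantomTruth) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(out_dir / "retina.tif", image.pixels.astype(np.float32))
    write_image(out_dir / "retina_mask.tif", image.mask.astype(np.uint8))
    write_truth(out_dir / "truth.json", truth)
    write_json(out_dir / "meta.json", {"pixel_size_um": image.pixel_size_um})


def write_sc_stack(out_dir, stack: SectionStack, truth: PhantomTruth) -> Path:
    """Write sections + per-section manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sec in enumerate(stack.sections):
        img = f"sec_{i:03d}_img.tif"
        roi = f"sec_{i:03d}_roi.tif"
        bg = f"sec_{i:03d}_bg.tif"
        write_image(out_dir / img, sec.pixels.astype(np.float32))
        write_image(out_dir / roi, sec.roi_mask.astype(np.uint8))
        write_image(out_dir / bg, sec.background_roi.astype(np.uint8))
        rows.append({"section_id": i, "image": img, "roi": roi,
                     "background": bg,
                     "rostrocaudal_index": sec.rostrocaudal_index,
                     "flip": int(sec.flip)})
    manifest = out_dir / "sections.csv"
    write_csv(manifest, pd.DataFrame(rows))
    write_truth(out_dir / "truth.json", truth)
    return manifest


def write_study(out_dir, projections: list[ProjectionPhantom],
                pixel_size_um: float) -> Path:
    """Write a whole synthetic study; returns the run-manifest CSV path.

    Layout: one directory per projection holding the retina pair, a ``ctb/``
    and an ``errb/`` section stack, and the truth sidecars; a top-level
    ``manifest.csv`` with one row per projection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for proj in projections:
        pdir = out_dir / proj.projection_id
        write_retina_phantom(pdir, proj.retina_image, proj.retina_truth)
        ctb_manifest = write_sc_stack(pdir / "ctb", proj.ctb_stack, proj.ctb_truth)
        errb_manifest = write_sc_stack(pdir / "errb", proj.errb_stack, proj.errb_truth)
        rows.append({
            "projection_id": proj.projection_id,
            "group": proj.group,
            "retina_image": str((pdir / "retina.tif").relative_to(out_dir)),
            "retina_mask": str((pdir / "retina_mask.tif").relative_to(out_dir)),
            "ctb_manifest": str(ctb_manifest.relative_to(out_dir)),
            "errb_manifest": str(errb_manifest.relative_to(out_dir)),
        })
    manifest = out_dir / "manifest.csv"
    write_csv(manifest, pd.DataFrame(rows))
    return manifest
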