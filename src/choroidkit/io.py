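"""File formats and run configuration.

Images travel as grayscale TIFF (preferred) or PNG with a JSON sidecar
carrying physical metadata (pixel scales, fovea position, axial length,
optional boundary annotations); masks as 8-bit 0/255 PNG; cohort tables as
CSV with unit-annotated ``#`` header comments; configuration as YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .quant import BScanImage, ChoroidSegmentation
from .angio import EnfaceAngiogram
from .synthetic import COHORT_COLUMNS

__all__ = [
    "save_image", "load_image", "save_mask", "load_mask",
    "save_bscan_sidecar", "load_bscan", "save_angio_sidecar", "load_angio",
    "save_cohort_csv", "load_cohort_csv", "RunConfig", "sha256_file",
]


def save_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif path.suffix.lower() == ".png":
        Image.fromarray(image).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    if path.suffix.lower() == ".png":
        return np.asarray(Image.open(path))
    raise ValueError(f"unsupported image format: {path.suffix}")


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (background 0, foreground 255)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr).save(Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path))) > 127


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

_BSCAN_REQUIRED = ("lateral_scale_um_px", "axial_scale_um_px",
                   "fovea_column", "axial_length_mm")


def save_bscan_sidecar(
    path: str | Path,
    bscan: BScanImage,
    seg: ChoroidSegmentation | None = None,
) -> None:
    meta = {
        "lateral_scale_um_px": bscan.lateral_scale,
        "axial_scale_um_px": bscan.axial_scale,
        "fovea_column": int(bscan.fovea_column),
        "axial_length_mm": bscan.axial_length_mm,
    }
    if seg is not None:
        meta["boundaries"] = {
            "upper": seg.upper.tolist(),
            "lower": seg.lower.tolist(),
        }
    Path(path).write_text(json.dumps(meta, indent=1))


def load_bscan(
    image_path: str | Path,
    meta_path: str | Path,
) -> tuple[BScanImage, ChoroidSegmentation | None]:
    meta = json.loads(Path(meta_path).read_text())
    missing = [k for k in _BSCAN_REQUIRED if k not in meta]
    if missing:
        raise KeyError(
            f"B-scan sidecar {meta_path} is missing required field(s): "
            f"{missing}"
        )
    bscan = BScanImage(
        intensity=load_image(image_path),
        lateral_scale=meta["lateral_scale_um_px"],
        axial_scale=meta["axial_scale_um_px"],
        fovea_column=meta["fovea_column"],
        axial_length_mm=meta["axial_length_mm"],
    )
    seg = None
    if "boundaries" in meta:
        seg = ChoroidSegmentation(
            upper=np.asarray(meta["boundaries"]["upper"]),
            lower=np.asarray(meta["boundaries"]["lower"]),
        )
    return bscan, seg


_ANGIO_REQUIRED = ("scale_um_px", "center")


def save_angio_sidecar(path: str | Path, angio: EnfaceAngiogram) -> None:
    meta = {"scale_um_px": angio.scale,
            "center": [float(c) for c in angio.center]}
    Path(path).write_text(json.dumps(meta, indent=1))


def load_angio(
    image_path: str | Path,
    meta_path: str | Path,
) -> EnfaceAngiogram:
    meta = json.loads(Path(meta_path).read_text())
    missing = [k for k in _ANGIO_REQUIRED if k not in meta]
    if missing:
        raise KeyError(
            f"angiogram sidecar {meta_path} is missing required field(s): "
            f"{missing}"
        )
    return EnfaceAngiogram(
        intensity=load_image(image_path),
        scale=meta["scale_um_px"],
        center=tuple(meta["center"]),
    )


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def save_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Write the cohort with a ``#``-commented column dictionary header."""
    lines = ["# choroidkit cohort table"]
    for col in table.columns:
        desc = COHORT_COLUMNS.get(col, "")
        lines.append(f"# {col}: {desc}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full simulate -> quantify -> analyze run.

    The override dicts are keyword arguments for the corresponding
    dataclasses (:class:`~choroidkit.synthetic.CohortGenParams`,
    :class:`~choroidkit.synthetic.BScanPhantomSpec`, ...); seeds for the
    phantoms are derived deterministically from ``seed``.
    """

    seed: int = 0
    outdir: str = "choroidkit_run"
    cohort: dict = field(default_factory=dict)
    n_bscan_phantoms: int = 3
    n_cc_phantoms: int = 3
    bscan_phantom: dict = field(default_factory=dict)
    cc_phantom: dict = field(default_factory=dict)
    binarization: dict = field(default_factory=dict)
    flow_deficit: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown RunConfig field(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
             else json.loads(text))
        return cls.from_dict(d)

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
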